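"""Protein grouping from peptide evidence.

Accessions that are identified by exactly the same set of peptides across the
whole dataset are indistinguishable by the evidence and are merged into one
group, counted once for quantification.  No subset/Occam collapsing is done:
only *identical* peptide sets merge.

A peptide is *unique* to a group when every accession it maps to belongs to
that group; only unique peptides enter between-sample quantification, and the
minimum-peptide rule (default 2) is applied to the unique set.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass

import pandas as pd

from .io_tables import split_accessions


@dataclass(frozen=True)
class ProteinGroup:
    """A set of accessions sharing identical peptide evidence.

    ``group_id`` is the lexicographically smallest member accession.
    ``quantifiable`` is True when the group has at least ``min_peptides``
    unique peptides.
    """

    group_id: str
    members: frozenset[str]
    peptide_set: frozenset[str]
    unique_peptides: frozenset[str]
    quantifiable: bool


def build_groups(table: pd.DataFrame, min_peptides: int = 2) -> list[ProteinGroup]:
    """Group accessions by identical peptide sets, over the union of samples.

    Returns groups sorted by ``group_id``; an empty table yields an empty
    list.
    """
    acc_peptides: dict[str, set[str]] = defaultdict(set)
    peptide_accs: dict[str, set[str]] = defaultdict(set)
    for pep, cell in zip(table.get("peptide_id", ()), table.get("accessions", ())):
        accs = split_accessions(cell)
        for acc in accs:
            acc_peptides[acc].add(pep)
        peptide_accs[pep].update(accs)

    by_evidence: dict[frozenset[str], set[str]] = defaultdict(set)
    for acc, peps in acc_peptides.items():
        by_evidence[frozenset(peps)].add(acc)

    groups: list[ProteinGroup] = []
    for peptide_set, members in by_evidence.items():
        members_f = frozenset(members)
        unique = frozenset(p for p in peptide_set if peptide_accs[p] <= members_f)
        groups.append(
            ProteinGroup(
                group_id=min(members_f),
                members=members_f,
                peptide_set=peptide_set,
                unique_peptides=unique,
                quantifiable=len(unique) >= min_peptides,
            )
        )
    groups.sort(key=lambda g: g.group_id)
    return groups


def unique_peptide_map(groups: list[ProteinGroup]) -> dict[str, str]:
    """Map each unique peptide to the group_id that owns it."""
    mapping: dict[str, str] = {}
    for group in groups:
        for pep in group.unique_peptides:
            mapping[pep] = group.group_id
    return mapping


def members_map(groups: list[ProteinGroup]) -> dict[str, frozenset[str]]:
    return {g.group_id: g.members for g in groups}


def groups_frame(groups: list[ProteinGroup]) -> pd.DataFrame:
    """Tabular view of the grouping, suitable for reporting."""
    return pd.DataFrame(
        {
            "group_id": [g.group_id for g in groups],
            "members": [";".join(sorted(g.members)) for g in groups],
            "n_peptides": [len(g.peptide_set) for g in groups],
            "n_unique": [len(g.unique_peptides) for g in groups],
            "quantifiable": [g.quantifiable for g in groups],
        }
    ).set_index("group_id")
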
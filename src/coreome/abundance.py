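"""Protein abundance estimators and nd-aware averaging.

Two estimators are provided, both computed over a group's *unique* peptides
measured in a sample:

``unique_sum``
    Sum of all unique-peptide abundances; used for *between-sample*
    comparison (enrichment ratios), where the same peptide universe is
    compared with itself across samples.

``top3``
    Sum of the three most abundant unique peptides (Hi-3).  Peptide ionisation
    response is roughly conserved for a protein's best responders, making the
    TOP3 value proportional to molar amount — so TOP3 values of *different*
    proteins in the same sample can be compared and turned into
    mass-contribution percentages.  With fewer than three measured peptides
    the available ones are summed and the group is flagged ``topN<3``.

"Not detected" (nd) entries are excluded from every mean, never imputed as
zero; a mean over all-nd values is itself nd.
"""

from __future__ import annotations

import warnings
from typing import Iterable

import numpy as np
import pandas as pd

from .errors import ConsistencyError
from .grouping import ProteinGroup, unique_peptide_map
from .io_tables import SAMPLE_COLUMNS

MODES = ("unique_sum", "top3")


def _measured(table: pd.DataFrame) -> pd.DataFrame:
    return table.dropna(subset=["abundance"])


def sample_totals(table: pd.DataFrame) -> pd.Series:
    """Summed measured peptide abundance per sample (every peptide counts:
    shared, non-quantifiable and ungrouped peptides included)."""
    return _measured(table).groupby(SAMPLE_COLUMNS)["abundance"].sum()


def protein_abundance(
    table: pd.DataFrame,
    group: ProteinGroup,
    sample: tuple[str, int, int],
    mode: str = "unique_sum",
) -> float:
    """Abundance of one group in one sample, or NaN if no unique peptide is
    measured there.  ``sample`` is (fraction, experiment, replicate)."""
    if mode not in MODES:
        raise ValueError(f"unknown mode {mode!r}")
    if not group.quantifiable:
        warnings.warn(f"group {group.group_id} is not quantifiable", stacklevel=2)
    frac, exp, rep = sample
    rows = _measured(table)
    mask = (
        rows["peptide_id"].isin(group.unique_peptides)
        & (rows["fraction"] == frac)
        & (rows["experiment"] == exp)
        & (rows["replicate"] == rep)
    )
    values = np.sort(rows.loc[mask, "abundance"].to_numpy())[::-1]
    if values.size == 0:
        return np.nan
    if mode == "top3":
        values = values[:3]
    return float(values.sum())


def abundance_matrix(
    table: pd.DataFrame,
    groups: Iterable[ProteinGroup],
    mode: str = "unique_sum",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Group × sample abundance matrix plus the per-cell unique-peptide count.

    Non-quantifiable groups are skipped (with a warning).  Columns are a
    MultiIndex over (fraction, experiment, replicate) covering every sample
    present in the table; cells with no measured unique peptide are NaN.
    """
    if mode not in MODES:
        raise ValueError(f"unknown mode {mode!r}")
    groups = list(groups)
    skipped = [g.group_id for g in groups if not g.quantifiable]
    if skipped:
        warnings.warn(
            f"skipping {len(skipped)} non-quantifiable group(s): {skipped[:5]}",
            stacklevel=2,
        )
    quant = [g for g in groups if g.quantifiable]
    pep_to_group = unique_peptide_map(quant)

    measured = _measured(table)
    samples = pd.MultiIndex.from_frame(
        table[SAMPLE_COLUMNS].drop_duplicates().sort_values(SAMPLE_COLUMNS)
    )
    sub = measured[measured["peptide_id"].isin(pep_to_group)].copy()
    sub["group_id"] = sub["peptide_id"].map(pep_to_group)
    if mode == "top3":
        sub = (
            sub.sort_values("abundance", ascending=False)
            .groupby(["group_id", *SAMPLE_COLUMNS], sort=False)
            .head(3)
        )
    index = pd.Index(sorted(g.group_id for g in quant), name="group_id")
    if sub.empty:
        empty = pd.DataFrame(np.nan, index=index, columns=samples)
        return empty, empty.copy()
    agg = sub.groupby(["group_id", *SAMPLE_COLUMNS])["abundance"].agg(["sum", "count"])
    matrix = agg["sum"].unstack(SAMPLE_COLUMNS).reindex(index=index, columns=samples)
    counts = agg["count"].unstack(SAMPLE_COLUMNS).reindex(index=index, columns=samples)
    return matrix, counts


def relative_abundance(
    table: pd.DataFrame,
    groups: Iterable[ProteinGroup],
    mode: str = "unique_sum",
) -> pd.DataFrame:
    """Relative normalized abundance r(group, sample) ∈ [0, 1].

    The numerator is the group's abundance (per ``mode``); the denominator is
    the summed abundance of *all* measured peptides in the sample, so the sum
    of r over groups never exceeds 1.  A sample with no measured peptide at
    all raises :class:`ConsistencyError` naming the sample.
    """
    matrix, _ = abundance_matrix(table, groups, mode)
    totals = sample_totals(table).reindex(matrix.columns)
    empty = totals.index[totals.isna() | (totals == 0)]
    if len(empty):
        raise ConsistencyError(f"sample(s) with no measured peptide: {list(empty)}")
    return matrix.div(totals, axis=1)


def average_over_replicates(values: Iterable[float]) -> float:
    """Arithmetic mean over non-nd replicates; nd if every replicate is nd."""
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0 or np.isnan(arr).all():
        return np.nan
    return float(np.nanmean(arr))


def average_over_experiments(values: Iterable[float]) -> float:
    """Arithmetic mean over non-nd experiments (same rule as replicates)."""
    return average_over_replicates(values)


def replicate_means(rel: pd.DataFrame) -> pd.DataFrame:
    """Average a group × sample matrix over replicates, nd-aware.

    Returns a group × (fraction, experiment) matrix; a (fraction, experiment)
    cell is nd when the group was nd in every replicate.
    """
    return rel.T.groupby(level=["fraction", "experiment"]).mean().T


def mass_contribution(averages: pd.Series) -> pd.Series:
    """Percent of the summed defined averages; nd averages get nd percent."""
    arr = averages.astype(float)
    total = np.nansum(arr.to_numpy())
    if not np.isfinite(total) or total <= 0 or arr.isna().all():
        raise ConsistencyError("no group has a defined average abundance")
    return 100.0 * arr / total


def top3_summary(
    table: pd.DataFrame,
    groups: Iterable[ProteinGroup],
    target_fraction: str = "LD",
    restrict_to: Iterable[str] | None = None,
    convention: str = "percent_of_averages",
) -> pd.DataFrame:
    """Per-group TOP3 abundance in the target fraction and mass contributions.

    Columns: ``top3_exp<e>`` (replicate-averaged TOP3 per experiment, nd
    aware), ``average`` (mean over experiments excluding nd),
    ``mass_contribution_pct`` and ``topn_flag`` (``topN<3`` when any
    contributing sample used fewer than 3 peptides).

    ``convention`` selects how percentages are formed:

    - ``percent_of_averages`` (default): each group's experiment-averaged
      TOP3 divided by the sum of those averages;
    - ``average_of_percentages``: the per-sample percentage (TOP3 of the
      group over summed TOP3 of all groups in that sample) averaged over
      replicates then experiments.
    """
    if convention not in ("percent_of_averages", "average_of_percentages"):
        raise ValueError(f"unknown convention {convention!r}")
    matrix, counts = abundance_matrix(table, groups, mode="top3")
    in_target = [c for c in matrix.columns if c[0] == target_fraction]
    matrix = matrix[in_target]
    counts = counts[in_target]
    if restrict_to is not None:
        keep = [g for g in matrix.index if g in set(restrict_to)]
        matrix = matrix.loc[keep]
        counts = counts.loc[keep]
    if matrix.empty:
        cols = ["average", "mass_contribution_pct", "topn_flag"]
        return pd.DataFrame(columns=cols, index=pd.Index([], name="group_id"))

    per_exp = matrix.T.groupby(level="experiment").mean().T
    summary = per_exp.copy()
    summary.columns = [f"top3_exp{e}" for e in per_exp.columns]
    summary["average"] = per_exp.mean(axis=1)

    if convention == "percent_of_averages":
        summary["mass_contribution_pct"] = mass_contribution(summary["average"])
    else:
        per_sample_pct = 100.0 * matrix.div(matrix.sum(axis=0), axis=1)
        pct_per_exp = per_sample_pct.T.groupby(level="experiment").mean().T
        summary["mass_contribution_pct"] = pct_per_exp.mean(axis=1)

    low_n = (counts < 3) & counts.notna()
    summary["topn_flag"] = np.where(low_n.any(axis=1), "topN<3", "")
    return summary.sort_values("mass_contribution_pct", ascending=False)
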
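"""Enrichment ratios and the multi-criteria core-proteome filter.

For every protein group and every independent experiment, the enrichment
ratio against a reference fraction is the quotient of replicate-averaged
relative normalized abundances::

    E_ref(g, e) = r̄_target(g, e) / r̄_ref(g, e)

A group absent from the target fraction (r̄_target nd) has an nd ratio.  A
group present in the target but absent from (or zero in) the reference gets
the infinite marker (``inf``): absence from a reference fraction is maximal
enrichment evidence, so the marker passes every threshold.

The core-proteome call applies, per experiment,

1. target/total ratio strictly above ``t_total`` (default 6), and
2. target/soluble and target/membrane ratios not below ``t_soluble`` /
   ``t_membrane`` (default 1.5; a ratio exactly at the threshold is kept —
   only strictly smaller values are discarded),

requires the per-experiment criteria to hold in at least ``k_required`` of
the experiments (default 2 of 3), and finally discards groups whose
target/contaminant ratio stays below ``t_contaminant`` (default 4) in every
experiment where it is available, as well as groups on the prior-localization
exclusion list.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, NamedTuple

import numpy as np
import pandas as pd

from .errors import CalibrationError, ConfigurationError
from .io_tables import AnnotationLists

logger = logging.getLogger(__name__)

#: Output status labels, in report order.
STATUSES = ("core", "excluded_contaminant", "excluded_prior", "fail_experiments")


@dataclass(frozen=True)
class FilterCriteria:
    """Thresholds and k-of-n rule of the core-proteome call.

    ``t_total`` is strict (ratio must exceed it); ``t_soluble``,
    ``t_membrane`` and ``t_contaminant`` are non-strict keeps (a ratio equal
    to the threshold survives).
    """

    t_total: float = 6.0
    t_soluble: float = 1.5
    t_membrane: float = 1.5
    t_contaminant: float = 4.0
    k_required: int = 2
    n_experiments: int = 3

    def __post_init__(self) -> None:
        for name in ("t_total", "t_soluble", "t_membrane", "t_contaminant"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be > 0, got {getattr(self, name)}")
        if not 1 <= self.k_required <= self.n_experiments:
            raise ConfigurationError(
                f"k_required must satisfy 1 <= k_required <= n_experiments, "
                f"got k_required={self.k_required}, n_experiments={self.n_experiments}"
            )


class FractionRoles(NamedTuple):
    """Which fraction label plays which role in the filter."""

    target: str = "LD"
    soluble: str = "SOL"
    membrane: str = "MEM"
    total: str = "TL"
    contaminant: str = "PG"


def ratio_column(target: str, reference: str) -> str:
    return f"{target}/{reference}"


def enrichment_ratios(
    rel: pd.DataFrame,
    target: str = "LD",
    references: Iterable[str] = ("SOL", "MEM", "TL", "PG"),
    method: str = "average_then_ratio",
) -> pd.DataFrame:
    """Per-experiment enrichment ratios from a group × sample relative matrix.

    ``rel`` has a (fraction, experiment, replicate) column MultiIndex as
    produced by :func:`coreome.abundance.relative_abundance`.  The default
    ``average_then_ratio`` averages relative abundances over replicates and
    then forms the ratio; ``ratio_then_average`` forms per-replicate ratios
    (pairing replicate i of the target with replicate i of the reference) and
    averages those.  Ratios for a reference are emitted only in experiments
    where that reference fraction was measured; experiments without a target
    sample have all ratios nd.

    Returns a frame indexed by (group_id, experiment) with one column per
    ``target/reference`` ratio.
    """
    if method not in ("average_then_ratio", "ratio_then_average"):
        raise ValueError(f"unknown method {method!r}")
    experiments = sorted(rel.columns.get_level_values("experiment").unique())
    fractions = set(rel.columns.get_level_values("fraction").unique())
    references = [r for r in references if r != target]

    index = pd.MultiIndex.from_product(
        [rel.index, experiments], names=["group_id", "experiment"]
    )
    out = pd.DataFrame(index=index, columns=[ratio_column(target, r) for r in references], dtype=float)

    rbar = rel.T.groupby(level=["fraction", "experiment"]).mean().T
    for exp in experiments:
        has_target = target in fractions and (target, exp) in rbar.columns
        for ref in references:
            col = ratio_column(target, ref)
            if not has_target or (ref, exp) not in rbar.columns:
                continue  # stays NaN: no target sample, or reference absent in this experiment
            if method == "average_then_ratio":
                num = rbar[(target, exp)].to_numpy(dtype=float)
                den = rbar[(ref, exp)].to_numpy(dtype=float)
                values = _safe_ratio(num, den)
            else:
                t_cols = [c for c in rel.columns if c[0] == target and c[1] == exp]
                ratios = []
                for (_, _, rep) in t_cols:
                    r_col = (ref, exp, rep)
                    if r_col not in rel.columns:
                        continue
                    ratios.append(
                        _safe_ratio(
                            rel[(target, exp, rep)].to_numpy(dtype=float),
                            rel[r_col].to_numpy(dtype=float),
                        )
                    )
                if not ratios:
                    continue
                stacked = np.vstack(ratios)
                with np.errstate(invalid="ignore"):
                    values = np.where(
                        np.isnan(stacked).all(axis=0), np.nan, np.nanmean(stacked, axis=0)
                    )
            out.loc[(slice(None), exp), col] = np.asarray(values, dtype=float)
    n_inf = int(np.isinf(out.to_numpy(dtype=float)).sum())
    if n_inf:
        logger.info("%d enrichment ratio(s) with absent reference marked infinite", n_inf)
    return out


def _safe_ratio(num: np.ndarray, den: np.ndarray) -> np.ndarray:
    """Elementwise num/den with nd/zero semantics: nd numerator → nd; zero or
    nd denominator with positive numerator → inf."""
    out = np.full(num.shape, np.nan)
    ref_absent = np.isnan(den) | (den == 0)
    ok = ~np.isnan(num) & ~ref_absent
    out[ok] = num[ok] / den[ok]
    out[~np.isnan(num) & (num > 0) & ref_absent] = np.inf
    out[~np.isnan(num) & (num == 0) & np.isnan(den)] = np.nan
    out[~np.isnan(num) & (num == 0) & (den == 0)] = np.nan
    return out


def passes_experiment(
    profiles: pd.DataFrame,
    criteria: FilterCriteria,
    roles: FractionRoles = FractionRoles(),
) -> pd.Series:
    """Per-(group, experiment) boolean: do the per-experiment criteria hold?

    True iff target/total > ``t_total`` AND target/soluble ≥ ``t_soluble``
    AND target/membrane ≥ ``t_membrane``.  The infinite marker passes any
    threshold; nd fails (NaN comparisons are False).
    """
    e_tl = profiles[ratio_column(roles.target, roles.total)]
    e_s = profiles[ratio_column(roles.target, roles.soluble)]
    e_mb = profiles[ratio_column(roles.target, roles.membrane)]
    return (e_tl > criteria.t_total) & (e_s >= criteria.t_soluble) & (e_mb >= criteria.t_membrane)


def call_core_proteome(
    profiles: pd.DataFrame,
    criteria: FilterCriteria,
    annotations: AnnotationLists | None = None,
    members: Mapping[str, Iterable[str]] | None = None,
    roles: FractionRoles = FractionRoles(),
) -> pd.DataFrame:
    """Apply the k-of-n rule, the contaminant-ratio cutoff and the prior
    exclusion list; return one row per group.

    ``profiles`` is indexed by (group_id, experiment) as produced by
    :func:`enrichment_ratios`.  ``members`` maps group_id to its accessions
    for matching the annotation lists (defaults to the group_id alone).

    Columns: ``pass_exp<e>`` flags, ``n_pass``, ``contaminant_flag``
    (every *available* target/contaminant ratio below ``t_contaminant``; no
    available ratio ⇒ False), ``prior_exclusion_flag`` and ``status``.
    Output is deterministically ordered by group_id.
    """
    annotations = annotations or AnnotationLists()
    experiments = sorted(profiles.index.get_level_values("experiment").unique())
    if criteria.k_required > len(experiments):
        raise ConfigurationError(
            f"k_required={criteria.k_required} exceeds the {len(experiments)} "
            f"experiment(s) present in the profiles"
        )
    passes = passes_experiment(profiles, criteria, roles).unstack("experiment")
    result = pd.DataFrame(index=passes.index.rename("group_id"))
    for exp in experiments:
        result[f"pass_exp{exp}"] = passes[exp].astype(bool)
    result["n_pass"] = passes.sum(axis=1).astype(int)

    pg_col = ratio_column(roles.target, roles.contaminant)
    if pg_col in profiles.columns:
        e_pg = profiles[pg_col].unstack("experiment")
        available = e_pg.notna()
        below = (e_pg < criteria.t_contaminant) & available
        result["contaminant_flag"] = available.any(axis=1) & (
            below.sum(axis=1) == available.sum(axis=1)
        )
    else:
        result["contaminant_flag"] = False

    def _is_prior(gid: str) -> bool:
        accs = set(members[gid]) if members and gid in members else {gid}
        return bool(accs & set(annotations.prior_exclusions))

    result["prior_exclusion_flag"] = [_is_prior(g) for g in result.index]

    status = np.where(
        result["n_pass"] < criteria.k_required,
        "fail_experiments",
        np.where(
            result["contaminant_flag"],
            "excluded_contaminant",
            np.where(result["prior_exclusion_flag"], "excluded_prior", "core"),
        ),
    )
    result["status"] = status
    result = result.sort_index()
    counts = result["status"].value_counts()
    logger.info(
        "%d core / %d excluded_contaminant / %d excluded_prior / %d fail_experiments",
        counts.get("core", 0),
        counts.get("excluded_contaminant", 0),
        counts.get("excluded_prior", 0),
        counts.get("fail_experiments", 0),
    )
    return result


class CalibrationResult(NamedTuple):
    threshold: float
    max_ratio: float
    group_id: str


def calibrate_contaminant_threshold(
    profiles: pd.DataFrame,
    contaminant_reference: Iterable[str],
    margin: float = 0.01,
    members: Mapping[str, Iterable[str]] | None = None,
    roles: FractionRoles = FractionRoles(),
) -> CalibrationResult:
    """Derive the contaminant-ratio cutoff from known contaminant proteins.

    The highest finite target/contaminant ratio observed among reference
    contaminants, rounded at ``margin`` granularity, is pushed up to the next
    integer step: a maximum of 3.99 yields 4.0.  The strictly-greater step
    guarantees the returned threshold excludes every reference contaminant
    (exclusion being ratio < threshold), including references at 0.

    Raises :class:`CalibrationError` when no reference contaminant has a
    finite ratio; callers should then fall back to the configured default.
    """
    reference = set(contaminant_reference)
    if not reference:
        raise CalibrationError("empty contaminant reference set")
    pg_col = ratio_column(roles.target, roles.contaminant)
    if pg_col not in profiles.columns:
        raise CalibrationError(f"profiles carry no {pg_col} ratio")

    best_value = -np.inf
    best_group = ""
    for gid in profiles.index.get_level_values("group_id").unique():
        accs = set(members[gid]) if members and gid in members else {gid}
        if not accs & reference:
            continue
        values = profiles.loc[gid, pg_col].to_numpy(dtype=float)
        values = values[np.isfinite(values)]
        if values.size and values.max() > best_value:
            best_value = float(values.max())
            best_group = gid
    if not np.isfinite(best_value):
        raise CalibrationError("no reference contaminant with a finite ratio")
    rounded = round(best_value / margin) * margin
    threshold = float(math.floor(rounded + 1e-12) + 1.0)
    logger.info(
        "calibrated contaminant threshold %.2f (max reference ratio %.2f, %s)",
        threshold,
        best_value,
        best_group,
    )
    return CalibrationResult(threshold, best_value, best_group)
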
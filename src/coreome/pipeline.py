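"""End-to-end orchestration: read → group → quantify → ratios → filter → report.

The full procedure mirrors how an organelle core proteome is called from
subcellular-fraction peptide data:

1. read and validate the long-format peptide table;
2. group accessions with identical peptide evidence, mark quantifiable
   groups (≥ 2 unique peptides);
3. compute relative normalized abundances (unique-peptide sums over the
   per-sample total peptide signal) for between-sample comparison;
4. average over technical replicates, form per-experiment enrichment ratios
   of the target fraction over every reference fraction;
5. apply the multi-criteria filter (k-of-n rule, contaminant-ratio cutoff,
   prior-localization exclusions);
6. in parallel, estimate within-sample abundance of the core members by
   TOP3 and convert to mass-contribution percentages.

A profile-injection entry point (:func:`run_from_profiles`) accepts
precomputed enrichment-ratio tables, so published ratio tables can be
re-filtered without the underlying peptide data.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from . import __version__
from .abundance import relative_abundance, top3_summary
from .enrichment import (
    CalibrationResult,
    FilterCriteria,
    FractionRoles,
    calibrate_contaminant_threshold,
    call_core_proteome,
    enrichment_ratios,
)
from .errors import CalibrationError, CoreomeError, PipelineError
from .grouping import ProteinGroup, build_groups, groups_frame, members_map
from .io_tables import (
    DEFAULT_FRACTIONS,
    AnnotationLists,
    read_annotation_lists,
    read_peptide_table,
    write_core_report,
)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Everything one end-to-end run needs."""

    table_path: str | Path = ""
    out_dir: str | Path = "coreome_out"
    fraction_set: tuple[str, ...] = DEFAULT_FRACTIONS
    roles: FractionRoles = FractionRoles()
    criteria: FilterCriteria = field(default_factory=FilterCriteria)
    contaminant_path: str | Path | None = None
    exclusions_path: str | Path | None = None
    category_path: str | Path | None = None
    min_peptides: int = 2
    mass_convention: str = "percent_of_averages"
    ratio_method: str = "average_then_ratio"
    calibrate_threshold: bool = False
    dialect: str = "long_tsv"

    def __post_init__(self) -> None:
        if self.roles.target not in self.fraction_set:
            raise PipelineError(
                f"target fraction {self.roles.target!r} not in fraction set {self.fraction_set}"
            )

    def config_hash(self) -> str:
        # out_dir is excluded: it does not affect the analysis
        fields = {k: str(v) for k, v in sorted(vars(self).items()) if k != "out_dir"}
        payload = json.dumps(fields, sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]


@dataclass
class AnalysisResult:
    """In-memory results of every pipeline stage."""

    groups: list[ProteinGroup]
    relative: pd.DataFrame
    profiles: pd.DataFrame
    result: pd.DataFrame
    top3: pd.DataFrame
    criteria: FilterCriteria
    calibration: CalibrationResult | None = None

    @property
    def core_ids(self) -> list[str]:
        return list(self.result.index[self.result["status"] == "core"])

    def status_counts(self) -> dict[str, int]:
        counts = self.result["status"].value_counts().to_dict()
        return {
            s: int(counts.get(s, 0))
            for s in ("core", "excluded_contaminant", "excluded_prior", "fail_experiments")
        }


def _stage(name: str):
    """Decorator-free stage wrapper: re-raise with the stage name attached."""

    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, PipelineError):
                raise PipelineError(f"stage '{name}': {exc}") from exc
            return False

    return _Ctx()


def run_analysis(
    table: pd.DataFrame,
    annotations: AnnotationLists | None = None,
    criteria: FilterCriteria | None = None,
    roles: FractionRoles = FractionRoles(),
    min_peptides: int = 2,
    mass_convention: str = "percent_of_averages",
    ratio_method: str = "average_then_ratio",
    calibrate_threshold: bool = False,
) -> AnalysisResult:
    """Run the full analysis on an in-memory peptide table."""
    annotations = annotations or AnnotationLists()
    criteria = criteria or FilterCriteria()
    references = [f for f in dict.fromkeys(table["fraction"]) if f != roles.target]

    with _stage("grouping"):
        groups = build_groups(table, min_peptides=min_peptides)
    with _stage("relative_abundance"):
        rel = relative_abundance(table, groups, mode="unique_sum")
    with _stage("enrichment_ratios"):
        profiles = enrichment_ratios(rel, roles.target, references, method=ratio_method)

    calibration = None
    if calibrate_threshold and annotations.contaminant_reference:
        with _stage("calibration"):
            try:
                calibration = calibrate_contaminant_threshold(
                    profiles,
                    annotations.contaminant_reference,
                    members=members_map(groups),
                    roles=roles,
                )
                criteria = FilterCriteria(
                    t_total=criteria.t_total,
                    t_soluble=criteria.t_soluble,
                    t_membrane=criteria.t_membrane,
                    t_contaminant=calibration.threshold,
                    k_required=criteria.k_required,
                    n_experiments=criteria.n_experiments,
                )
            except CalibrationError as exc:
                logger.warning("calibration failed (%s); keeping t_contaminant=%s",
                               exc, criteria.t_contaminant)

    with _stage("core_proteome_call"):
        result = call_core_proteome(
            profiles, criteria, annotations, members=members_map(groups), roles=roles
        )
    with _stage("top3_summary"):
        core = list(result.index[result["status"] == "core"])
        top3 = top3_summary(
            table, groups, roles.target, restrict_to=core, convention=mass_convention
        )
    return AnalysisResult(groups, rel, profiles, result, top3, criteria, calibration)


def run_pipeline(config: PipelineConfig) -> AnalysisResult:
    """File-to-file end-to-end run: reads inputs, persists every intermediate
    table, the two reports and a machine-readable run summary."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    with _stage("read_peptide_table"):
        table = read_peptide_table(config.table_path, config.fraction_set, config.dialect)
    with _stage("read_annotations"):
        annotations = read_annotation_lists(
            config.contaminant_path, config.exclusions_path, config.category_path
        )
    analysis = run_analysis(
        table,
        annotations,
        config.criteria,
        roles=config.roles,
        min_peptides=config.min_peptides,
        mass_convention=config.mass_convention,
        ratio_method=config.ratio_method,
        calibrate_threshold=config.calibrate_threshold,
    )
    with _stage("write_reports"):
        groups_frame(analysis.groups).to_csv(out_dir / "groups.tsv", sep="\t")
        rel_out = analysis.relative.copy()
        rel_out.columns = [f"{f}.{e}.{r}" for f, e, r in rel_out.columns]
        rel_out.to_csv(out_dir / "relative_abundance.tsv", sep="\t")
        profiles_out = analysis.profiles.reset_index()
        profiles_out.to_csv(out_dir / "enrichment_profiles.tsv", sep="\t", index=False)
        write_core_report(analysis.result, analysis.top3, out_dir, analysis.profiles)
        summary = {
            "version": __version__,
            "config_hash": config.config_hash(),
            "n_groups": len(analysis.groups),
            "n_quantifiable": sum(g.quantifiable for g in analysis.groups),
            "status_counts": analysis.status_counts(),
            "criteria": vars(analysis.criteria) | {},
            "calibration": (
                analysis.calibration._asdict() if analysis.calibration else None
            ),
        }
        with open(out_dir / "run_summary.json", "w", encoding="utf-8") as handle:
            json.dump(summary, handle, indent=2, sort_keys=True)
            handle.write("\n")
    counts = analysis.status_counts()
    logger.info(
        "%(core)d core / %(excluded_contaminant)d excluded_contaminant / "
        "%(excluded_prior)d excluded_prior / %(fail_experiments)d fail_experiments",
        counts,
    )
    return analysis


def run_from_profiles(
    profiles: pd.DataFrame,
    criteria: FilterCriteria | None = None,
    annotations: AnnotationLists | None = None,
    members: Mapping[str, Iterable[str]] | None = None,
    roles: FractionRoles = FractionRoles(),
) -> pd.DataFrame:
    """Profile-injection entry point: filter precomputed enrichment ratios."""
    return call_core_proteome(
        profiles, criteria or FilterCriteria(), annotations, members=members, roles=roles
    )


def summarize_top_proteins(top3: pd.DataFrame, n: int) -> pd.DataFrame:
    """Top-n groups by mass contribution, with the cumulative percentage."""
    defined = top3.dropna(subset=["mass_contribution_pct"])
    if defined.empty:
        raise CoreomeError("no group has a defined mass contribution")
    ranked = defined.sort_values("mass_contribution_pct", ascending=False).head(n)
    out = ranked[["average", "mass_contribution_pct"]].copy()
    out["cumulative_pct"] = out["mass_contribution_pct"].cumsum()
    return out


def fold_difference(top3: pd.DataFrame, group_a: str, group_b: str) -> float:
    """Ratio of experiment-averaged TOP3 abundances of two groups."""
    for gid in (group_a, group_b):
        if gid not in top3.index or not np.isfinite(top3.loc[gid, "average"]):
            raise CoreomeError(f"group {gid} has no defined average abundance")
        if top3.loc[gid, "average"] <= 0:
            raise CoreomeError(f"group {gid} has a non-positive average abundance")
    return float(top3.loc[group_a, "average"] / top3.loc[group_b, "average"])


def evaluate_recovery(
    result: pd.DataFrame,
    truth: pd.DataFrame,
    members: Mapping[str, Iterable[str]],
) -> tuple[float, float]:
    """(recall, precision) of the core call against per-accession ground truth.

    A group counts as truly core when all its member accessions are flagged
    ``is_true_core``.
    """
    flag = dict(zip(truth["accession"], truth["is_true_core"]))
    true_core = {
        gid for gid, accs in members.items() if accs and all(flag.get(a, False) for a in accs)
    }
    called = set(result.index[result["status"] == "core"])
    recall = len(called & true_core) / len(true_core) if true_core else float("nan")
    precision = len(called & true_core) / len(called) if called else float("nan")
    return recall, precision


def plot_contributions(top3: pd.DataFrame, path: str | Path, n: int = 20) -> Path:
    """Ranked mass-contribution bar chart (the only plot this package makes)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    ranked = top3.dropna(subset=["mass_contribution_pct"]).sort_values(
        "mass_contribution_pct", ascending=False
    ).head(n)
    fig, ax = plt.subplots(figsize=(8, 4))
    ax.bar(range(len(ranked)), ranked["mass_contribution_pct"])
    ax.set_xticks(range(len(ranked)))
    ax.set_xticklabels(ranked.index, rotation=90, fontsize=7)
    ax.set_ylabel("mass contribution (%)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)
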
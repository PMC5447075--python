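"""Synthetic peptide-level quantification data with known ground truth.

The generator emulates a subcellular-fractionation label-free experiment:
five fractions (lipid droplet LD, soluble SOL, membrane MEM, total leaf TL,
plastoglobule PG), three independent experiments with three technical
replicates each, the contaminant-organelle (PG) fraction being purified in
one experiment only.  Every protein belongs to a class (LD resident, PG
contaminant, soluble/membrane background, plastid-annotated) whose
``fraction_means`` set its expected abundance per fraction on the linear
scale.

Measurement model, per peptide j of protein p in sample s::

    a_{j,s} = fraction_mean_p(fraction(s)) × ρ_j × exp(ε_{j,s})

where ρ_j = exp(N(0, response_sigma²)) is a peptide-specific response factor
drawn once and reused in every sample (the premise of TOP3 quantification is
that peptide response is sample-invariant), and ε is i.i.d. Gaussian
log-scale replicate noise.  Measurements below ``detection_limit`` are
left-censored to nd.  ``shared_peptide_pairs`` protein pairs are given
identical peptide sets so the grouping stage has work to do.

All randomness flows from ``config.seed`` through per-protein sub-streams,
so a given seed yields a byte-identical table even if protein order changes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .io_tables import (
    ACCESSION_SEP,
    DEFAULT_FRACTIONS,
    TABLE_COLUMNS,
    AnnotationLists,
    write_peptide_table,
)


@dataclass(frozen=True)
class ProteinClassSpec:
    """One class of simulated proteins with a common abundance profile.

    ``fraction_means`` maps every fraction label to the expected
    protein-level abundance (linear scale, strictly positive);
    ``is_true_core`` marks the class as genuinely resident in the target
    fraction — the ground truth recovery tests score against.
    """

    class_name: str
    n_proteins: int
    fraction_means: Mapping[str, float]
    is_true_core: bool = False

    def validate(self, fractions: Sequence[str]) -> None:
        if self.n_proteins < 1:
            raise ConfigurationError(f"class_specs[{self.class_name}].n_proteins must be >= 1")
        for frac in fractions:
            mean = self.fraction_means.get(frac)
            if mean is None:
                raise ConfigurationError(
                    f"class_specs[{self.class_name}].fraction_means misses fraction {frac!r}"
                )
            if not mean > 0:
                raise ConfigurationError(
                    f"class_specs[{self.class_name}].fraction_means[{frac!r}] must be > 0"
                )


def default_class_specs() -> list[ProteinClassSpec]:
    """A 25-protein, five-class scenario with unambiguous ground truth.

    LD residents are ≥ 50× enriched over every reference fraction in the
    realized relative abundances (per-fraction totals are of comparable
    magnitude); PG contaminants sit well below the contaminant cutoff
    (LD/PG ≈ 0.07); plastid-annotated proteins show an LD-enriched profile
    but are flagged for prior-localization exclusion; the two background
    classes dominate the soluble/membrane/total-leaf fractions the way
    abundant cytosolic and membrane proteins dominate a leaf extract.
    """
    return [
        ProteinClassSpec(
            "ld_resident",
            5,
            {"LD": 1e5, "SOL": 500.0, "MEM": 500.0, "TL": 500.0, "PG": 500.0},
            is_true_core=True,
        ),
        ProteinClassSpec(
            "pg_contaminant",
            5,
            {"LD": 1e4, "SOL": 1e3, "MEM": 1e3, "TL": 1e3, "PG": 1e5},
        ),
        ProteinClassSpec(
            "soluble_background",
            5,
            {"LD": 200.0, "SOL": 1e5, "MEM": 5e3, "TL": 5e4, "PG": 1e3},
        ),
        ProteinClassSpec(
            "membrane_background",
            5,
            {"LD": 200.0, "SOL": 5e3, "MEM": 1e5, "TL": 5e4, "PG": 1e3},
        ),
        ProteinClassSpec(
            "plastid_annotated",
            5,
            {"LD": 5e4, "SOL": 500.0, "MEM": 500.0, "TL": 500.0, "PG": 2e3},
        ),
    ]


@dataclass(frozen=True)
class SyntheticConfig:
    """Design and noise parameters of the simulated dataset.

    Defaults reproduce the study design the analysis assumes: 3 independent
    experiments × 3 technical replicates over 5 fractions, with the
    contaminant (PG) fraction present in experiment 3 only.
    """

    n_experiments: int = 3
    n_replicates: int = 3
    fractions: Sequence[str] = DEFAULT_FRACTIONS
    pg_experiments: Sequence[int] = (3,)
    class_specs: Sequence[ProteinClassSpec] = field(default_factory=default_class_specs)
    peptide_count_range: tuple[int, int] = (2, 12)
    response_sigma: float = 0.5
    noise_sigma: float = 0.2
    detection_limit: float = 100.0
    shared_peptide_pairs: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_experiments < 1:
            raise ConfigurationError(f"n_experiments must be >= 1, got {self.n_experiments}")
        if self.n_replicates < 1:
            raise ConfigurationError(f"n_replicates must be >= 1, got {self.n_replicates}")
        if self.detection_limit < 0:
            raise ConfigurationError(f"detection_limit must be >= 0, got {self.detection_limit}")
        if self.response_sigma < 0:
            raise ConfigurationError(f"response_sigma must be >= 0, got {self.response_sigma}")
        if self.noise_sigma < 0:
            raise ConfigurationError(f"noise_sigma must be >= 0, got {self.noise_sigma}")
        lo, hi = self.peptide_count_range
        if not 1 <= lo <= hi:
            raise ConfigurationError(
                f"peptide_count_range must satisfy 1 <= lo <= hi, got {self.peptide_count_range}"
            )
        bad = [e for e in self.pg_experiments if not 1 <= e <= self.n_experiments]
        if bad:
            raise ConfigurationError(f"pg_experiments outside 1..n_experiments: {bad}")
        if self.shared_peptide_pairs < 0:
            raise ConfigurationError(
                f"shared_peptide_pairs must be >= 0, got {self.shared_peptide_pairs}"
            )
        for spec in self.class_specs:
            spec.validate(self.fractions)
        if self.shared_peptide_pairs > sum(s.n_proteins // 2 for s in self.class_specs):
            raise ConfigurationError(
                "shared_peptide_pairs exceeds the number of same-class protein pairs"
            )


def censor_to_nd(abundance: float, limit: float) -> float:
    """Left-censor a measurement: nd (NaN) when below the detection limit.

    A value exactly at the limit is kept; ``limit=0`` is the identity.
    """
    if abundance < 0:
        raise ValueError(f"abundance must be >= 0, got {abundance}")
    if limit < 0:
        raise ValueError(f"limit must be >= 0, got {limit}")
    return np.nan if abundance < limit else abundance


def _class_abbrev(class_name: str) -> str:
    return "".join(word[0] for word in class_name.split("_")).upper()


def _protein_roster(config: SyntheticConfig) -> list[tuple[str, ProteinClassSpec, str | None]]:
    """(accession, class spec, shared-partner accession or None) per protein.

    The first ``shared_peptide_pairs`` same-class adjacent pairs share one
    peptide set; the second member of a pair carries its partner's accession
    and is not simulated separately.
    """
    roster: list[tuple[str, ProteinClassSpec, str | None]] = []
    pairs_left = config.shared_peptide_pairs
    for ci, spec in enumerate(config.class_specs):
        accs = [f"{_class_abbrev(spec.class_name)}{ci}{i:03d}" for i in range(spec.n_proteins)]
        i = 0
        while i < spec.n_proteins:
            if pairs_left > 0 and i + 1 < spec.n_proteins:
                roster.append((accs[i], spec, accs[i + 1]))
                pairs_left -= 1
                i += 2
            else:
                roster.append((accs[i], spec, None))
                i += 1
    return roster


def _samples(config: SyntheticConfig) -> list[tuple[str, int, int]]:
    pg_exps = set(config.pg_experiments)
    samples = []
    for frac in config.fractions:
        for exp in range(1, config.n_experiments + 1):
            if frac == "PG" and exp not in pg_exps:
                continue
            for rep in range(1, config.n_replicates + 1):
                samples.append((frac, exp, rep))
    return samples


def simulate_dataset(config: SyntheticConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a peptide quantification table and its ground truth.

    Returns ``(table, truth)``: the long-format table (one row per peptide ×
    sample, nd entries as NaN) and a per-accession frame with columns
    ``class_name`` and ``is_true_core``.
    """
    samples = _samples(config)
    rows: list[tuple] = []
    truth_rows: list[tuple[str, str, bool]] = []
    lo, hi = config.peptide_count_range

    for pidx, (acc, spec, partner) in enumerate(_protein_roster(config)):
        rng = np.random.default_rng([config.seed, pidx])
        n_pep = int(rng.integers(lo, hi + 1))
        if config.response_sigma > 0:
            response = np.exp(rng.normal(0.0, config.response_sigma, n_pep))
        else:
            response = np.ones(n_pep)
        acc_cell = acc if partner is None else ACCESSION_SEP.join(sorted((acc, partner)))
        truth_rows.append((acc, spec.class_name, spec.is_true_core))
        if partner is not None:
            truth_rows.append((partner, spec.class_name, spec.is_true_core))
        noise = (
            rng.normal(0.0, config.noise_sigma, (len(samples), n_pep))
            if config.noise_sigma > 0
            else np.zeros((len(samples), n_pep))
        )
        for si, (frac, exp, rep) in enumerate(samples):
            mean = spec.fraction_means[frac]
            for j in range(n_pep):
                value = mean * response[j] * float(np.exp(noise[si, j]))
                rows.append(
                    (
                        f"{acc}_pep{j:02d}",
                        acc_cell,
                        frac,
                        exp,
                        rep,
                        censor_to_nd(value, config.detection_limit),
                    )
                )

    table = pd.DataFrame(rows, columns=TABLE_COLUMNS)
    truth = pd.DataFrame(truth_rows, columns=["accession", "class_name", "is_true_core"])
    truth = truth.sort_values("accession").reset_index(drop=True)
    return table, truth


def annotations_from_truth(truth: pd.DataFrame) -> AnnotationLists:
    """Build the annotation lists a real analysis would supply: known
    contaminant-organelle proteins and prior-localization exclusions."""
    contaminants = frozenset(truth.loc[truth["class_name"] == "pg_contaminant", "accession"])
    prior = frozenset(truth.loc[truth["class_name"] == "plastid_annotated", "accession"])
    return AnnotationLists(contaminant_reference=contaminants, prior_exclusions=prior)


def write_dataset(
    table: pd.DataFrame, truth: pd.DataFrame, out_dir: str | Path
) -> tuple[Path, Path]:
    """Write the peptide table and ground truth as TSVs."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    table_path = write_peptide_table(table, out_dir / "peptides.tsv")
    truth_path = out_dir / "ground_truth.tsv"
    truth.to_csv(truth_path, sep="\t", index=False)
    return table_path, truth_path


def noise_free(config: SyntheticConfig) -> SyntheticConfig:
    """The same design with all stochastic components switched off."""
    return replace(config, response_sigma=0.0, noise_sigma=0.0)
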
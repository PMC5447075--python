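"""Reading, validation and writing of peptide quantification tables.

The canonical interchange format is a long-format TSV (or CSV) with one row
per (peptide, sample) measurement::

    peptide_id  accessions  fraction  experiment  replicate  abundance

``accessions`` holds one or more protein accessions joined by ``;`` — a
peptide whose sequence occurs in several database entries lists them all.
``abundance`` is a non-negative number (scientific notation such as
``4.47E+04`` accepted) or a missing-value token.  "Not detected" (``nd``)
measurements are carried internally as ``NaN`` and written back as ``nd`` —
never coerced to zero, because a censored measurement carries different
information than a measured zero.

A wide "one column per run" dialect, as exported by typical label-free
quantification software, is accepted on read only (:func:`read_peptide_table_wide`).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import ConsistencyError, FormatError

logger = logging.getLogger(__name__)

#: Token written for a missing ("not detected") abundance.
ND_TOKEN = "nd"

#: Strings accepted as a missing abundance on read (case-insensitive).
ND_STRINGS = frozenset({"nd", "na", "n.d.", "n/a", ""})

#: Canonical column order of the long-format peptide table.
TABLE_COLUMNS = [
    "peptide_id",
    "accessions",
    "fraction",
    "experiment",
    "replicate",
    "abundance",
]

#: Columns identifying one sample (one LC-MS/MS run).
SAMPLE_COLUMNS = ["fraction", "experiment", "replicate"]

#: Separator joining accessions inside one cell.
ACCESSION_SEP = ";"

#: Default fraction labels: lipid droplet, soluble, membrane, total leaf,
#: plastoglobule.
DEFAULT_FRACTIONS = ("LD", "SOL", "MEM", "TL", "PG")


def parse_abundance(text: str) -> float:
    """Parse one abundance cell: a non-negative float or a missing token.

    Decimal point only (locale-independent); scientific notation accepted.
    """
    stripped = str(text).strip()
    if stripped.lower() in ND_STRINGS:
        return np.nan
    try:
        value = float(stripped)
    except ValueError as exc:
        raise FormatError(f"unparseable abundance {text!r}") from exc
    if value < 0:
        raise FormatError(f"negative abundance {value!r}")
    return value


def split_accessions(cell: str) -> frozenset[str]:
    accs = frozenset(a.strip() for a in str(cell).split(ACCESSION_SEP) if a.strip())
    if not accs:
        raise FormatError(f"empty accessions cell {cell!r}")
    return accs


def validate_peptide_table(table: pd.DataFrame, fraction_set: Iterable[str]) -> pd.DataFrame:
    """Validate a long-format table in place; return it for chaining.

    Raises :class:`FormatError` naming offending rows (1-based data rows) for
    duplicate (peptide, sample) keys, unknown fraction labels, negative
    abundances or empty accession cells.
    """
    missing = [c for c in TABLE_COLUMNS if c not in table.columns]
    if missing:
        raise FormatError(f"missing columns: {missing}")
    fractions = set(fraction_set)
    bad_frac = ~table["fraction"].isin(fractions)
    if bad_frac.any():
        rows = (np.flatnonzero(bad_frac.to_numpy()) + 1).tolist()
        labels = sorted(table.loc[bad_frac, "fraction"].unique())
        raise FormatError(f"unknown fraction labels {labels} in rows {rows[:10]}")
    neg = table["abundance"] < 0
    if neg.any():
        rows = (np.flatnonzero(neg.to_numpy()) + 1).tolist()
        raise FormatError(f"negative abundance in rows {rows[:10]}")
    key = ["peptide_id", *SAMPLE_COLUMNS]
    dup = table.duplicated(subset=key, keep=False)
    if dup.any():
        rows = (np.flatnonzero(dup.to_numpy()) + 1).tolist()
        raise FormatError(f"duplicate (peptide, sample) entries in rows {rows[:10]}")
    empty_acc = table["accessions"].astype(str).str.strip().isin({"", ACCESSION_SEP})
    if empty_acc.any():
        rows = (np.flatnonzero(empty_acc.to_numpy()) + 1).tolist()
        raise FormatError(f"empty accessions in rows {rows[:10]}")
    return table


def read_peptide_table(
    path: str | Path,
    fraction_set: Iterable[str] = DEFAULT_FRACTIONS,
    dialect: str = "long_tsv",
) -> pd.DataFrame:
    """Read a long-format peptide quantification table.

    ``dialect`` is ``"long_tsv"`` or ``"long_csv"``.  ``nd``/``NA``/empty
    abundance cells all parse to the internal missing marker (NaN).
    """
    if dialect not in ("long_tsv", "long_csv"):
        raise FormatError(f"unknown dialect {dialect!r}")
    sep = "\t" if dialect == "long_tsv" else ","
    raw = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    missing = [c for c in TABLE_COLUMNS if c not in raw.columns]
    if missing:
        raise FormatError(f"{path}: missing columns: {missing}")
    table = pd.DataFrame(
        {
            "peptide_id": raw["peptide_id"].str.strip(),
            "accessions": raw["accessions"].str.strip(),
            "fraction": raw["fraction"].str.strip(),
            "experiment": pd.to_numeric(raw["experiment"]).astype(int),
            "replicate": pd.to_numeric(raw["replicate"]).astype(int),
            "abundance": [parse_abundance(v) for v in raw["abundance"]],
        }
    )
    validate_peptide_table(table, fraction_set)
    _log_read(table)
    return table


def read_peptide_table_wide(
    path: str | Path,
    fraction_set: Iterable[str] = DEFAULT_FRACTIONS,
    sep: str = "\t",
) -> pd.DataFrame:
    """Read a wide "one column per run" export and return the long format.

    Run columns are named ``<fraction>.<experiment>.<replicate>`` (e.g.
    ``LD.1.2``); the first two columns must be ``peptide_id`` and
    ``accessions``.
    """
    raw = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    for col in ("peptide_id", "accessions"):
        if col not in raw.columns:
            raise FormatError(f"{path}: missing column {col!r}")
    run_cols = [c for c in raw.columns if c not in ("peptide_id", "accessions")]
    records = []
    for col in run_cols:
        parts = col.split(".")
        if len(parts) != 3:
            raise FormatError(f"{path}: run column {col!r} not <fraction>.<exp>.<rep>")
        frac, exp, rep = parts[0], int(parts[1]), int(parts[2])
        for pep, acc, cell in zip(raw["peptide_id"], raw["accessions"], raw[col]):
            records.append((pep.strip(), acc.strip(), frac, exp, rep, parse_abundance(cell)))
    table = pd.DataFrame(records, columns=TABLE_COLUMNS)
    validate_peptide_table(table, fraction_set)
    _log_read(table)
    return table


def _log_read(table: pd.DataFrame) -> None:
    n_nd = int(table["abundance"].isna().sum())
    logger.info(
        "read %d rows, %d peptides, %d samples, %d nd entries",
        len(table),
        table["peptide_id"].nunique(),
        len(table.groupby(SAMPLE_COLUMNS, sort=False)),
        n_nd,
    )
    per_sample = table.assign(nd=table["abundance"].isna()).groupby(SAMPLE_COLUMNS)["nd"].sum()
    for sample, count in per_sample.items():
        logger.debug("sample %s: %d nd entries", sample, int(count))


def format_abundance(value: float) -> str:
    """Format an abundance: scientific notation, 3 significant digits, or nd."""
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return ND_TOKEN
    return f"{value:.2E}"


def write_peptide_table(table: pd.DataFrame, path: str | Path) -> Path:
    """Write the long format to TSV; full float precision, NaN as ``nd``."""
    path = Path(path)
    out = table.copy()
    out["abundance"] = [ND_TOKEN if np.isnan(v) else repr(float(v)) for v in out["abundance"]]
    out.to_csv(path, sep="\t", index=False)
    return path


@dataclass
class AnnotationLists:
    """User-supplied accession lists steering the core-proteome call.

    ``contaminant_reference`` — proteins with established residency in the
    co-purifying contaminant organelle (e.g. the known plastoglobule core
    proteins); these calibrate/justify the contaminant-ratio cutoff.
    ``prior_exclusions`` — proteins with a previously characterised non-target
    localization, removed from the final call regardless of enrichment.
    ``category_map`` — optional accession → functional-category labels used
    only for reporting.
    """

    contaminant_reference: frozenset[str] = frozenset()
    prior_exclusions: frozenset[str] = frozenset()
    category_map: Mapping[str, str] = field(default_factory=dict)


def _read_accession_file(path: str | Path) -> tuple[frozenset[str], dict[str, str]]:
    accs: set[str] = set()
    second: dict[str, str] = {}
    with open(path, encoding="utf-8") as handle:
        for line in handle:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            acc = parts[0].strip()
            if not acc:
                continue
            accs.add(acc)
            if len(parts) > 1 and parts[1].strip():
                second[acc] = parts[1].strip()
    return frozenset(accs), second


def read_annotation_lists(
    contaminant_path: str | Path | None = None,
    exclusions_path: str | Path | None = None,
    category_path: str | Path | None = None,
) -> AnnotationLists:
    """Read annotation lists (one accession per line, optional second column)."""
    contaminants: frozenset[str] = frozenset()
    exclusions: frozenset[str] = frozenset()
    categories: dict[str, str] = {}
    if contaminant_path is not None:
        contaminants, _ = _read_accession_file(contaminant_path)
    if exclusions_path is not None:
        exclusions, _ = _read_accession_file(exclusions_path)
    if category_path is not None:
        accs, second = _read_accession_file(category_path)
        categories = {a: second.get(a, "") for a in accs}
    overlap = contaminants & exclusions
    if overlap:
        logger.info("%d accessions on both annotation lists: %s", len(overlap), sorted(overlap))
    return AnnotationLists(contaminants, exclusions, categories)


_REASONS = {
    "core": "",
    "fail_experiments": "insufficient_experiments",
    "excluded_contaminant": "contaminant_fraction",
    "excluded_prior": "prior_localization",
}


def write_core_report(
    result: pd.DataFrame,
    top3_summary: pd.DataFrame,
    out_dir: str | Path,
    profiles: pd.DataFrame | None = None,
) -> tuple[Path, Path]:
    """Write the enrichment-filter report and the TOP3 abundance report.

    ``result`` is the frame returned by
    :func:`coreome.enrichment.call_core_proteome` (indexed by group);
    ``top3_summary`` the frame from :func:`coreome.abundance.top3_summary`.
    Ratios are printed with one decimal, abundances in scientific notation
    with 3 significant digits, percentages with two decimals.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    extra = set(top3_summary.index) - set(result.index)
    if extra:
        raise ConsistencyError(
            f"abundance summary has groups absent from the filter result: {sorted(extra)[:5]}"
        )

    enr = result.copy()
    if profiles is not None:
        wide = profiles.unstack("experiment")
        wide.columns = [f"{ratio}.exp{exp}" for ratio, exp in wide.columns]
        for col in wide.columns:
            wide[col] = [ND_TOKEN if np.isnan(v) else ("inf" if np.isinf(v) else f"{v:.1f}") for v in wide[col]]
        enr = wide.join(enr, how="right")
    enr["exclusion_reason"] = [_REASONS.get(s, "") for s in enr["status"]]
    enr_path = out_dir / "enrichment_report.tsv"
    enr.to_csv(enr_path, sep="\t", index_label="group_id")

    ab = top3_summary.copy()
    for col in ab.columns:
        if col.startswith("top3_exp") or col == "average":
            ab[col] = [format_abundance(v) for v in ab[col]]
        elif col == "mass_contribution_pct":
            ab[col] = [ND_TOKEN if np.isnan(v) else f"{v:.2f}" for v in ab[col]]
    ab_path = out_dir / "abundance_report.tsv"
    ab.to_csv(ab_path, sep="\t", index_label="group_id")
    return enr_path, ab_path
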
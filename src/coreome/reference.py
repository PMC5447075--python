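"""Published reference dataset: the Arabidopsis aging-leaf lipid-droplet
core proteome (28 protein groups).

Two small tables ship with the package:

- ``ld_reference_ratios.tsv`` — per-experiment LD/soluble, LD/membrane and
  LD/total-leaf enrichment ratios for the 28 groups, plus the LD/plastoglobule
  ratio from the single experiment in which plastoglobules were purified;
- ``ld_reference_top3.tsv`` — per-experiment TOP3 abundances in the LD
  fraction, with the published nd-aware averages and mass-contribution
  percentages.

They serve as desk-scale fixtures: re-filtering the published ratios with the
default criteria must call all 28 groups core, and nd-aware averaging of the
published TOP3 values must reproduce the published averages.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

from .io_tables import parse_abundance

_RATIO_COLS = {
    1: ("e1_ld_s", "e1_ld_mb", "e1_ld_tl", None),
    2: ("e2_ld_s", "e2_ld_mb", "e2_ld_tl", None),
    3: ("e3_ld_s", "e3_ld_mb", "e3_ld_tl", "e3_ld_pg"),
}


def _read(name: str) -> pd.DataFrame:
    with resources.files("coreome.data").joinpath(name).open("r", encoding="utf-8") as fh:
        return pd.read_csv(fh, sep="\t", dtype=str, keep_default_na=False)


def load_reference_profiles() -> tuple[pd.DataFrame, dict[str, frozenset[str]]]:
    """The reference enrichment ratios as an injection-ready profile frame.

    Returns ``(profiles, members)``: a frame indexed by (group_id,
    experiment) with columns ``LD/SOL``, ``LD/MEM``, ``LD/TL``, ``LD/PG``
    (nd as NaN; LD/PG defined in experiment 3 only), and the group → member
    accessions mapping.
    """
    raw = _read("ld_reference_ratios.tsv")
    records = []
    for _, row in raw.iterrows():
        for exp, (c_s, c_mb, c_tl, c_pg) in _RATIO_COLS.items():
            records.append(
                {
                    "group_id": row["group_id"],
                    "experiment": exp,
                    "LD/SOL": parse_abundance(row[c_s]),
                    "LD/MEM": parse_abundance(row[c_mb]),
                    "LD/TL": parse_abundance(row[c_tl]),
                    "LD/PG": parse_abundance(row[c_pg]) if c_pg else np.nan,
                }
            )
    profiles = pd.DataFrame.from_records(records).set_index(["group_id", "experiment"])
    members = {
        row["group_id"]: frozenset(row["members"].split(";")) for _, row in raw.iterrows()
    }
    return profiles, members


def load_reference_top3() -> pd.DataFrame:
    """The reference TOP3 table, indexed by group_id.

    Columns ``top3_exp1..3`` (floats, nd as NaN) carry the per-experiment
    TOP3 abundances; ``published_average`` and ``published_mass_pct`` the
    values as published (the latter not recomputable from the averages, see
    the methods note).
    """
    raw = _read("ld_reference_top3.tsv").set_index("group_id")
    out = raw[["members", "name"]].copy()
    for col in ("top3_exp1", "top3_exp2", "top3_exp3", "published_average"):
        out[col] = [parse_abundance(v) for v in raw[col]]
    out["published_mass_pct"] = raw["published_mass_pct"].astype(float)
    return out
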
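import numpy as np
import pandas as pd
import pytest

from coreome import ProteinClassSpec, SyntheticConfig, simulate_dataset
from coreome.io_tables import TABLE_COLUMNS


def make_table(rows):
    """Build a long-format peptide table from (pep, accs, frac, exp, rep, ab)."""
    return pd.DataFrame(rows, columns=TABLE_COLUMNS)


@pytest.fixture
def tiny_table():
    """Two proteins, two samples; P2 has one shared and one unique peptide."""
    nd = np.nan
    return make_table(
        [
            ("p1", "P1", "LD", 1, 1, 30.0),
            ("p2", "P1", "LD", 1, 1, 20.0),
            ("p3", "P1", "LD", 1, 1, 10.0),
            ("p4", "P1;P2", "LD", 1, 1, 5.0),
            ("p5", "P2", "LD", 1, 1, 15.0),
            ("p6", "P2", "LD", 1, 1, 20.0),
            ("p1", "P1", "TL", 1, 1, 3.0),
            ("p2", "P1", "TL", 1, 1, 2.0),
            ("p3", "P1", "TL", 1, 1, 1.0),
            ("p4", "P1;P2", "TL", 1, 1, 0.5),
            ("p5", "P2", "TL", 1, 1, nd),
            ("p6", "P2", "TL", 1, 1, 2.0),
        ]
    )


def equal_totals_specs(enrichment: float = 50.0):
    """Two classes whose per-fraction totals are equal, so realized relative
    enrichment ratios equal the means ratios exactly at zero noise."""
    hi, lo = 100.0 * enrichment, 100.0
    return [
        ProteinClassSpec(
            "ld_resident",
            1,
            {"LD": hi, "SOL": lo, "MEM": lo, "TL": lo, "PG": lo},
            is_true_core=True,
        ),
        ProteinClassSpec(
            "soluble_background",
            1,
            {"LD": lo, "SOL": hi, "MEM": hi, "TL": hi, "PG": hi},
        ),
    ]


@pytest.fixture
def zero_noise_dataset():
    """Noise-free, censoring-free equal-totals design: LD/ref = 50 exactly."""
    config = SyntheticConfig(
        class_specs=equal_totals_specs(),
        peptide_count_range=(3, 3),
        response_sigma=0.0,
        noise_sigma=0.0,
        detection_limit=0.0,
        shared_peptide_pairs=0,
        seed=7,
    )
    table, truth = simulate_dataset(config)
    return config, table, truth


@pytest.fixture
def default_dataset():
    table, truth = simulate_dataset(SyntheticConfig(seed=11))
    return table, truth
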
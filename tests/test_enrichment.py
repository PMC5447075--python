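"""Enrichment ratios, the multi-criteria filter and threshold calibration."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from coreome import (
    AnnotationLists,
    ConfigurationError,
    FilterCriteria,
    build_groups,
    calibrate_contaminant_threshold,
    call_core_proteome,
    enrichment_ratios,
    load_reference_profiles,
    passes_experiment,
    relative_abundance,
)
from coreome.errors import CalibrationError


def make_profiles(rows):
    """Profile frame from (group, experiment, e_s, e_mb, e_tl, e_pg) tuples."""
    frame = pd.DataFrame(
        rows, columns=["group_id", "experiment", "LD/SOL", "LD/MEM", "LD/TL", "LD/PG"]
    )
    return frame.set_index(["group_id", "experiment"])


def make_rel(data, samples):
    """Relative-abundance frame from {group: [values per sample]}."""
    columns = pd.MultiIndex.from_tuples(samples, names=["fraction", "experiment", "replicate"])
    return pd.DataFrame.from_dict(data, orient="index", columns=columns).rename_axis("group_id")


class TestEnrichmentRatios:
    def test_ratio_of_replicate_averages(self):
        samples = [("LD", 1, 1), ("LD", 1, 2), ("TL", 1, 1), ("TL", 1, 2)]
        rel = make_rel({"G": [0.03, 0.01, 0.003, 0.001]}, samples)
        profiles = enrichment_ratios(rel, "LD", ["TL"])
        assert profiles.loc[("G", 1), "LD/TL"] == pytest.approx(10.0)

    def test_absent_reference_is_infinite_marker(self):
        samples = [("LD", 1, 1), ("SOL", 1, 1)]
        rel = make_rel({"G": [0.02, np.nan]}, samples)
        profiles = enrichment_ratios(rel, "LD", ["SOL"])
        assert np.isinf(profiles.loc[("G", 1), "LD/SOL"])

    def test_nd_target_gives_nd_ratio(self):
        samples = [("LD", 1, 1), ("TL", 1, 1)]
        rel = make_rel({"G": [np.nan, 0.01]}, samples)
        profiles = enrichment_ratios(rel, "LD", ["TL"])
        assert np.isnan(profiles.loc[("G", 1), "LD/TL"])

    def test_reference_absent_from_experiment_left_unset(self):
        samples = [("LD", 1, 1), ("LD", 2, 1), ("TL", 1, 1), ("TL", 2, 1), ("PG", 2, 1)]
        rel = make_rel({"G": [0.02, 0.02, 0.002, 0.002, 0.001]}, samples)
        profiles = enrichment_ratios(rel, "LD", ["TL", "PG"])
        assert np.isnan(profiles.loc[("G", 1), "LD/PG"])  # no PG sample in exp 1
        assert profiles.loc[("G", 2), "LD/PG"] == pytest.approx(20.0)

    @pytest.mark.parametrize("method", ["average_then_ratio", "ratio_then_average"])
    def test_zero_noise_design_recovers_means_ratio(self, method, zero_noise_dataset):
        """Equal per-fraction totals: realized ratios equal the 50x design."""
        _, table, _ = zero_noise_dataset
        groups = build_groups(table)
        rel = relative_abundance(table, groups)
        profiles = enrichment_ratios(rel, "LD", ["SOL", "MEM", "TL", "PG"], method=method)
        ld_group = [g.group_id for g in groups if g.group_id.startswith("LR")][0]
        for exp in (1, 2, 3):
            for col in ("LD/SOL", "LD/MEM", "LD/TL"):
                assert profiles.loc[(ld_group, exp), col] == pytest.approx(50.0)
        assert profiles.loc[(ld_group, 3), "LD/PG"] == pytest.approx(50.0)

    def test_single_protein_raw_ratio_matches_means(self):
        """With one protein the raw (unnormalized) LD/TL abundance ratio equals
        the means ratio; relative normalization collapses it to 1."""
        from conftest import make_table
        from coreome import abundance_matrix

        rows = []
        for frac, mean in (("LD", 100.0), ("TL", 10.0)):
            rows += [(f"p{i}", "A", frac, 1, 1, mean) for i in range(3)]
        table = make_table(rows)
        groups = build_groups(table)
        raw, _ = abundance_matrix(table, groups)
        assert raw.loc["A", ("LD", 1, 1)] / raw.loc["A", ("TL", 1, 1)] == pytest.approx(10.0)
        rel = relative_abundance(table, groups)
        profiles = enrichment_ratios(rel, "LD", ["TL"])
        assert profiles.loc[("A", 1), "LD/TL"] == pytest.approx(1.0)

    def test_ratios_invariant_under_per_sample_rescaling(self, default_dataset):
        table, _ = default_dataset
        groups = build_groups(table)
        rel = relative_abundance(table, groups)
        base = enrichment_ratios(rel, "LD", ["SOL", "MEM", "TL", "PG"])
        scaled = table.copy()
        mask = (scaled["fraction"] == "TL") & (scaled["experiment"] == 2)
        scaled.loc[mask, "abundance"] *= 0.01
        rel2 = relative_abundance(scaled, build_groups(scaled))
        again = enrichment_ratios(rel2, "LD", ["SOL", "MEM", "TL", "PG"])
        pd.testing.assert_frame_equal(base, again)


class TestPassesExperiment:
    @pytest.mark.parametrize(
        "e_s, e_mb, e_tl, expected",
        [
            (2.8, 40.2, 3.1, False),   # total-leaf ratio not above 6
            (12.0, 1.5, 8.3, True),    # exactly 1.5 is kept, not discarded
            (0.5, 0.2, 0.7, False),    # depleted in every comparison
            (np.inf, np.inf, np.inf, True),  # absent from references passes
            (np.nan, 5.0, 10.0, False),      # nd fails
            (5.0, 5.0, 6.0, False),    # threshold on total is strict
        ],
    )
    def test_criteria(self, e_s, e_mb, e_tl, expected):
        profiles = make_profiles([("G", 1, e_s, e_mb, e_tl, np.nan)])
        assert passes_experiment(profiles, FilterCriteria()).iloc[0] == expected


class TestCallCoreProteome:
    def test_two_of_three_rule(self):
        profiles = make_profiles(
            [
                ("G", 1, 2.8, 40.2, 3.1, np.nan),
                ("G", 2, 19.8, 21.5, 21.7, np.nan),
                ("G", 3, 3.2, 3.3, 6.6, 4.4),
            ]
        )
        result = call_core_proteome(profiles, FilterCriteria())
        assert result.loc["G", "n_pass"] == 2
        assert result.loc["G", "status"] == "core"

    def test_contaminant_ratio_below_cutoff_excludes(self):
        profiles = make_profiles(
            [
                ("G", 1, 50.0, 50.0, 50.0, np.nan),
                ("G", 2, 50.0, 50.0, 50.0, np.nan),
                ("G", 3, 50.0, 50.0, 50.0, 3.99),
            ]
        )
        result = call_core_proteome(profiles, FilterCriteria())
        assert result.loc["G", "status"] == "excluded_contaminant"

    def test_missing_contaminant_ratio_does_not_exclude(self):
        profiles = make_profiles(
            [
                ("G", 1, 50.0, 50.0, 50.0, np.nan),
                ("G", 2, 50.0, 50.0, 50.0, np.nan),
                ("G", 3, np.nan, np.nan, np.nan, np.nan),
            ]
        )
        result = call_core_proteome(profiles, FilterCriteria())
        assert result.loc["G", "status"] == "core"

    def test_prior_localization_excludes_passing_group(self):
        profiles = make_profiles(
            [("G", e, 50.0, 50.0, 50.0, 10.0 if e == 3 else np.nan) for e in (1, 2, 3)]
        )
        annotations = AnnotationLists(prior_exclusions=frozenset({"ACC2"}))
        result = call_core_proteome(
            profiles, FilterCriteria(), annotations, members={"G": {"ACC1", "ACC2"}}
        )
        assert result.loc["G", "status"] == "excluded_prior"

    def test_nd_experiments_count_as_failed_but_two_detections_suffice(self):
        profiles = make_profiles(
            [
                ("G", 1, 43.2, 8.7, 51.1, np.nan),
                ("G", 2, 83.7, 4.0, 54.0, np.nan),
                ("G", 3, np.nan, np.nan, np.nan, np.nan),
            ]
        )
        result = call_core_proteome(profiles, FilterCriteria())
        assert result.loc["G", "n_pass"] == 2
        assert result.loc["G", "status"] == "core"

    def test_k_exceeding_observed_experiments_rejected(self):
        profiles = make_profiles([("G", 1, 50.0, 50.0, 50.0, np.nan)])
        with pytest.raises(ConfigurationError, match="k_required"):
            call_core_proteome(profiles, FilterCriteria(k_required=2, n_experiments=3), None)

    def test_invalid_criteria_rejected(self):
        with pytest.raises(ConfigurationError, match="t_total"):
            FilterCriteria(t_total=0)
        with pytest.raises(ConfigurationError, match="k_required"):
            FilterCriteria(k_required=4, n_experiments=3)

    @pytest.mark.parametrize("seed", range(5))
    def test_threshold_monotonicity(self, seed):
        """Raising any threshold never adds a group to the core set."""
        rng = np.random.default_rng(seed)
        rows = []
        for g in range(30):
            for e in (1, 2, 3):
                rows.append(
                    (
                        f"G{g:02d}",
                        e,
                        float(rng.lognormal(1, 1.5)),
                        float(rng.lognormal(1, 1.5)),
                        float(rng.lognormal(1.5, 1.5)),
                        float(rng.lognormal(1, 1.5)) if e == 3 else np.nan,
                    )
                )
        profiles = make_profiles(rows)
        base = FilterCriteria()
        core0 = set(
            call_core_proteome(profiles, base).query("status == 'core'").index
        )
        for stricter in (
            FilterCriteria(t_total=9.0),
            FilterCriteria(t_soluble=3.0),
            FilterCriteria(t_membrane=3.0),
            FilterCriteria(t_contaminant=8.0),
            FilterCriteria(k_required=3),
        ):
            core1 = set(
                call_core_proteome(profiles, stricter).query("status == 'core'").index
            )
            assert core1 <= core0
        looser = FilterCriteria(t_total=3.0, t_soluble=1.0, t_membrane=1.0,
                                t_contaminant=2.0, k_required=1)
        core2 = set(call_core_proteome(profiles, looser).query("status == 'core'").index)
        assert core0 <= core2


class TestCalibration:
    def test_reference_maximum_just_below_four_gives_four(self):
        rows = []
        for g, ratio in (("C1", 1.2), ("C2", 3.99), ("C3", 0.5)):
            rows.append((g, 3, 1.0, 1.0, 1.0, ratio))
        profiles = make_profiles(rows)
        result = calibrate_contaminant_threshold(profiles, {"C1", "C2", "C3"})
        assert result.threshold == 4.0
        assert result.max_ratio == pytest.approx(3.99)
        assert result.group_id == "C2"

    def test_reference_at_zero_gives_smallest_step(self):
        profiles = make_profiles([("C1", 3, 1.0, 1.0, 1.0, 0.0)])
        assert calibrate_contaminant_threshold(profiles, {"C1"}).threshold == 1.0

    def test_no_quantified_reference_raises(self):
        profiles = make_profiles([("C1", 3, 1.0, 1.0, 1.0, np.nan)])
        with pytest.raises(CalibrationError):
            calibrate_contaminant_threshold(profiles, {"C1"})

    @given(
        ratios=st.lists(st.floats(min_value=0, max_value=500), min_size=1, max_size=20)
    )
    @settings(max_examples=60, derandomize=True)
    def test_threshold_dominates_every_reference(self, ratios):
        rows = [(f"C{i}", 3, 1.0, 1.0, 1.0, r) for i, r in enumerate(ratios)]
        profiles = make_profiles(rows)
        refs = {f"C{i}" for i in range(len(ratios))}
        threshold = calibrate_contaminant_threshold(profiles, refs).threshold
        assert all(threshold > r for r in ratios)

    def test_calibrated_threshold_excludes_reference_contaminants(self):
        rows = []
        for g, ratio in (("C1", 3.99), ("C2", 1.5)):
            rows += [(g, e, 50.0, 50.0, 50.0, ratio if e == 3 else np.nan) for e in (1, 2, 3)]
        profiles = make_profiles(rows)
        threshold = calibrate_contaminant_threshold(profiles, {"C1", "C2"}).threshold
        result = call_core_proteome(
            profiles, FilterCriteria(t_contaminant=threshold)
        )
        assert (result["status"] == "excluded_contaminant").all()


def test_reference_dataset_rows_pass_in_at_least_two_experiments():
    """Every published core-proteome row passes the per-experiment criteria
    in >= 2 of the 3 experiments under the default thresholds."""
    profiles, _ = load_reference_profiles()
    passes = passes_experiment(profiles, FilterCriteria()).unstack("experiment")
    assert (passes.sum(axis=1) >= 2).all()
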
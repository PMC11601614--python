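"""Candidate flagging, window aggregation and model-ready arrays."""

import numpy as np
import pytest

from arraycnv.features import (
    DELETION_CATALOG,
    DELETION_RULE,
    DUPLICATION_CATALOG,
    DUPLICATION_RULE,
    aggregate_window,
    build_feature_array,
    flag_candidates,
    flag_insertion_band,
    flag_midrange_baf,
)
from arraycnv.regions import RegionSpec, compute_window_scheme
from arraycnv.simulate import simulate_panel

from conftest import make_panel


class TestFlagging:
    def test_deletion_threshold_strict(self):
        lrr = np.array([-0.25, -0.20, -0.1999, 0.0, np.nan])
        mask = flag_candidates(lrr, DELETION_RULE)
        assert mask.tolist() == [True, False, False, False, False]

    def test_duplication_threshold_strict(self):
        lrr = np.array([0.25, 0.20, 0.2001, -0.5, np.nan])
        mask = flag_candidates(lrr, DUPLICATION_RULE)
        assert mask.tolist() == [True, False, True, False, False]

    def test_insertion_bands_open(self):
        baf = np.array([0.15, 0.25, 0.35, 0.5, 0.65, 0.75, 0.85, np.nan])
        mask = flag_insertion_band(baf)
        assert mask.tolist() == [False, True, False, False, False, True, False, False]

    def test_midrange_inclusive(self):
        baf = np.array([0.1499, 0.15, 0.5, 0.85, 0.851, np.nan])
        mask = flag_midrange_baf(baf)
        assert mask.tolist() == [False, True, True, True, False, False]


class TestAggregateWindow:
    def test_hand_computed_deletion_window(self):
        """LRRs {-0.5, -0.3, 0.1}: two candidates, mean -0.4, fraction 2/3."""
        lrr = np.array([-0.5, -0.3, 0.1])
        baf = np.array([0.5, 0.5, 0.5])
        vec = aggregate_window(baf, lrr, DELETION_CATALOG, DELETION_RULE)
        f = dict(zip(DELETION_CATALOG.feature_names, vec))
        assert f["cand_count"] == 2
        assert f["cand_frac"] == pytest.approx(2 / 3)
        assert f["cand_lrr_avg"] == pytest.approx(-0.4)
        assert f["cand_lrr_sd"] == pytest.approx(0.1)  # population SD of {-0.5,-0.3}
        assert f["all_count"] == 3
        assert f["all_lrr_avg"] == pytest.approx(np.mean(lrr))

    def test_empty_window_is_all_zero(self):
        vec = aggregate_window(np.array([]), np.array([]), DELETION_CATALOG, DELETION_RULE)
        assert np.all(vec == 0.0)

    def test_single_snp_dispersion_zero(self):
        vec = aggregate_window(np.array([0.5]), np.array([-0.9]),
                               DELETION_CATALOG, DELETION_RULE)
        f = dict(zip(DELETION_CATALOG.feature_names, vec))
        assert f["cand_count"] == 1
        assert f["cand_lrr_sd"] == 0.0
        assert f["cand_lrr_iqr"] == 0.0

    def test_missing_fields_excluded_from_value_stats(self):
        baf = np.array([np.nan, 0.5])
        lrr = np.array([-0.5, np.nan])
        vec = aggregate_window(baf, lrr, DELETION_CATALOG, DELETION_RULE)
        f = dict(zip(DELETION_CATALOG.feature_names, vec))
        assert f["cand_count"] == 1       # NaN LRR is never a candidate
        assert f["cand_baf_avg"] == 0.0   # the candidate's BAF is missing
        assert f["all_count"] == 2
        assert f["all_lrr_avg"] == pytest.approx(-0.5)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(5)
        baf = rng.uniform(0, 1, 40)
        lrr = rng.normal(0, 0.4, 40)
        perm = rng.permutation(40)
        a = aggregate_window(baf, lrr, DUPLICATION_CATALOG, DUPLICATION_RULE)
        b = aggregate_window(baf[perm], lrr[perm], DUPLICATION_CATALOG, DUPLICATION_RULE)
        # summation order may differ in the last ulp
        np.testing.assert_allclose(a, b, rtol=1e-12, atol=1e-14)

    def test_candidate_fraction_consistency(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            n = rng.integers(1, 30)
            baf = rng.uniform(0, 1, n)
            lrr = rng.normal(0, 0.3, n)
            vec = aggregate_window(baf, lrr, DELETION_CATALOG, DELETION_RULE)
            f = dict(zip(DELETION_CATALOG.feature_names, vec))
            assert f["cand_frac"] == pytest.approx(f["cand_count"] / n)


def _naive_feature_block(panel, scheme, catalog, rule):
    """Brute-force per-(sample, window) oracle for build_feature_array."""
    samples = panel.samples
    out = np.zeros((len(samples), scheme.total_windows, catalog.n_features))
    rec = panel.records
    for si, sid in enumerate(samples):
        sub = rec.loc[rec["sample_id"] == sid]
        for wi, (ws, we) in enumerate(scheme.windows):
            in_win = sub.loc[(sub["position"] >= ws) & (sub["position"] < we)]
            out[si, wi] = aggregate_window(
                in_win["baf"].to_numpy(), in_win["lrr"].to_numpy(), catalog, rule
            )
    return out


class TestBuildFeatureArray:
    def test_deletion_shape(self, toy_region):
        panel = make_panel(np.arange(95_000, 205_000, 500), ["A", "B", "C"])
        scheme = compute_window_scheme(toy_region, split=5, total_windows=50)
        arr = build_feature_array(panel, scheme, "deletion")
        assert arr.values.shape == (3, 50, 13)

    def test_duplication_shape(self, toy_region):
        panel = make_panel(np.arange(95_000, 205_000, 500), ["A", "B"])
        scheme = compute_window_scheme(toy_region, split=10, total_windows=70)
        arr = build_feature_array(panel, scheme, "duplication")
        assert arr.values.shape == (2, 70, 11)

    @pytest.mark.parametrize("cnv_type", ["deletion", "duplication"])
    def test_oracle_equivalence_on_random_panel(self, cnv_type):
        from arraycnv.features import catalog_for, rule_for
        from arraycnv.regions import resolve_region

        region = RegionSpec("chr6", 1_000_000, 1_400_000, buffer=50_000)
        panel, _ = simulate_panel(
            region, n_samples=4, carrier_fraction=0.5, cnv_type=cnv_type,
            event_size_range=(50_000, 200_000), n_snps=300, seed=21,
        )
        scheme = compute_window_scheme(region, split=5, total_windows=12)
        arr = build_feature_array(panel, scheme, cnv_type, scale=False)
        oracle = _naive_feature_block(panel, scheme, catalog_for(cnv_type), rule_for(cnv_type))
        np.testing.assert_array_equal(arr.values, oracle)

    def test_scaling_round_trip_bitwise(self, toy_region):
        panel = make_panel(np.arange(95_000, 205_000, 1_000), ["A", "B"],
                           lrr=np.linspace(-1, 1, 110), baf=np.linspace(0, 1, 110))
        scheme = compute_window_scheme(toy_region, split=2, total_windows=5)
        train = build_feature_array(panel, scheme, "deletion")
        again = build_feature_array(panel, scheme, "deletion", scaling=train.scaling)
        np.testing.assert_array_equal(train.values, again.values)

    def test_catalog_rule_mismatch_rejected(self, toy_region):
        panel = make_panel([100_000], ["A"])
        scheme = compute_window_scheme(toy_region, split=1, total_windows=1)
        with pytest.raises(ValueError, match="does not match"):
            build_feature_array(panel, scheme, "deletion",
                                catalog=DELETION_CATALOG, rule=DUPLICATION_RULE)

    def test_long_table_round_trip(self, toy_region, tmp_path):
        import pandas as pd

        panel = make_panel(np.arange(95_000, 205_000, 2_000), ["A", "B"])
        scheme = compute_window_scheme(toy_region, split=2, total_windows=4)
        arr = build_feature_array(panel, scheme, "duplication", scale=False)
        path = tmp_path / "features.tsv"
        arr.to_long_table(path)
        flat = pd.read_csv(path, sep="\t")
        assert len(flat) == 2 * 4 * 11
        back = (
            flat.pivot_table(index=["sampleID", "window_index"],
                             columns="feature_name", values="value", sort=False)
            .loc[:, list(arr.feature_names)]
            .to_numpy()
            .reshape(2, 4, 11)
        )
        np.testing.assert_allclose(back, arr.values)
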
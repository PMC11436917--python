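import numpy as np
import pandas as pd
import pytest

from triageshift import (
    DEFAULT_SCHEMA,
    GATSFill,
    apply_standardizer,
    fit_imputer,
    fit_standardizer,
    gats_fill,
    harmonize_units,
    invert_standardizer,
    knn_match,
    median_impute,
)
from triageshift.preprocess import canonical_units, write_fill_records
from triageshift.exceptions import ConfigurationError, DataError, SizingError

from conftest import toy_cohort


class TestHarmonizeUnits:
    def test_hemoglobin_gdl_times_ten(self):
        cohort = toy_cohort({"hemoglobin": [11.0, 13.5]})
        units = {"hemoglobin": "g/dL"}
        out = harmonize_units(cohort, units)
        assert list(out["hemoglobin"]) == [110.0, 135.0]

    def test_canonical_cohort_unchanged(self, base_cohort):
        out = harmonize_units(base_cohort, canonical_units())
        pd.testing.assert_frame_equal(out, base_cohort)

    def test_unknown_unit_names_feature(self):
        cohort = toy_cohort({"temperature": [98.6]})
        with pytest.raises(ConfigurationError, match="temperature"):
            harmonize_units(cohort, {"temperature": "kelvin"})

    def test_undeclared_present_feature_rejected(self):
        cohort = toy_cohort({"sodium": [140.0]})
        with pytest.raises(ConfigurationError, match="sodium"):
            harmonize_units(cohort, {})

    def test_fahrenheit_conversion(self):
        cohort = toy_cohort({"temperature": [98.6]})
        out = harmonize_units(cohort, {"temperature": "degF"})
        assert out["temperature"].iloc[0] == pytest.approx(37.0)


class TestStandardizer:
    def test_hand_computed_population_sd_convention(self):
        train = toy_cohort({"sodium": [2.0, 4.0, 6.0]})
        stats = fit_standardizer(train, ["sodium"])
        out = apply_standardizer(train, stats)
        np.testing.assert_allclose(
            out["sodium"], [-1.22474487, 0.0, 1.22474487], atol=1e-8
        )

    def test_training_cohort_becomes_zero_mean_unit_sd(self, base_cohort):
        feats = DEFAULT_SCHEMA.matched
        stats = fit_standardizer(base_cohort, feats)
        out = apply_standardizer(base_cohort, stats)
        for f in feats:
            v = out[f].dropna()
            assert abs(v.mean()) < 1e-9
            assert abs(v.std(ddof=0) - 1.0) < 1e-9

    def test_value_at_training_mean_maps_to_zero(self):
        train = toy_cohort({"sodium": [2.0, 4.0, 6.0]})
        stats = fit_standardizer(train, ["sodium"])
        test = toy_cohort({"sodium": [4.0]})
        assert apply_standardizer(test, stats)["sodium"].iloc[0] == 0.0

    def test_constant_feature_rejected(self):
        train = toy_cohort({"sodium": [5.0, 5.0, 5.0]})
        with pytest.raises(DataError, match="sodium"):
            fit_standardizer(train, ["sodium"])

    def test_round_trip_recovers_values(self, base_cohort):
        feats = DEFAULT_SCHEMA.matched
        stats = fit_standardizer(base_cohort, feats)
        back = invert_standardizer(apply_standardizer(base_cohort, stats), stats)
        np.testing.assert_allclose(
            back[feats].to_numpy(), base_cohort[feats].to_numpy(), atol=1e-9
        )


class TestMedianImpute:
    def test_missing_cells_get_training_median(self):
        train = toy_cohort({"sodium": [1.0, 2.0, 3.0]})
        medians = fit_imputer(train, ["sodium"])
        cohort = toy_cohort({"sodium": [1.0, np.nan, 3.0]})
        out, mask = median_impute(cohort, medians)
        assert list(out["sodium"]) == [1.0, 2.0, 3.0]
        assert list(mask["sodium"]) == [False, True, False]

    def test_complete_cohort_unchanged(self):
        train = toy_cohort({"sodium": [1.0, 2.0]})
        medians = fit_imputer(train, ["sodium"])
        cohort = toy_cohort({"sodium": [5.0, 6.0]})
        out, mask = median_impute(cohort, medians)
        pd.testing.assert_frame_equal(out, cohort)
        assert not mask.any().any()

    def test_unfitted_feature_with_missing_cells_rejected(self):
        train = toy_cohort({"albumin": [np.nan, np.nan]})
        medians = fit_imputer(train, ["albumin"])
        cohort = toy_cohort({"albumin": [np.nan, 40.0]})
        with pytest.raises(DataError, match="albumin"):
            median_impute(cohort, medians, features=["albumin"])


class TestKnnMatch:
    def test_identical_row_is_first_with_zero_distance(self):
        source = toy_cohort({"sodium": [1.0, 2.0, 3.0], "urea": [1.0, 5.0, 9.0]})
        target = toy_cohort({"sodium": [2.0], "urea": [5.0]})
        idx, dist = knn_match(target, source, ["sodium", "urea"], k=2)
        assert idx[0, 0] == 1
        assert dist[0, 0] == 0.0

    def test_k_equals_source_returns_all_sorted(self):
        source = toy_cohort({"sodium": [5.0, 1.0, 3.0]})
        target = toy_cohort({"sodium": [0.0]})
        idx, dist = knn_match(target, source, ["sodium"], k=3)
        assert list(idx[0]) == [1, 2, 0]
        assert list(dist[0]) == [1.0, 3.0, 5.0]

    def test_matches_brute_force_oracle_200x200(self):
        rng = np.random.default_rng(17)
        n, m, d, k = 200, 200, 5, 7
        feats = DEFAULT_SCHEMA.matched[:d]
        source = toy_cohort({f: rng.normal(size=m) for f in feats})
        target = toy_cohort({f: rng.normal(size=n) for f in feats})
        idx, dist = knn_match(target, source, feats, k=k)

        Xt = target[feats].to_numpy()
        Xs = source[feats].to_numpy()
        for i in range(n):
            d_all = np.sqrt(((Xt[i] - Xs) ** 2).sum(axis=1))
            oracle = np.argsort(d_all, kind="stable")[:k]
            np.testing.assert_array_equal(idx[i], oracle)
            np.testing.assert_allclose(dist[i], d_all[oracle], atol=1e-12)

    def test_distance_ties_broken_by_source_order(self):
        source = toy_cohort({"sodium": [2.0, 0.0, 2.0]})
        target = toy_cohort({"sodium": [1.0]})
        idx, _ = knn_match(target, source, ["sodium"], k=3)
        assert list(idx[0]) == [0, 1, 2]

    def test_k_too_large_rejected(self):
        source = toy_cohort({"sodium": [1.0]})
        target = toy_cohort({"sodium": [1.0]})
        with pytest.raises(SizingError):
            knn_match(target, source, ["sodium"], k=2)


def _gats_tables(n_target=6, n_source=30, seed=0):
    rng = np.random.default_rng(seed)
    feats = DEFAULT_SCHEMA.matched
    source = toy_cohort({f: rng.normal(size=n_source) for f in feats})
    source["albumin"] = rng.normal(40, 5, n_source)
    source["c_reactive_protein"] = rng.lognormal(3, 0.5, n_source)
    target = toy_cohort({f: rng.normal(size=n_target) for f in feats})
    target["albumin"] = np.nan
    target["c_reactive_protein"] = np.nan
    return target, source


class TestGatsFill:
    def test_uniform_weights_give_neighbor_mean(self):
        target, source = _gats_tables()
        filled, config = gats_fill(target, source, ["albumin"], GATSFill(k=3))
        idx, _ = knn_match(
            apply_standardizer(target, fit_standardizer(source, DEFAULT_SCHEMA.matched)),
            apply_standardizer(source, fit_standardizer(source, DEFAULT_SCHEMA.matched)),
            DEFAULT_SCHEMA.matched, k=3,
        )
        expected = source["albumin"].to_numpy()[idx].mean(axis=1)
        np.testing.assert_allclose(filled["albumin"], expected, atol=1e-12)

    def test_constant_neighbors_yield_constant(self):
        target, source = _gats_tables()
        source["albumin"] = 7.0
        for scheme in ("uniform", "inverse-distance", "random-convex"):
            filled, _ = gats_fill(
                target, source, ["albumin"], GATSFill(k=4, weight_scheme=scheme, seed=3)
            )
            np.testing.assert_allclose(filled["albumin"], 7.0, atol=1e-9)

    def test_k_one_copies_the_single_neighbor(self):
        target, source = _gats_tables()
        filled, config = gats_fill(target, source, ["albumin"], GATSFill(k=1))
        for record, (_, row) in zip(config.records, filled.iterrows()):
            assert row["albumin"] == source.loc[record["neighbors"][0], "albumin"]

    @pytest.mark.parametrize("scheme", ["uniform", "inverse-distance", "random-convex"])
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_convex_hull_property(self, scheme, seed):
        """Every filled cell lies within the componentwise neighbor [min, max]."""
        target, source = _gats_tables(n_target=15, n_source=40, seed=seed)
        missing = ["albumin", "c_reactive_protein"]
        config = GATSFill(k=5, weight_scheme=scheme, seed=seed)
        filled, config = gats_fill(target, source, missing, config)
        for record, (_, row) in zip(config.records, filled.iterrows()):
            donors = source.loc[record["neighbors"], missing]
            for feat in missing:
                assert donors[feat].min() - 1e-9 <= row[feat] <= donors[feat].max() + 1e-9
            assert sum(record["weights"]) == pytest.approx(1.0)
            assert min(record["weights"]) >= 0

    def test_random_convex_is_seeded(self):
        target, source = _gats_tables()
        a, _ = gats_fill(target, source, ["albumin"], GATSFill(k=3, weight_scheme="random-convex", seed=5))
        b, _ = gats_fill(target, source, ["albumin"], GATSFill(k=3, weight_scheme="random-convex", seed=5))
        c, _ = gats_fill(target, source, ["albumin"], GATSFill(k=3, weight_scheme="random-convex", seed=6))
        np.testing.assert_array_equal(a["albumin"], b["albumin"])
        assert not np.array_equal(a["albumin"], c["albumin"])

    def test_empty_missing_features_is_noop_with_warning(self):
        target, source = _gats_tables()
        with pytest.warns(UserWarning):
            out, _ = gats_fill(target, source, [], GATSFill(k=3))
        pd.testing.assert_frame_equal(out, target)

    def test_partially_observed_target_column_rejected(self):
        target, source = _gats_tables()
        target.loc[0, "albumin"] = 40.0
        with pytest.raises(DataError, match="albumin"):
            gats_fill(target, source, ["albumin"], GATSFill(k=3))

    def test_fill_records_serialize_as_json_lines(self, tmp_path):
        import json

        target, source = _gats_tables()
        _, config = gats_fill(target, source, ["albumin"], GATSFill(k=2))
        path = tmp_path / "records.jsonl"
        write_fill_records(config, path)
        lines = path.read_text().strip().splitlines()
        assert len(lines) == len(target)
        record = json.loads(lines[0])
        assert set(record) == {"row", "neighbors", "weights", "filled_features"}


def test_pipeline_order_is_deterministic(base_cohort):
    """harmonize -> impute -> standardize applied twice yields identical tables."""
    feats = DEFAULT_SCHEMA.matched
    cohort = base_cohort.copy()
    cohort.loc[cohort.index[:50], "sodium"] = np.nan

    def pipeline():
        h = harmonize_units(cohort, canonical_units())
        medians = fit_imputer(h, feats)
        imputed, _ = median_impute(h, medians)
        stats = fit_standardizer(imputed, feats)
        return apply_standardizer(imputed, stats)

    pd.testing.assert_frame_equal(pipeline(), pipeline())
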
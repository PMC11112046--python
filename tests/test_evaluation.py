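import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from ppamut.evaluation import (feature_importance, kfold_split, looc_split,
                               metrics, run_cv, site_grouped_split,
                               train_test_report)
from ppamut.ensemble_model import AffinityModel, EncoderSpec


def _oracle_predictor(y_full, data):
    """Echoes the truth for each test row: the perfect-predictor control."""
    lookup = pd.Series(y_full, index=data.index)

    def predict(train_X, train_y, test_X, seed, class_label):
        return lookup.loc[test_X.index].to_numpy()
    return predict


class TestMetrics:
    def test_identity_is_perfect(self):
        m = metrics([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert m == {"pcc": pytest.approx(1.0), "mae": 0.0, "rmse": 0.0}

    def test_perfect_anticorrelation(self):
        assert metrics([1, 2, 3], [3, 2, 1])["pcc"] == pytest.approx(-1.0)

    def test_fixed_arithmetic_example(self):
        m = metrics([0, 1, 2], [0, 2, 3])
        assert m["mae"] == pytest.approx(2 / 3)
        assert m["rmse"] == pytest.approx(np.sqrt(2 / 3))

    def test_matches_textbook_pearson_on_random_pairs(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            n = int(rng.integers(3, 40))
            x = rng.standard_normal(n)
            y = rng.standard_normal(n)
            assert metrics(x, y)["pcc"] == pytest.approx(
                stats.pearsonr(x, y).statistic, abs=1e-12)

    def test_zero_variance_truth_gives_nan_pcc_but_errors(self):
        m = metrics([1.0, 1.0, 1.0], [0.5, 1.5, 1.0])
        assert np.isnan(m["pcc"]) and m["mae"] > 0

    @given(st.lists(st.floats(-10, 10), min_size=2, max_size=30),
           st.integers(0, 10**6))
    @settings(max_examples=50, derandomize=True)
    def test_rmse_dominates_mae(self, xs, seed):
        rng = np.random.default_rng(seed)
        ys = rng.normal(0, 1, len(xs))
        m = metrics(xs, ys)
        assert m["rmse"] >= m["mae"] - 1e-12


class TestSplits:
    def test_kfold_sizes_differ_by_at_most_one(self):
        folds = kfold_split(25, k=10, seed=0)
        sizes = sorted(len(test) for _, test in folds)
        assert sizes == [2] * 5 + [3] * 5

    def test_kfold_disjoint_cover_and_seeded(self):
        folds = kfold_split(40, k=7, seed=3)
        all_test = np.concatenate([test for _, test in folds])
        assert sorted(all_test) == list(range(40))
        again = kfold_split(40, k=7, seed=3)
        for (tr1, te1), (tr2, te2) in zip(folds, again):
            np.testing.assert_array_equal(te1, te2)

    def test_kfold_too_few_rows(self):
        with pytest.raises(ValueError):
            kfold_split(5, k=10)

    def test_looc_one_fold_per_complex(self):
        complexes = ["c1"] * 3 + ["c2"] * 2 + ["c3", "c4", "c5"]
        folds = looc_split(complexes)
        assert len(folds) == 5
        total = 0
        for train, test in folds:
            test_ids = {complexes[i] for i in test}
            train_ids = {complexes[i] for i in train}
            assert len(test_ids) == 1 and not test_ids & train_ids
            total += len(test)
        assert total == len(complexes)

    def test_looc_single_complex_is_error(self):
        with pytest.raises(ValueError):
            looc_split(["c1", "c1"])

    def test_site_mode_never_splits_a_site(self, synth_small):
        folds = site_grouped_split(synth_small.sites, k=5, seed=2,
                                   mode="site")
        sites = synth_small.sites
        for _, test in folds:
            test_sites = {sites[i] for i in test}
            for train_idx, _ in [f for f in folds if f[1] is not test]:
                pass
        fold_of = {}
        for f, (_, test) in enumerate(folds):
            for i in test:
                fold_of.setdefault(sites[i], set()).add(f)
        assert all(len(v) == 1 for v in fold_of.values())

    def test_variation_mode_matches_kfold(self):
        a = site_grouped_split(30, k=5, seed=9, mode="variation")
        b = kfold_split(30, k=5, seed=9)
        for (_, ta), (_, tb) in zip(a, b):
            np.testing.assert_array_equal(ta, tb)

    def test_site_mode_k_exceeding_groups(self):
        sites = [("c1", "A", 1)] * 5
        with pytest.raises(ValueError):
            site_grouped_split(sites, k=2, mode="site")

    def test_all_regimes_are_disjoint_covers(self, synth_small):
        n = len(synth_small.ddg_true)
        regimes = [
            kfold_split(n, k=6, seed=1),
            looc_split(synth_small.complexes),
            site_grouped_split(synth_small.sites, k=6, seed=1, mode="site"),
        ]
        for folds in regimes:
            covered = np.concatenate([test for _, test in folds])
            assert sorted(covered) == list(range(n))
            for train, test in folds:
                assert not set(train) & set(test)


class TestRunCV:
    def test_oracle_predictor_is_perfect_in_every_regime(self, synth_small):
        y = synth_small.ddg_true
        data = synth_small.features.data
        oracle = _oracle_predictor(y, data)
        for regime in ("kfold", "looc", "site", "variation"):
            report = run_cv(synth_small.features, y, synth_small.classes,
                            complexes=synth_small.complexes,
                            sites=synth_small.sites, regime=regime, k=4,
                            seed=0, predict_fn=oracle)
            assert report.pooled["pcc"] == pytest.approx(1.0)
            assert report.pooled["mae"] == pytest.approx(0.0, abs=1e-12)
            for cell in report.per_fold:
                if not np.isnan(cell["pcc"]):
                    assert cell["pcc"] == pytest.approx(1.0)

    def test_constant_predictor_flags_undefined_pcc(self, synth_small):
        y = synth_small.ddg_true

        def constant(train_X, train_y, test_X, seed, label):
            return np.full(len(test_X), 0.5)
        report = run_cv(synth_small.features, y, synth_small.classes,
                        regime="kfold", k=4, seed=0, predict_fn=constant)
        assert all(np.isnan(c["pcc"]) for c in report.per_fold)
        expected_mae = np.abs(y - 0.5).mean()
        assert report.pooled["mae"] == pytest.approx(expected_mae)

    def test_overall_is_unweighted_class_mean(self, synth_small):
        y = synth_small.ddg_true
        oracle = _oracle_predictor(y, synth_small.features.data)

        def noisy(train_X, train_y, test_X, seed, label):
            base = oracle(train_X, train_y, test_X, seed, label)
            rng = np.random.default_rng(abs(hash(label)) % 2**31)
            return base + rng.normal(0, 0.5, len(base))
        report = run_cv(synth_small.features, y, synth_small.classes,
                        regime="kfold", k=4, seed=0, predict_fn=noisy)
        pccs = [cell["pcc"] for cell in report.per_class.values()]
        assert report.overall["pcc"] == pytest.approx(np.mean(pccs))

    def test_report_serialises(self, synth_small):
        oracle = _oracle_predictor(synth_small.ddg_true,
                                   synth_small.features.data)
        report = run_cv(synth_small.features, synth_small.ddg_true,
                        synth_small.classes, regime="kfold", k=4, seed=0,
                        predict_fn=oracle)
        d = report.to_dict()
        assert d["regime"] == "kfold" and d["n"] == len(synth_small.ddg_true)
        frame = report.to_frame()
        assert "overall" in frame.index


class TestFeatureImportance:
    @pytest.fixture(scope="class")
    def fitted(self):
        rng = np.random.default_rng(21)
        X = pd.DataFrame({
            "x1": rng.standard_normal(300),
            "noise_a": rng.standard_normal(300),
            "noise_b": rng.standard_normal(300),
            "flat": np.zeros(300),
        })
        y = 2.0 * X["x1"].to_numpy() + rng.normal(0, 0.2, 300)
        import warnings as w
        model = AffinityModel(y, X, encoder_spec=EncoderSpec(hidden_dim=16,
                                                             epochs=60),
                              n_features=4)
        with w.catch_warnings():
            w.simplefilter("ignore")
            res = model.fit(seed=0)
        return X, y, res

    def test_signal_feature_ranked_first(self, fitted):
        X, y, res = fitted
        table = feature_importance(res, X, y, n_repeats=3, seed=0)
        assert table.iloc[0]["feature"] == "x1"
        assert table.iloc[0]["importance"] > 0.2

    def test_noise_importance_near_zero(self, fitted):
        X, y, res = fitted
        table = feature_importance(res, X, y, n_repeats=3, seed=0)
        noise = table.set_index("feature").loc[["noise_a", "noise_b"]]
        assert (noise["importance"].abs()
                <= 5 * noise["importance_std"] + 0.05).all()

    def test_constant_column_importance_exactly_zero(self, fitted):
        X, y, res = fitted
        table = feature_importance(res, X, y, n_repeats=3, seed=0)
        assert table.set_index("feature").loc["flat", "importance"] == 0.0

    def test_repeat_parameter_validated(self, fitted):
        X, y, res = fitted
        with pytest.raises(ValueError):
            feature_importance(res, X, y, n_repeats=1)


def test_train_test_report_shapes(synth_small):
    rep = train_test_report(synth_small.features, synth_small.ddg_true,
                            synth_small.classes, seed=0,
                            encoder_spec=EncoderSpec(hidden_dim=16, epochs=40),
                            n_features=5)
    assert rep["n_train"] + rep["n_test"] == len(synth_small.ddg_true)
    assert rep["train"]["pcc"] > rep["test"]["pcc"] - 0.3
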
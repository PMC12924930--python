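import math

import numpy as np
import pandas as pd
import pytest

import tilgraph.modeling as modeling
from tilgraph.modeling import (
    ClinicalEncoder,
    ModelBundle,
    collinearity_filter,
    cv_auc,
    feature_cap,
    make_classifier,
    sffs_select,
    smote_oversample,
    stratified_split,
    theils_u,
    train_model,
    tune_hyperparameters,
    zscore_apply,
    zscore_fit,
)

# ---------------------------------------------------------------------------
# Theil's U
# ---------------------------------------------------------------------------


class TestTheilsU:
    def test_identical_columns(self):
        x = np.array(["a", "b", "a", "c", "b"])
        assert theils_u(x, x) == 1.0

    def test_independent_balanced(self):
        x = np.array(["a", "a", "b", "b"])
        y = np.array(["u", "v", "u", "v"])
        assert theils_u(x, y) == pytest.approx(0.0, abs=1e-12)

    def test_three_by_two_table_vs_hand_entropy(self):
        # counts {{20,10},{5,25},{10,10}}
        x = np.repeat(["r1", "r2", "r3"], [30, 30, 20])
        y = np.concatenate([
            np.repeat(["c1", "c2"], [20, 10]),
            np.repeat(["c1", "c2"], [5, 25]),
            np.repeat(["c1", "c2"], [10, 10]),
        ])
        # brute-force entropy computation straight from the table
        n = 80
        px = np.array([30, 30, 20]) / n
        hx = -(px * np.log(px)).sum()
        hxy = 0.0
        for col, total in (("c1", 35), ("c2", 45)):
            counts = {"c1": np.array([20, 5, 10]), "c2": np.array([10, 25, 10])}[col]
            p = counts / total
            p = p[p > 0]
            hxy += (total / n) * (-(p * np.log(p)).sum())
        assert theils_u(x, y) == pytest.approx((hx - hxy) / hx)

    def test_constant_x_is_one(self):
        assert theils_u(np.array(["a", "a"]), np.array(["u", "v"])) == 1.0


# ---------------------------------------------------------------------------
# Collinearity filter
# ---------------------------------------------------------------------------


class TestCollinearity:
    def test_duplicate_column_removed_once(self):
        rng = np.random.default_rng(0)
        a = rng.normal(size=40)
        df = pd.DataFrame({"a": a, "a_copy": a, "b": rng.normal(size=40)})
        y = (a + rng.normal(0, 0.5, 40) > 0).astype(int)
        keep = collinearity_filter(df, y)
        assert keep.sum() == 2
        assert keep[2]  # unrelated column untouched

    def test_less_relevant_member_removed(self):
        rng = np.random.default_rng(1)
        y = rng.integers(0, 2, size=200)
        strong = y * 1.0 + rng.normal(0, 0.8, 200)
        weak = strong + rng.normal(0, 0.25, 200) - y * 0.9  # correlated, weaker link
        r = np.corrcoef(strong, weak)[0, 1]
        assert r > 0.7
        df = pd.DataFrame({"weak": weak, "strong": strong})
        keep = collinearity_filter(df, y, threshold=min(0.9, r - 0.01))
        assert list(keep) == [False, True]

    def test_identical_nominal_columns(self):
        x = np.array(["a", "b", "c"] * 10)
        df = pd.DataFrame({"n1": x, "n2": x})
        y = np.tile([0, 1], 15)
        keep = collinearity_filter(df, y, types={"n1": "nominal", "n2": "nominal"})
        assert keep.sum() == 1

    def test_constant_column_dropped_with_warning(self):
        df = pd.DataFrame({"c": np.ones(20), "x": np.arange(20.0)})
        with pytest.warns(UserWarning):
            keep = collinearity_filter(df, np.tile([0, 1], 10))
        assert list(keep) == [False, True]

    def test_deterministic(self):
        rng = np.random.default_rng(2)
        df = pd.DataFrame(rng.normal(size=(50, 6)), columns=list("abcdef"))
        y = rng.integers(0, 2, size=50)
        assert np.array_equal(collinearity_filter(df, y), collinearity_filter(df, y))


# ---------------------------------------------------------------------------
# Z-score
# ---------------------------------------------------------------------------


class TestZscore:
    def test_population_parameters(self):
        mu, sigma = zscore_fit(np.array([[2.0], [4.0], [6.0]]))
        assert mu[0] == 4.0
        assert sigma[0] == pytest.approx(math.sqrt(8 / 3))  # ~1.633
        assert zscore_apply(np.array([[4.0]]), mu, sigma)[0, 0] == 0.0

    def test_train_transform_is_standard(self):
        rng = np.random.default_rng(3)
        x = rng.normal(5, 3, size=(50, 4))
        mu, sigma = zscore_fit(x)
        z = zscore_apply(x, mu, sigma)
        assert np.allclose(z.mean(axis=0), 0, atol=1e-12)
        assert np.allclose(z.std(axis=0), 1, atol=1e-12)

    def test_shifted_test_split_nonzero_mean(self):
        rng = np.random.default_rng(4)
        train = rng.normal(0, 1, size=(100, 1))
        test = rng.normal(2, 1, size=(50, 1))  # shifted distribution
        mu, sigma = zscore_fit(train)
        z_test = zscore_apply(test, mu, sigma)
        assert abs(z_test.mean()) > 1.0

    def test_zero_variance_warns(self):
        with pytest.warns(UserWarning):
            mu, sigma = zscore_fit(np.array([[1.0], [1.0]]))
        assert sigma[0] == 1.0


# ---------------------------------------------------------------------------
# Split and cap
# ---------------------------------------------------------------------------


class TestSplitAndCap:
    def test_tnbc_sizes(self):
        y = np.array([1] * 30 + [0] * 55)  # n = 85
        tr, te = stratified_split(y, seed=0)
        assert len(tr) == 68 and len(te) == 17

    def test_her2_sizes(self):
        y = np.array([1] * 37 + [0] * 19)  # n = 56
        tr, te = stratified_split(y, seed=0)
        assert len(tr) == 44 and len(te) == 12

    def test_small_balanced(self):
        y = np.tile([0, 1], 5)
        tr, te = stratified_split(y, seed=1)
        assert len(tr) == 8 and len(te) == 2
        assert set(y[te]) == {0, 1}

    def test_disjoint_exhaustive_stratified(self):
        rng = np.random.default_rng(5)
        y = rng.integers(0, 2, size=100)
        tr, te = stratified_split(y, seed=2)
        assert len(set(tr) & set(te)) == 0
        assert len(tr) + len(te) == 100
        assert abs(y[tr].mean() - y.mean()) < 0.02

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            stratified_split(np.ones(10, dtype=int))

    @pytest.mark.parametrize("n,cap", [(68, 7), (44, 4), (100, 10), (9, 1), (45, 5)])
    def test_feature_cap(self, n, cap):
        assert feature_cap(n) == cap


# ---------------------------------------------------------------------------
# SMOTE
# ---------------------------------------------------------------------------


class TestSmote:
    def test_balances_20_vs_80(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=(100, 3))
        y = np.array([1] * 20 + [0] * 80)
        xb, yb = smote_oversample(x, y, seed=0)
        assert (yb == 1).sum() == 80 and (yb == 0).sum() == 80

    def test_synthetic_points_on_minority_segments(self):
        rng = np.random.default_rng(7)
        x = np.vstack([rng.uniform(0, 1, size=(10, 2)), rng.uniform(5, 6, size=(40, 2))])
        y = np.array([1] * 10 + [0] * 40)
        xb, yb = smote_oversample(x, y, seed=1)
        minority = x[:10]
        for row in xb[50:]:
            dists = []
            for i in range(10):
                for j in range(10):
                    if i != j:
                        dists.append(_point_segment_distance(row, minority[i], minority[j]))
            assert min(dists) < 1e-9

    def test_deterministic(self):
        rng = np.random.default_rng(8)
        x = rng.normal(size=(30, 2))
        y = np.array([1] * 10 + [0] * 20)
        a = smote_oversample(x, y, seed=3)
        b = smote_oversample(x, y, seed=3)
        assert np.array_equal(a[0], b[0])

    def test_k_reduced_with_warning(self):
        x = np.random.default_rng(9).normal(size=(13, 2))
        y = np.array([1] * 3 + [0] * 10)
        with pytest.warns(UserWarning):
            xb, yb = smote_oversample(x, y, k_neighbors=5, seed=0)
        assert (yb == 1).sum() == 10


def _point_segment_distance(p, a, b):
    ab = b - a
    t = np.clip(np.dot(p - a, ab) / (ab @ ab), 0, 1)
    return np.linalg.norm(p - (a + t * ab))


# ---------------------------------------------------------------------------
# SFFS
# ---------------------------------------------------------------------------


class TestSffs:
    def test_cap_one(self):
        rng = np.random.default_rng(10)
        x = rng.normal(size=(40, 5))
        y = rng.integers(0, 2, size=40)
        y[:2] = [0, 1]
        res = sffs_select(x, y, cap=1, folds=5, iterations=3, seed=0)
        assert len(res.selected) == 1

    def test_planted_feature_dominates(self):
        rng = np.random.default_rng(11)
        n = 60
        y = np.repeat([1, 0], [20, 40])
        x = rng.normal(size=(n, 8))
        x[:, 2] += y * 2.4  # single informative feature, AUC ~ 0.95
        res = sffs_select(x, y, kind="gnb", cap=2, folds=10, iterations=20, seed=0)
        assert res.candidate_frequencies[2] >= 18
        assert 2 in res.selected

    def test_noise_selection_is_exchangeable(self):
        # With pure-noise features, selection frequency concentrates on
        # whichever feature is spuriously correlated in a given sample, so a
        # per-sample binomial band does not hold. The exchangeability claim
        # that does hold: across independently redrawn noise datasets, a
        # PRE-SPECIFIED feature is selected no more often than the binomial
        # 99th percentile under uniform selection.
        from scipy.stats import binom

        p, cap, datasets, iters = 8, 2, 12, 3
        hits = 0
        for d in range(datasets):
            rng = np.random.default_rng(100 + d)
            x = rng.normal(size=(40, p))
            y = np.repeat([1, 0], 20)
            res = sffs_select(x, y, kind="gnb", cap=cap, folds=5,
                              iterations=iters, seed=d)
            hits += res.candidate_frequencies[0]
        assert hits <= binom.ppf(0.99, datasets * iters, cap / p)

    def test_frequencies_bounded_by_iterations(self):
        rng = np.random.default_rng(12)
        x = rng.normal(size=(30, 4))
        y = np.tile([0, 1], 15)
        res = sffs_select(x, y, cap=2, folds=5, iterations=5, seed=1)
        assert all(0 <= f <= 5 for f in res.candidate_frequencies.values())
        assert len(res.selected) <= res.cap


# ---------------------------------------------------------------------------
# Tuning
# ---------------------------------------------------------------------------


class TestTuning:
    def test_budget_zero_returns_defaults(self):
        x = np.random.default_rng(13).normal(size=(30, 2))
        y = np.tile([0, 1], 15)
        assert tune_hyperparameters(x, y, "knn", budget=0) == {}

    def test_budget_one_returns_single_sample(self):
        rng = np.random.default_rng(14)
        x = rng.normal(size=(40, 2))
        y = np.tile([0, 1], 20)
        params = tune_hyperparameters(x, y, "knn", budget=1, folds=5, seed=5)
        rng2 = np.random.default_rng(5)
        assert params == modeling._sample_params("knn", rng2)

    def test_knn_tuned_beats_extreme_k(self):
        rng = np.random.default_rng(15)
        y = np.repeat([1, 0], 30)
        x = rng.normal(y[:, None] * 3.0, 1.0, size=(60, 2))
        tuned = tune_hyperparameters(x, y, "knn", budget=10, folds=5, seed=1)
        auc_tuned = cv_auc(x, y, "knn", tuned, folds=5, seed=2)
        auc_big_k = cv_auc(x, y, "knn", {"n_neighbors": 30}, folds=5, seed=2)
        assert auc_tuned >= auc_big_k

    def test_deterministic(self):
        rng = np.random.default_rng(16)
        x = rng.normal(size=(40, 3))
        y = np.tile([0, 1], 20)
        a = tune_hyperparameters(x, y, "svm", budget=5, folds=5, seed=7)
        b = tune_hyperparameters(x, y, "svm", budget=5, folds=5, seed=7)
        assert a == b


# ---------------------------------------------------------------------------
# Clinical encoding
# ---------------------------------------------------------------------------


class TestClinicalEncoder:
    def _table(self):
        return pd.DataFrame({
            "age": [40.0, 60.0, 55.0],
            "menopausal_status": ["pre", "post", "peri"],
            "er_status": ["negative", "positive", "positive"],
            "nottingham_grade": [1, 3, 2],
        })

    def test_encoding_shapes(self):
        enc = ClinicalEncoder().fit(self._table())
        out = enc.transform(self._table())
        assert "age" in out and "nottingham_grade" in out
        assert "menopausal_status=pre" in out or "menopausal_status=post" in out
        assert set(out["er_status"]) == {0, 1}

    def test_unseen_level_maps_to_reference_with_warning(self):
        enc = ClinicalEncoder().fit(self._table())
        new = self._table()
        new.loc[0, "menopausal_status"] = "unknown"
        with pytest.warns(UserWarning):
            out = enc.transform(new)
        onehots = [c for c in out if c.startswith("menopausal_status=")]
        assert out.loc[0, onehots].sum() == 0


# ---------------------------------------------------------------------------
# train_model and leakage audit
# ---------------------------------------------------------------------------


def _separable(n=40, p=4, seed=17):
    rng = np.random.default_rng(seed)
    y = np.repeat([1, 0], n // 2)
    x = rng.normal(y[:, None] * 8.0, 1.0, size=(n, p))
    cols = [f"f{i}" for i in range(p)]
    return pd.DataFrame(x, columns=cols), y


class TestTrainModel:
    @pytest.mark.parametrize("kind", ["gnb", "knn", "lr", "rfc", "svm", "xgb"])
    def test_separable_training_auc_one(self, kind):
        from tilgraph.ensemble import roc_auc

        df, y = _separable()
        bundle = train_model(df, y, classifier_kind=kind, selection_iterations=2,
                             tuning_budget=0, folds=5, seed=0)
        assert roc_auc(bundle.predict_proba(df), y) == 1.0

    def test_permuted_labels_cv_auc_near_half(self):
        rng = np.random.default_rng(18)
        x = rng.normal(size=(60, 5))
        aucs = []
        for seed in range(20):
            y = np.repeat([1, 0], 30)
            np.random.default_rng(seed).shuffle(y)
            aucs.append(cv_auc(x, y, "gnb", folds=5, seed=seed))
        assert 0.35 < np.mean(aucs) < 0.65

    def test_bundle_roundtrip(self, tmp_path):
        df, y = _separable()
        bundle = train_model(df, y, classifier_kind="lr", selection_iterations=2,
                             tuning_budget=2, folds=5, seed=1)
        path = tmp_path / "bundle.joblib"
        bundle.save(path)
        loaded = ModelBundle.load(path)
        probe, _ = _separable(seed=99)
        assert np.array_equal(bundle.predict_proba(probe), loaded.predict_proba(probe))
        assert (tmp_path / "bundle.joblib.json").exists()

    def test_probabilities_valid(self):
        df, y = _separable()
        bundle = train_model(df, y, classifier_kind="rfc", selection_iterations=2,
                             tuning_budget=0, folds=5, seed=2)
        p = bundle.predict_proba(df)
        assert ((p >= 0) & (p <= 1)).all()


class TestLeakage:
    def test_adversarial_outlier(self):
        rng = np.random.default_rng(19)
        cols = [f"f{i}" for i in range(3)]
        train = pd.DataFrame(rng.normal(size=(40, 3)), columns=cols)
        test = pd.DataFrame(rng.normal(size=(10, 3)), columns=cols)
        outlier = pd.DataFrame([[250.0, -300.0, 500.0]], columns=cols)
        y_train = np.tile([0, 1], 20)

        bundle_a = train_model(train, y_train, selection_iterations=1,
                               tuning_budget=0, folds=5, seed=3)
        # outlier sitting in the *test* data must not move the fitted stats
        _ = bundle_a.predict_proba(pd.concat([test, outlier]))
        bundle_b = train_model(train, y_train, selection_iterations=1,
                               tuning_budget=0, folds=5, seed=3)
        assert np.array_equal(bundle_a.mu, bundle_b.mu)
        assert np.array_equal(bundle_a.sigma, bundle_b.sigma)
        # moving it into training must change them
        train_with = pd.concat([train, outlier], ignore_index=True)
        y_with = np.concatenate([y_train, [1]])
        bundle_c = train_model(train_with, y_with, selection_iterations=1,
                               tuning_budget=0, folds=5, seed=3)
        assert not np.allclose(bundle_a.mu, bundle_c.mu)
        assert not np.allclose(bundle_a.sigma, bundle_c.sigma)

    def test_zscore_params_derive_from_train_only(self):
        df, y = _separable()
        bundle = train_model(df, y, selection_iterations=1, tuning_budget=0,
                             folds=5, seed=4)
        kept = [c for c, k in zip(bundle.columns, bundle.keep_mask) if k]
        mu, sigma = zscore_fit(df[kept].to_numpy())
        assert np.allclose(bundle.mu, mu)
        assert np.allclose(bundle.sigma, sigma)

    def test_smote_applied_inside_training_folds_only(self, monkeypatch):
        calls = []
        real = modeling.smote_oversample

        def spy(x, y, *args, **kwargs):
            calls.append(len(x))
            return real(x, y, *args, **kwargs)

        monkeypatch.setattr(modeling, "smote_oversample", spy)
        rng = np.random.default_rng(20)
        x = rng.normal(size=(50, 3))
        y = np.array([1] * 15 + [0] * 35)
        cv_auc(x, y, "gnb", folds=5, seed=0)
        assert len(calls) == 5
        # each call saw one training fold (40 rows), never the full data
        assert all(c == 40 for c in calls)
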
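"""Splits, model fitting, RFE feature selection, ECOD outlier exclusion."""

import numpy as np
import pytest

from esipt_screen.featurize import FeatureMatrix
from esipt_screen.mlcore import (
    ModelConfig,
    ecod_outliers,
    ecod_scores,
    fit,
    make_split,
    rfe_select,
)


def _fm(values, kind="DESC2D", prefix="s"):
    values = np.asarray(values, dtype=float)
    return FeatureMatrix(
        molecule_ids=[f"{prefix}{i}" for i in range(values.shape[0])],
        feature_names=[f"f{j}" for j in range(values.shape[1])],
        values=values, kind=kind,
    )


class TestSplit:
    def test_split_arithmetic(self):
        ids = [f"m{i}" for i in range(100)]
        labels = ["A"] * 50 + ["B"] * 50
        plan = make_split(ids, labels, seed=7)
        assert len(plan.train_ids) == 75 and len(plan.test_ids) == 25
        assert len(plan.cv_folds) == 5
        assert all(len(va) == 15 for _, va in plan.cv_folds)

    def test_deterministic_under_seed(self):
        ids = [f"m{i}" for i in range(60)]
        labels = ["A", "B"] * 30
        a = make_split(ids, labels, seed=3)
        b = make_split(ids, labels, seed=3)
        assert a.train_ids == b.train_ids and a.test_ids == b.test_ids
        assert a.cv_folds == b.cv_folds

    def test_folds_partition_training_ids(self):
        ids = [f"m{i}" for i in range(80)]
        plan = make_split(ids, None, seed=1)
        val_ids = [m for _, va in plan.cv_folds for m in va]
        assert sorted(val_ids) == sorted(plan.train_ids)

    def test_stratification_within_one_sample(self):
        ids = [f"m{i}" for i in range(100)]
        labels = ["A"] * 40 + ["B"] * 60
        plan = make_split(ids, labels, seed=5)
        lab = dict(zip(ids, labels))
        test_a = sum(lab[m] == "A" for m in plan.test_ids)
        assert abs(test_a - 10) <= 1
        for _, va in plan.cv_folds:
            frac = sum(lab[m] == "A" for m in va) / len(va)
            assert abs(frac * len(va) - 0.4 * len(va)) <= 1

    def test_small_class_raises(self):
        ids = [f"m{i}" for i in range(20)]
        labels = ["A"] * 17 + ["B"] * 3
        with pytest.raises(ValueError, match="fewer than"):
            make_split(ids, labels, k=5, seed=0)


class TestFit:
    def _separable(self, n=80, seed=0):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(n, 2))
        X[: n // 2] += 6.0
        y = ["pos"] * (n // 2) + ["neg"] * (n // 2)
        return _fm(X), y

    def test_separable_data_perfect_test_accuracy(self):
        X, y = self._separable()
        plan = make_split(X.molecule_ids, y, seed=0)
        cfg = ModelConfig("RF", "classify", {"n_estimators": 50}, seed=0)
        model, report = fit(cfg, X, y, plan, positive_label="pos")
        assert report.test.ACC == 1.0

    def test_permuted_labels_give_chance_auc(self):
        """Null model: label permutation destroys signal, CV AUC ~ 0.5."""
        X, y = self._separable(n=120, seed=1)
        rng = np.random.default_rng(11)
        aucs = []
        for rep in range(20):
            y_perm = list(rng.permutation(y))
            plan = make_split(X.molecule_ids, y_perm, seed=rep)
            cfg = ModelConfig("DT", "classify", {"max_depth": 3}, seed=rep)
            _, report = fit(cfg, X, y_perm, plan, positive_label="pos")
            aucs.append(report.cv_mean["AUC"])
        assert abs(np.mean(aucs) - 0.5) <= 0.1

    def test_reproducible_under_seed(self):
        X, y = self._separable(seed=2)
        plan = make_split(X.molecule_ids, y, seed=2)
        for alg in ("RF", "SVM"):
            cfg = ModelConfig(alg, "classify", {"n_estimators": 30} if alg == "RF" else {}, seed=2)
            m1, _ = fit(cfg, X, y, plan, positive_label="pos")
            m2, _ = fit(cfg, X, y, plan, positive_label="pos")
            assert np.array_equal(
                m1.predict_proba_positive(X), m2.predict_proba_positive(X)
            )

    def test_single_class_labels_error(self):
        X, _ = self._separable()
        y = ["pos"] * X.n_molecules
        with pytest.raises(ValueError):
            plan = make_split(X.molecule_ids, y, seed=0)
            fit(ModelConfig("RF", "classify", seed=0), X, y, plan)

    def test_nonfinite_features_error(self):
        X, y = self._separable()
        X.values[0, 0] = np.nan
        plan = make_split(X.molecule_ids, None, seed=0)
        with pytest.raises(ValueError, match="non-finite"):
            fit(ModelConfig("RF", "classify", seed=0), X, y, plan)

    def test_manifest_mismatch_refused(self):
        X, y = self._separable()
        plan = make_split(X.molecule_ids, y, seed=0)
        cfg = ModelConfig("RF", "classify", {"n_estimators": 20}, seed=0)
        model, _ = fit(cfg, X, y, plan, positive_label="pos")
        wrong = FeatureMatrix(X.molecule_ids, ["g0", "g1"], X.values, kind="DESC2D")
        with pytest.raises(ValueError, match="manifest"):
            model.predict(wrong)

    def test_model_persistence_roundtrip(self, tmp_path):
        X, y = self._separable()
        plan = make_split(X.molecule_ids, y, seed=0)
        cfg = ModelConfig("RF", "classify", {"n_estimators": 20}, seed=0)
        model, _ = fit(cfg, X, y, plan, positive_label="pos")
        from esipt_screen.mlcore import TrainedModel
        path = tmp_path / "model.joblib"
        model.save(path)
        back = TrainedModel.load(path)
        assert back.feature_names == model.feature_names
        assert np.array_equal(
            back.predict_proba_positive(X), model.predict_proba_positive(X)
        )


class TestRFE:
    def _planted(self, seed, n=300, informative=5, noise=20):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(n, informative + noise))
        w = rng.uniform(1, 2, informative)
        y = X[:, :informative] @ w + rng.normal(0, 0.5, n)
        names = [f"inf{j}" for j in range(informative)] + [f"noise{j}" for j in range(noise)]
        fm = FeatureMatrix([f"s{i}" for i in range(n)], names, X, kind="DESC2D")
        return fm, y

    def test_identity_when_target_equals_n_features(self):
        fm, y = self._planted(0, n=50)
        cfg = ModelConfig("RF", "regress", {"n_estimators": 20}, seed=0)
        assert rfe_select(cfg, fm, y, target_n=25) == fm.feature_names

    def test_recovers_planted_informative_features(self):
        hits = 0
        for seed in range(3):
            fm, y = self._planted(seed)
            cfg = ModelConfig("RF", "regress", {"n_estimators": 60}, seed=seed)
            selected = rfe_select(cfg, fm, y, target_n=5)
            hits += sum(1 for s in selected if s.startswith("inf")) >= 4
        assert hits == 3

    def test_single_informative_feature_survives_to_one(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(200, 6))
        y = 3 * X[:, 2] + rng.normal(0, 0.1, 200)
        fm = _fm(X)
        cfg = ModelConfig("RF", "regress", {"n_estimators": 60}, seed=4)
        assert rfe_select(cfg, fm, y, target_n=1) == ["f2"]

    def test_nested_subsets_under_same_seed(self):
        fm, y = self._planted(5)
        cfg = ModelConfig("RF", "regress", {"n_estimators": 40}, seed=5)
        bigger = set(rfe_select(cfg, fm, y, target_n=10))
        smaller = set(rfe_select(cfg, fm, y, target_n=9))
        assert smaller < bigger

    def test_importance_free_algorithm_unsupported(self):
        fm, y = self._planted(6, n=60)
        cfg = ModelConfig("KNN", "regress", seed=6)
        with pytest.raises(TypeError, match="importance"):
            rfe_select(cfg, fm, y, target_n=5)


class TestECOD:
    def test_extreme_point_top_scored(self):
        x = np.zeros((50, 1))
        x[-1] = 100.0
        _, _, scores = ecod_outliers(x, contamination=0.05)
        assert max(scores, key=scores.get) == "49"

    def test_planted_outliers_flagged(self):
        rng = np.random.default_rng(0)
        X = np.vstack([rng.normal(0, 1, (95, 5)), rng.normal(0, 1, (5, 5)) + 8.0])
        _, outliers, _ = ecod_outliers(X, contamination=0.05)
        assert set(outliers) == {str(i) for i in range(95, 100)}

    def test_scores_match_independent_ecdf_oracle(self):
        from scipy.stats import skew

        rng = np.random.default_rng(1)
        X = rng.normal(size=(30, 3))

        def oracle(X):
            n, d = X.shape
            o_l = np.zeros(n)
            o_r = np.zeros(n)
            o_a = np.zeros(n)
            for j in range(d):
                sk = skew(X[:, j])
                for i in range(n):
                    left = sum(X[k, j] <= X[i, j] for k in range(n)) / n
                    right = sum(X[k, j] >= X[i, j] for k in range(n)) / n
                    o_l[i] += -np.log(left)
                    o_r[i] += -np.log(right)
                    o_a[i] += -np.log(left) if sk < 0 else -np.log(right)
            return np.maximum(np.maximum(o_l, o_r), o_a)

        assert np.array_equal(ecod_scores(X), oracle(X))

    def test_contamination_bounds(self):
        X = np.random.default_rng(2).normal(size=(20, 2))
        for bad in (0.0, 0.6, -0.1):
            with pytest.raises(ValueError):
                ecod_outliers(X, contamination=bad)

    def test_minimum_sample_size(self):
        with pytest.raises(ValueError, match="at least 10"):
            ecod_outliers(np.zeros((5, 2)), contamination=0.1)
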
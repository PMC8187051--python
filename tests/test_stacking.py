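import numpy as np
import pytest

from mc4stack.config import StackConfig
from mc4stack.encoders import encode_set, get_scheme
from mc4stack.evaluation import roc_auc
from mc4stack.learners import LEARNERS, Learner, register_learner
from mc4stack.simulate import GeneratorConfig, generate
from mc4stack.stacking import (
    StackedEnsembleModel,
    StackedEnsembleResults,
    fit_stack,
    make_folds,
    oof_base_predictions,
    predict_stack,
)


class ConstantLearner(Learner):
    """Scores every row 0.7 regardless of the data."""

    name = "constant"

    def _fit(self, X, y, seed):
        pass

    def _score(self, X):
        return np.full(X.shape[0], 0.7)


class MemorizingLearner(Learner):
    """Scores 1.0 for rows seen at fit time, 0.0 otherwise (leakage sentinel)."""

    name = "memorizer"

    def _fit(self, X, y, seed):
        self.seen_ = {row.tobytes() for row in X}

    def _score(self, X):
        return np.array([1.0 if r.tobytes() in self.seen_ else 0.0 for r in X])


@pytest.fixture(autouse=True)
def _register_test_learners():
    register_learner("constant", ConstantLearner)
    register_learner("memorizer", MemorizingLearner)
    yield
    LEARNERS.pop("constant", None)
    LEARNERS.pop("memorizer", None)


@pytest.fixture(scope="module")
def encoded_small():
    train = generate(GeneratorConfig(n_pos=60, n_neg=60, seed=31, id_prefix="tr_"))
    test = generate(GeneratorConfig(n_pos=20, n_neg=20, seed=77, id_prefix="te_"))
    scheme = get_scheme("multifeature")
    X_tr, y_tr, _ = encode_set(train, scheme)
    X_te, y_te, _ = encode_set(test, scheme)
    return X_tr, y_tr, X_te, y_te


class TestMakeFolds:
    def test_balanced_twenty_instances_ten_folds(self):
        labels = np.array([0, 1] * 10)
        fa = make_folds(20, labels, k=10, seed=1)
        for fold in range(1, 11):
            held = fa.heldout_indices(fold)
            assert held.size == 2
            assert labels[held].sum() == 1  # one positive + one negative

    def test_deterministic_given_seed(self):
        labels = np.array([0, 1] * 30)
        a = make_folds(60, labels, k=10, seed=4)
        b = make_folds(60, labels, k=10, seed=4)
        np.testing.assert_array_equal(a.fold_of, b.fold_of)
        c = make_folds(60, labels, k=10, seed=5)
        assert not np.array_equal(a.fold_of, c.fold_of)

    def test_benchmark_sized_fold_sizes(self):
        labels = np.array([0, 1] * 746)
        fa = make_folds(1492, labels, k=10, seed=1)
        sizes = sorted(np.bincount(fa.fold_of)[1:])
        assert set(sizes) <= {149, 150}
        assert sum(sizes) == 1492

    def test_stratification_within_one_instance(self):
        rng = np.random.default_rng(0)
        labels = (rng.random(103) < 0.3).astype(int)
        fa = make_folds(103, labels, k=10, seed=2)
        global_rate = labels.mean()
        for fold in range(1, 11):
            held = fa.heldout_indices(fold)
            assert abs(labels[held].sum() - global_rate * held.size) <= 1

    def test_too_few_instances_rejected(self):
        with pytest.raises(ValueError):
            make_folds(5, np.array([0, 1, 0, 1, 0]), k=10)


class TestOOFBasePredictions:
    def test_no_leakage_with_memorizer(self, encoded_small):
        """A memorizer scores its own training rows 1.0; out-of-fold scores
        must therefore all be 0.0 — any 1.0 in A would be leakage."""
        X_tr, y_tr, X_te, _ = encoded_small
        folds = make_folds(len(y_tr), y_tr, k=5, seed=1)
        A, B, _ = oof_base_predictions(
            "memorizer", X_tr, y_tr, X_te, folds, seed=0
        )
        assert (A == 0.0).all()
        assert (B == 0.0).all()

    def test_constant_learner_propagates_exactly(self, encoded_small):
        X_tr, y_tr, X_te, _ = encoded_small
        folds = make_folds(len(y_tr), y_tr, k=5, seed=1)
        A, B, _ = oof_base_predictions(
            "constant", X_tr, y_tr, X_te, folds, seed=0
        )
        assert (A == 0.7).all()
        assert (B == 0.7).all()

    def test_B_is_fold_model_average(self, encoded_small):
        """Brute-force averaging oracle on a 3-row test set."""
        X_tr, y_tr, X_te, _ = encoded_small
        X_probe = X_te[:3]
        folds = make_folds(len(y_tr), y_tr, k=4, seed=2)
        A, B, fold_models = oof_base_predictions(
            "logistic", X_tr, y_tr, X_probe, folds, seed=0
        )
        manual = np.mean(
            [fm.learner.score(X_probe) for fm in fold_models], axis=0
        )
        np.testing.assert_allclose(B, manual, rtol=0, atol=1e-15)

    def test_fold_models_record_training_indices(self, encoded_small):
        X_tr, y_tr, _, _ = encoded_small
        folds = make_folds(len(y_tr), y_tr, k=5, seed=3)
        _, _, fold_models = oof_base_predictions(
            "logistic", X_tr, y_tr, None, folds, seed=0
        )
        for fm in fold_models:
            held = folds.heldout_indices(fm.fold)
            assert np.intersect1d(fm.train_index, held).size == 0
            assert fm.train_index.size + held.size == folds.n


class TestFitStack:
    def test_meta_matrix_shapes_default_four_bases(self, encoded_small):
        X_tr, y_tr, X_te, _ = encoded_small
        cfg = StackConfig(k=5)
        ensemble, A, B = fit_stack(X_tr, y_tr, X_te, config=cfg)
        assert A.values.shape == (len(y_tr), 4)
        assert B.values.shape == (X_te.shape[0], 4)
        assert A.role == "train" and B.role == "test"
        assert ensemble.base_names == (
            "bayesnet", "nb_multinomial", "svm", "voted_perceptron"
        )

    def test_no_leakage_invariant_instrumented(self, encoded_small):
        """Machine-check: every A[i, b] comes from the fold model whose
        training index set excludes instance i."""
        X_tr, y_tr, _, _ = encoded_small
        cfg = StackConfig(k=5, base_learners=[("logistic", {}), ("constant", {})])
        ensemble, A, _ = fit_stack(X_tr, y_tr, config=cfg)
        for name in ensemble.base_names:
            for fm in ensemble.fold_models[name]:
                held = ensemble.folds.heldout_indices(fm.fold)
                assert np.intersect1d(fm.train_index, held).size == 0

    def test_determinism_full_stack(self, encoded_small):
        X_tr, y_tr, X_te, _ = encoded_small
        cfg = StackConfig(
            k=5,
            base_learners=[("logistic", {}), ("voted_perceptron", {}),
                           ("bayesnet", {})],
        )
        e1, A1, B1 = fit_stack(X_tr, y_tr, X_te, config=cfg)
        e2, A2, B2 = fit_stack(X_tr, y_tr, X_te, config=cfg)
        np.testing.assert_array_equal(A1.values, A2.values)
        np.testing.assert_array_equal(B1.values, B2.values)
        np.testing.assert_array_equal(e1.meta.coef_, e2.meta.coef_)

    def test_planted_oracle_column_lifts_stack(self):
        """One perfectly informative base among noise: stacked accuracy must
        track the informative one (within 0.05)."""
        rng = np.random.default_rng(6)
        n, m = 200, 100
        y_tr = np.array([0, 1] * (n // 2))
        y_te = np.array([0, 1] * (m // 2))
        # feature 0 carries the label; the rest are pure noise
        X_tr = np.column_stack([y_tr + 0.05 * rng.normal(size=n),
                                rng.normal(size=(n, 5))])
        X_te = np.column_stack([y_te + 0.05 * rng.normal(size=m),
                                rng.normal(size=(m, 5))])
        cfg = StackConfig(k=5, base_learners=[("logistic", {}), ("constant", {})])
        ensemble, _, _ = fit_stack(X_tr, y_tr, X_te, config=cfg)
        scores, labels = predict_stack(ensemble, X_te)
        base_acc = 1.0  # logistic on the oracle column is perfect here
        assert (labels == y_te).mean() >= base_acc - 0.05

    def test_fewer_than_two_bases_rejected(self, encoded_small):
        X_tr, y_tr, _, _ = encoded_small
        with pytest.raises(ValueError):
            StackedEnsembleModel(
                X_tr, y_tr, config=StackConfig(base_learners=[("logistic", {})])
            )


class TestPredictStack:
    def test_consistent_with_B_at_fit_time(self, encoded_small):
        X_tr, y_tr, X_te, _ = encoded_small
        cfg = StackConfig(k=5, base_learners=[("logistic", {}), ("bayesnet", {})])
        ensemble, _, B = fit_stack(X_tr, y_tr, X_te, config=cfg)
        scores, _ = predict_stack(ensemble, X_te)
        np.testing.assert_allclose(
            scores, ensemble.meta.score(B.values), atol=1e-12
        )

    def test_single_row_and_row_order_invariance(self, encoded_small):
        X_tr, y_tr, X_te, _ = encoded_small
        cfg = StackConfig(k=5, base_learners=[("logistic", {}), ("bayesnet", {})])
        ensemble, _, _ = fit_stack(X_tr, y_tr, config=cfg)
        s_one, l_one = predict_stack(ensemble, X_te[0])
        assert s_one.shape == (1,) and 0 <= s_one[0] <= 1
        s_fwd, _ = predict_stack(ensemble, X_te)
        s_rev, _ = predict_stack(ensemble, X_te[::-1])
        np.testing.assert_allclose(s_fwd, s_rev[::-1], atol=1e-15)

    def test_single_base_identity_meta_reduces_to_fold_average(self, encoded_small):
        """Stacking coherence: with one base and an identity-like meta the
        deployment path is exactly fold-averaged base scoring."""

        class IdentityMeta(Learner):
            name = "identity_meta"

            def _fit(self, X, y, seed):
                pass

            def _score(self, X):
                return X[:, 0]

        register_learner("identity_meta", IdentityMeta)
        try:
            X_tr, y_tr, X_te, _ = encoded_small
            cfg = StackConfig(
                k=5,
                base_learners=[("bayesnet", {}), ("constant", {})],
                meta_learner="identity_meta",
            )
            ensemble, _, B = fit_stack(X_tr, y_tr, X_te, config=cfg)
            scores, _ = predict_stack(ensemble, X_te)
            fold_avg = np.mean(
                [fm.learner.score(X_te) for fm in ensemble.fold_models["bayesnet"]],
                axis=0,
            )
            np.testing.assert_allclose(scores, fold_avg, atol=1e-15)
        finally:
            LEARNERS.pop("identity_meta", None)

    def test_dimension_mismatch_rejected(self, encoded_small):
        X_tr, y_tr, _, _ = encoded_small
        cfg = StackConfig(k=5, base_learners=[("logistic", {}), ("bayesnet", {})])
        ensemble, _, _ = fit_stack(X_tr, y_tr, config=cfg)
        with pytest.raises(ValueError):
            predict_stack(ensemble, np.ones((2, 7)))


class TestStackHelps:
    def test_stacked_auc_tracks_best_base(self):
        """Core stacking premise at desk scale: over several seeds the
        stacked AUC is not materially below the best single base's AUC."""
        stacked, best_base = [], []
        for seed in range(5):
            train = generate(GeneratorConfig(
                n_pos=60, n_neg=60, seed=100 + seed, id_prefix="tr_",
                motif_match_prob=0.95))
            test = generate(GeneratorConfig(
                n_pos=30, n_neg=30, seed=900 + seed, id_prefix="te_",
                motif_match_prob=0.95))
            scheme = get_scheme("multifeature")
            X_tr, y_tr, _ = encode_set(train, scheme)
            X_te, y_te, _ = encode_set(test, scheme)
            cfg = StackConfig(k=5, seed=seed + 1)
            ensemble, _, B = fit_stack(X_tr, y_tr, X_te, config=cfg)
            s, _ = predict_stack(ensemble, X_te)
            stacked.append(roc_auc(y_te, s)[0])
            best_base.append(
                max(roc_auc(y_te, B.values[:, b])[0]
                    for b in range(B.values.shape[1]))
            )
        assert np.mean(stacked) >= np.mean(best_base) - 0.02


class TestPersistence:
    def test_bundle_round_trip_bit_identical_scores(self, tmp_path, encoded_small):
        X_tr, y_tr, X_te, _ = encoded_small
        cfg = StackConfig(k=5, base_learners=[("logistic", {}),
                                              ("voted_perceptron", {})])
        ensemble, _, _ = fit_stack(X_tr, y_tr, config=cfg)
        before, _ = predict_stack(ensemble, X_te)
        ensemble.save(tmp_path / "bundle")
        loaded = StackedEnsembleResults.load(tmp_path / "bundle")
        after, _ = predict_stack(loaded, X_te)
        np.testing.assert_array_equal(before, after)
        assert loaded.base_names == ensemble.base_names
        assert loaded.config.to_dict() == cfg.to_dict()
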
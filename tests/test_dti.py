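"""DTI preprocessing, classifier training and evaluation."""

import numpy as np
import pandas as pd
import pytest

from gwgen.dti import (
    DTIConfig,
    DTIFeatureSet,
    balance_classes,
    binary_cross_entropy,
    build_pair_features,
    cross_validate,
    evaluate_scores,
    fit_preprocessing,
    kfold_indices,
    pair_blocks,
    predict_binding,
    reduce_dimensions,
    standardize,
    train_dti,
)


def _toy_feature_set():
    drugs = pd.DataFrame([[1.0, 2.0], [0.0, 0.0]], index=["d1", "d2"],
                         columns=["a", "b"])
    targets = pd.DataFrame([[3.0, 4.0, 5.0], [0.0, 0.0, 0.0]],
                           index=["t1", "t2"], columns=["x", "y", "z"])
    pairs = pd.DataFrame({"drug": ["d1", "d2"], "target": ["t1", "t2"],
                          "label": [1, 0]})
    return DTIFeatureSet(drugs, targets, pairs)


class TestPairFeatures:
    def test_concatenation_order_drug_block_first(self):
        fs = _toy_feature_set()
        v = build_pair_features(fs, "d1", "t1")
        np.testing.assert_array_equal(v, [1.0, 2.0, 3.0, 4.0, 5.0])

    def test_zero_descriptors_give_zero_vector(self):
        fs = _toy_feature_set()
        assert not build_pair_features(fs, "d2", "t2").any()

    def test_unknown_id_raises(self):
        fs = _toy_feature_set()
        with pytest.raises(KeyError):
            build_pair_features(fs, "ghost", "t1")


class TestStandardize:
    def test_training_transform_is_zero_mean_unit_sd(self):
        rng = np.random.default_rng(0)
        X = rng.normal(3, 5, size=(50, 4))
        Z, state = standardize(X)
        np.testing.assert_allclose(Z.mean(axis=0), 0, atol=1e-6)
        np.testing.assert_allclose(Z.std(axis=0), 1, atol=1e-6)

    def test_constant_column_maps_to_zero_with_warning(self):
        X = np.column_stack([np.ones(10), np.arange(10.0)])
        with pytest.warns(UserWarning, match="constant"):
            Z, _ = standardize(X)
        assert not Z[:, 0].any()

    def test_saved_state_applies_training_statistics(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(30, 3))
        _, state = standardize(X)
        Xnew = rng.normal(size=(5, 3))
        Z, _ = standardize(Xnew, state)
        np.testing.assert_allclose(Z, (Xnew - X.mean(0)) / X.std(0), atol=1e-12)


class TestBalanceClasses:
    def test_downsamples_negatives_to_parity(self):
        pairs = pd.DataFrame({
            "drug": [f"d{i}" for i in range(110)],
            "target": "t",
            "label": [1] * 10 + [0] * 100,
        })
        out = balance_classes(pairs, seed=4)
        assert (out.label == 1).sum() == 10
        assert (out.label == 0).sum() == 10

    def test_balanced_input_unchanged(self):
        pairs = pd.DataFrame({"drug": list("abcd"), "target": "t",
                              "label": [1, 1, 0, 0]})
        out = balance_classes(pairs, seed=0)
        assert len(out) == 4

    def test_same_seed_same_selection(self):
        pairs = pd.DataFrame({"drug": [f"d{i}" for i in range(60)], "target": "t",
                              "label": [1] * 10 + [0] * 50})
        a = balance_classes(pairs, seed=9)
        b = balance_classes(pairs, seed=9)
        pd.testing.assert_frame_equal(a, b)

    def test_single_class_rejected(self):
        pairs = pd.DataFrame({"drug": list("ab"), "target": "t", "label": [1, 1]})
        with pytest.raises(ValueError):
            balance_classes(pairs, seed=0)


class TestReduceDimensions:
    def test_planar_data_needs_two_components(self):
        rng = np.random.default_rng(2)
        basis = rng.normal(size=(2, 6))
        X = rng.normal(size=(100, 2)) @ basis
        Xz, st_ = standardize(X)
        state, _ = reduce_dimensions(Xz, Xz, st_, st_, variance_threshold=0.85)
        assert state.drug_pca.retained == 2
        assert state.drug_pca.explained_variance_ratio[:2].sum() == pytest.approx(1.0)

    def test_retention_matches_covariance_eigendecomposition(self):
        rng = np.random.default_rng(3)
        spectrum = 2.0 ** -np.arange(20)
        X = rng.normal(size=(200, 20)) * np.sqrt(spectrum)
        Xz, st_ = standardize(X)
        state, _ = reduce_dimensions(Xz, Xz, st_, st_, variance_threshold=0.85)
        Xc = Xz - Xz.mean(0)
        eig = np.sort(np.linalg.eigvalsh(Xc.T @ Xc))[::-1]
        ratio = eig / eig.sum()
        expected = int(np.argmax(np.cumsum(ratio) >= 0.85)) + 1
        assert state.drug_pca.retained == expected
        np.testing.assert_allclose(
            state.drug_pca.explained_variance_ratio, ratio, atol=1e-9
        )

    def test_threshold_one_keeps_every_informative_component(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(30, 5))
        Xz, st_ = standardize(X)
        state, _ = reduce_dimensions(Xz, Xz, st_, st_, variance_threshold=1.0)
        assert state.drug_pca.retained == 5

    def test_too_few_samples_rejected(self):
        X = np.ones((1, 3))
        _, st_ = standardize(np.ones((2, 3)))
        with pytest.raises(ValueError, match="2 samples"):
            reduce_dimensions(X, X, st_, st_)


class TestLossAndMetrics:
    def test_perfect_prediction_loss_is_zero(self):
        y = np.array([0.0, 1.0, 1.0])
        assert binary_cross_entropy(y, y) == pytest.approx(0.0, abs=1e-10)

    def test_tpr_from_confusion_counts(self):
        m = evaluate_scores(np.array([1, 1]), np.array([0.9, 0.1]))
        assert m.tp == 1 and m.fn == 1
        assert m.tpr == pytest.approx(0.5)

    def test_perfect_classifier_auc_one(self):
        y = np.array([0, 1, 0, 1])
        m = evaluate_scores(y, y.astype(float))
        assert m.auc == pytest.approx(1.0)
        assert m.fpr == pytest.approx(0.0)

    def test_hand_worked_confusion_table(self):
        y = np.array([1, 1, 1, 0, 0, 0])
        s = np.array([0.9, 0.6, 0.2, 0.7, 0.4, 0.1])
        m = evaluate_scores(y, s)
        assert (m.tp, m.fn, m.fp, m.tn) == (2, 1, 1, 2)
        assert m.tpr == pytest.approx(2 / 3)
        assert m.specificity == pytest.approx(2 / 3)
        assert m.fpr == pytest.approx(1 / 3)
        # hand ROC walk, descending scores: 1,0,1,0,1,0
        assert m.auc == pytest.approx(6 / 9)

    def test_auc_agrees_with_sklearn(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(5)
        y = rng.integers(0, 2, 200)
        s = rng.random(200)
        m = evaluate_scores(y, s)
        assert m.auc == pytest.approx(roc_auc_score(y, s), abs=1e-12)

    def test_single_class_auc_undefined(self):
        m = evaluate_scores(np.ones(4), np.linspace(0, 1, 4))
        assert m.auc is None


class TestTraining:
    @staticmethod
    def _separable(n=300, d=8, seed=6):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(n, d))
        w = rng.normal(size=d)
        y = (X @ w > 0).astype(float)
        return X, y

    def test_loss_decreases_on_separable_data(self):
        X, y = self._separable()
        cfg = DTIConfig(hidden_layers=(16, 8), epochs=150, batch_size=25,
                        dropout=0.1, learning_rate=0.01)
        model = train_dti(X, y, cfg, seed=0)
        assert model.loss_trace[-1] < model.loss_trace[0]
        assert model.accuracy_trace[-1] > 0.9

    def test_output_is_probability_and_deterministic(self):
        X, y = self._separable(n=100)
        cfg = DTIConfig(hidden_layers=(8,), epochs=5, batch_size=25)
        model = train_dti(X, y, cfg, seed=1)
        p1 = model.predict_proba(X)
        p2 = model.predict_proba(X)
        np.testing.assert_array_equal(p1, p2)
        assert np.all((p1 > 0) & (p1 < 1))

    def test_early_stopping_restores_best_parameters(self):
        X, y = self._separable(n=200)
        Xv, yv = self._separable(n=80, seed=7)
        cfg = DTIConfig(hidden_layers=(8,), epochs=60, batch_size=50, patience=3)
        model = train_dti(X, y, cfg, seed=2, validation=(Xv, yv))
        if model.stopped_epoch is not None:
            assert model.stopped_epoch < cfg.epochs - 1
        best = min(model.val_loss_trace)
        final = binary_cross_entropy(yv, model.predict_proba(Xv))
        assert final == pytest.approx(best, abs=1e-9)

    def test_folds_partition_data_exactly(self):
        folds = kfold_indices(103, 5, seed=3)
        flat = np.concatenate(folds)
        assert len(flat) == 103
        assert len(np.unique(flat)) == 103
        assert max(len(f) for f in folds) - min(len(f) for f in folds) <= 1

    def test_adam_optimizer_option(self):
        X, y = self._separable(n=200)
        cfg = DTIConfig(hidden_layers=(8,), epochs=40, batch_size=50,
                        optimizer="adam")
        model = train_dti(X, y, cfg, seed=4)
        assert model.accuracy_trace[-1] > 0.8


class TestPreprocessingPipeline:
    def test_no_leakage_state_fit_on_training_pairs_only(self, small_config):
        from gwgen.synthetic import generate_dti_data

        fs, _, _ = generate_dti_data(small_config)
        train = fs.pairs.iloc[: len(fs.pairs) // 2]
        state, X, y = fit_preprocessing(fs, train)
        D, _, _ = pair_blocks(fs, train)
        np.testing.assert_allclose(state.drug_standardization.mean, D.mean(0), atol=1e-12)
        # held-out transform equals the manual chain with training statistics
        test = fs.pairs.iloc[len(fs.pairs) // 2:]
        Dt, Tt, _ = pair_blocks(fs, test)
        manual = np.hstack([
            state.drug_pca.transform(state.drug_standardization.transform(Dt)),
            state.target_pca.transform(state.target_standardization.transform(Tt)),
        ])
        np.testing.assert_allclose(state.transform(Dt, Tt), manual, atol=1e-12)

    def test_predict_binding_roundtrip(self, small_config):
        from gwgen.synthetic import generate_dti_data

        fs, rule, _ = generate_dti_data(small_config)
        train = fs.pairs.iloc[:200]
        state, X, y = fit_preprocessing(fs, train)
        cfg = DTIConfig(hidden_layers=(32, 16), epochs=20, batch_size=50)
        model = train_dti(X, y, cfg, seed=5)
        # a known binder should outrank a known non-binder
        pos = fs.pairs[fs.pairs.label == 1].iloc[0]
        neg = fs.pairs[fs.pairs.label == 0].iloc[0]
        p_pos = predict_binding(model, state,
                                fs.drug_features.loc[pos.drug].to_numpy(),
                                fs.target_features.loc[pos.target].to_numpy())
        p_neg = predict_binding(model, state,
                                fs.drug_features.loc[neg.drug].to_numpy(),
                                fs.target_features.loc[neg.target].to_numpy())
        assert 0 < p_neg < p_pos < 1

    def test_cross_validation_disjoint_and_scored(self, small_config):
        from gwgen.synthetic import generate_dti_data

        fs, _, _ = generate_dti_data(small_config)
        state, X, y = fit_preprocessing(fs, fs.pairs)
        cfg = DTIConfig(hidden_layers=(32,), epochs=80, batch_size=30)
        cv = cross_validate(X, y, k=5, config=cfg, seed=6)
        flat = np.concatenate(cv.fold_indices)
        assert len(np.unique(flat)) == len(y)
        assert cv.mean_auc > 0.7
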
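"""Fold assignment, out-of-fold construction, and the stacking ensemble."""

import numpy as np
import pytest

from sixmastack.encoders import EncoderSpec, encode_dataset
from sixmastack.errors import (
    ConfigurationError,
    ContractError,
    DegenerateFoldError,
    SerializationError,
    StratificationError,
)
from sixmastack.evaluation import roc_auc
from sixmastack.stacking import (
    BaseLearnerSpec,
    assign_folds,
    fit_base_oof,
    fit_stacking,
    fit_stacking_matrix,
    load_model,
    meta_features_matrix,
    predict_label,
    predict_proba,
    predict_proba_matrix,
    save_model,
)


class TestAssignFolds:
    def test_balanced_stratified_folds(self):
        y = np.array([1] * 5 + [0] * 5)
        folds = assign_folds(y, K=5, seed=0)
        for f in range(1, 6):
            mask = folds.fold_ids == f
            assert mask.sum() == 2
            assert y[mask].sum() == 1  # one positive, one negative

    def test_fold_sizes_near_equal_for_n_11(self):
        y = np.array([1] * 6 + [0] * 5)
        folds = assign_folds(y, K=5, seed=1)
        sizes = sorted(np.bincount(folds.fold_ids)[1:].tolist())
        assert sizes == [2, 2, 2, 2, 3]

    def test_deterministic_given_seed(self):
        y = np.array([0, 1] * 20)
        a = assign_folds(y, K=4, seed=9)
        b = assign_folds(y, K=4, seed=9)
        assert np.array_equal(a.fold_ids, b.fold_ids)

    def test_k_larger_than_n_rejected(self):
        with pytest.raises(ConfigurationError):
            assign_folds(np.array([0, 1, 0]), K=5)

    def test_k_below_two_rejected(self):
        with pytest.raises(ConfigurationError):
            assign_folds(np.array([0, 1, 0, 1]), K=1)

    def test_small_class_under_stratification_rejected(self):
        y = np.array([1, 1, 0, 0, 0, 0, 0, 0])
        with pytest.raises(StratificationError):
            assign_folds(y, K=3, seed=0, stratified=True)


def oracle_oof_positive_rate(y, fold_ids):
    """Brute-force oracle: per sample, positive rate of its fold complement."""
    return np.array(
        [y[fold_ids != fold_ids[i]].mean() for i in range(len(y))]
    )


class TestFitBaseOof:
    def test_positive_rate_learner_matches_counting_oracle(self):
        rng = np.random.default_rng(21)
        for _ in range(20):
            n = int(rng.integers(20, 51))
            K = int(rng.integers(2, 6))
            n_pos = int(rng.integers(K, n - K + 1))
            y = np.zeros(n, dtype=int)
            y[rng.choice(n, n_pos, replace=False)] = 1
            X = rng.random((n, 4))
            folds = assign_folds(y, K=K, seed=int(rng.integers(100)))
            _, oof = fit_base_oof(BaseLearnerSpec("positive_rate"), X, y, folds)
            np.testing.assert_allclose(oof, oracle_oof_positive_rate(y, folds.fold_ids))

    def test_returns_k_fitted_models(self):
        y = np.array([0, 1] * 10)
        X = np.random.default_rng(0).random((20, 3))
        folds = assign_folds(y, K=5, seed=0)
        models, oof = fit_base_oof(BaseLearnerSpec("positive_rate"), X, y, folds)
        assert len(models) == 5
        assert oof.shape == (20,)

    def test_oof_purity_with_memorizing_learner(self):
        # the memorizer outputs 1 only for rows it trained on, so pure OOF
        # values must all be 0
        rng = np.random.default_rng(17)
        y = np.array([0, 1] * 15)
        X = rng.random((30, 5))
        folds = assign_folds(y, K=5, seed=3)
        _, oof = fit_base_oof(BaseLearnerSpec("memorizer"), X, y, folds)
        assert np.all(oof == 0.0)

    def test_separable_data_gives_perfect_oof_ranking(self, signal_dataset):
        X = encode_dataset(signal_dataset, [EncoderSpec("onehot")])
        y = signal_dataset.labels
        folds = assign_folds(y, K=5, seed=0)
        _, oof = fit_base_oof(BaseLearnerSpec("logistic_regression"), X, y, folds)
        auc, _ = roc_auc(y, oof)
        assert auc >= 0.98

    def test_degenerate_fold_raises_with_fold_number(self):
        y = np.array([1, 1, 1, 1, 1, 1, 0, 0])
        X = np.random.default_rng(1).random((8, 2))
        # fold 1's training complement (fold 2) holds only positives
        from sixmastack.stacking import FoldAssignment

        rigged = FoldAssignment(np.array([2, 2, 2, 1, 1, 1, 1, 1]), 2, 0, False)
        with pytest.raises(DegenerateFoldError, match="fold"):
            fit_base_oof(BaseLearnerSpec("positive_rate"), X, y, rigged)


class TestFitStacking:
    def test_model_shape_for_default_configuration(self, signal_dataset,
                                                   fast_base_specs,
                                                   fast_final_spec, onehot_eiip):
        model = fit_stacking(signal_dataset, onehot_eiip, fast_base_specs,
                             fast_final_spec, K=5, seed=0)
        assert model.n_base == 2
        assert model.K == 5
        assert all(len(m) == 5 for m in model.fold_models)
        assert model.training_length == 41

    def test_meta_feature_matrix_shape_single_learner(self):
        rng = np.random.default_rng(2)
        X = rng.random((20, 6))
        y = np.array([0, 1] * 10)
        model = fit_stacking_matrix(
            X, y, [BaseLearnerSpec("positive_rate")],
            BaseLearnerSpec("logistic_regression"), K=2, seed=0,
        )
        meta = meta_features_matrix(model, X)
        assert meta.shape == (20, 1)
        assert np.all((meta >= 0) & (meta <= 1))

    def test_constant_fold_models_average_into_meta_feature(self):
        rng = np.random.default_rng(4)
        X = rng.random((25, 3))
        y = np.array([0, 1] * 12 + [0])
        model = fit_stacking_matrix(
            X, y, [BaseLearnerSpec("positive_rate")],
            BaseLearnerSpec("logistic_regression"), K=5, seed=0,
        )
        from conftest import ConstantLearner

        model.fold_models[0] = [
            ConstantLearner(prob=p).fit(X, y) for p in (0.1, 0.2, 0.3, 0.4, 0.5)
        ]
        meta = meta_features_matrix(model, X)
        np.testing.assert_allclose(meta[:, 0], 0.3)

    def test_meta_columns_follow_base_spec_order(self):
        rng = np.random.default_rng(6)
        X = rng.random((30, 4))
        y = np.array([0, 1] * 15)
        specs = [
            BaseLearnerSpec("positive_rate"),
            BaseLearnerSpec("logistic_regression"),
        ]
        m_ab = fit_stacking_matrix(X, y, specs, BaseLearnerSpec("decision_tree"),
                                   K=3, seed=1)
        m_ba = fit_stacking_matrix(X, y, specs[::-1], BaseLearnerSpec("decision_tree"),
                                   K=3, seed=1)
        np.testing.assert_allclose(
            meta_features_matrix(m_ab, X), meta_features_matrix(m_ba, X)[:, ::-1]
        )

    def test_single_class_training_set_rejected(self):
        X = np.random.default_rng(0).random((10, 2))
        with pytest.raises(ConfigurationError):
            fit_stacking_matrix(
                X, np.ones(10, dtype=int), [BaseLearnerSpec("positive_rate")],
                BaseLearnerSpec("logistic_regression"), K=2, seed=0,
            )

    def test_end_to_end_determinism(self, signal_dataset, fast_base_specs,
                                    fast_final_spec, onehot_eiip):
        runs = [
            predict_proba(
                fit_stacking(signal_dataset, onehot_eiip, fast_base_specs,
                             fast_final_spec, K=3, seed=7),
                signal_dataset,
            )
            for _ in range(2)
        ]
        np.testing.assert_array_equal(runs[0], runs[1])


@pytest.fixture(scope="module")
def toy_model(signal_dataset):
    return fit_stacking(
        signal_dataset,
        [EncoderSpec("onehot")],
        [BaseLearnerSpec("logistic_regression", seed=0)],
        BaseLearnerSpec("logistic_regression", seed=0),
        K=3,
        seed=0,
    )


class TestPrediction:
    def test_probabilities_in_unit_interval(self, toy_model, signal_dataset):
        p = predict_proba(toy_model, signal_dataset)
        assert np.all((p >= 0) & (p <= 1))

    def test_training_positives_score_above_half(self, toy_model, signal_dataset):
        pos = signal_dataset.subset(np.nonzero(signal_dataset.labels == 1)[0][:10])
        assert np.all(predict_proba(toy_model, pos) > 0.5)

    def test_labels_consistent_with_probabilities(self, toy_model, signal_dataset):
        p = predict_proba(toy_model, signal_dataset)
        for threshold in (0.3, 0.5, 0.9):
            labels = predict_label(toy_model, signal_dataset, threshold)
            np.testing.assert_array_equal(labels, (p >= threshold).astype(int))

    def test_threshold_outside_unit_interval_rejected(self, toy_model, signal_dataset):
        for bad in (0.0, 1.0, -0.1, 1.5):
            with pytest.raises(ConfigurationError):
                predict_label(toy_model, signal_dataset, bad)

    def test_wrong_length_sequence_rejected(self, toy_model):
        from sixmastack.sequence_io import DnaSequence

        with pytest.raises(ContractError, match="length"):
            predict_proba(toy_model, [DnaSequence("short", "ACGT")])

    def test_feature_layout_mismatch_rejected(self, toy_model):
        with pytest.raises(ContractError):
            predict_proba_matrix(toy_model, np.zeros((3, 7)))


class TestSerialization:
    def test_roundtrip_preserves_predictions(self, tmp_path, signal_dataset):
        model = fit_stacking(
            signal_dataset, [EncoderSpec("eiip")],
            [BaseLearnerSpec("decision_tree", seed=0)],
            BaseLearnerSpec("logistic_regression", seed=0), K=3, seed=0,
        )
        probe = signal_dataset.subset(range(10))
        path = tmp_path / "model.joblib"
        save_model(model, path)
        reloaded = load_model(path)
        np.testing.assert_array_equal(
            predict_proba(model, probe), predict_proba(reloaded, probe)
        )
        assert reloaded.encoder_specs == model.encoder_specs

    def test_reloaded_model_keeps_length_contract(self, tmp_path, signal_dataset):
        model = fit_stacking(
            signal_dataset, [EncoderSpec("nac")],
            [BaseLearnerSpec("positive_rate")],
            BaseLearnerSpec("logistic_regression"), K=2, seed=0,
        )
        path = tmp_path / "model.joblib"
        save_model(model, path)
        from sixmastack.sequence_io import DnaSequence

        with pytest.raises(ContractError):
            predict_proba(load_model(path), [DnaSequence("s", "ACGT")])

    def test_corrupted_file_raises_serialization_error(self, tmp_path):
        path = tmp_path / "bad.joblib"
        path.write_bytes(b"not a joblib archive")
        with pytest.raises(SerializationError):
            load_model(path)

    def test_foreign_payload_raises_serialization_error(self, tmp_path):
        import joblib

        path = tmp_path / "foreign.joblib"
        joblib.dump({"something": "else"}, path)
        with pytest.raises(SerializationError):
            load_model(path)
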
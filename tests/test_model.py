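import numpy as np
import pytest

from cnvpatho.annotate import FeatureMatrix, apply_impute, fit_impute
from cnvpatho.core import CNVType, Label
from cnvpatho.metrics import roc_auc
from cnvpatho.model import (Hyperparameters, TaskSpec, TrainedModel,
                            cv_objective, predict, split_dataset, train_model,
                            tune_hyperparameters)
from cnvpatho.registry import FeatureDef, FeatureRegistry

SMALL_SPACE = {
    "eta": ("loguniform", 0.05, 0.3),
    "gamma": ("uniform", 0.0, 2.0),
    "max_depth": ("int", 2, 5),
    "min_child_weight": ("uniform", 1.0, 5.0),
    "subsample": ("uniform", 0.6, 1.0),
    "nrounds": ("int", 10, 40),
}


def _tiny_registry(n=3):
    return FeatureRegistry(
        [FeatureDef("length", "length", "cnv_itself")] +
        [FeatureDef(f"f{i}", "count", "genes", "protein_coding")
         for i in range(1, n)])


def _matrix(X, registry=None):
    registry = registry or _tiny_registry(X.shape[1])
    m = FeatureMatrix(registry, [f"r{i}" for i in range(len(X))], X)
    return apply_impute(m, fit_impute(m))


def _separable(n=120, seed=0):
    """One feature cleanly separates benign from pathogenic."""
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, 3))
    y = [Label.PATHOGENIC if i % 2 else Label.BENIGN for i in range(n)]
    X[:, 0] = np.where([l is Label.PATHOGENIC for l in y],
                       rng.uniform(2, 3, n), rng.uniform(-3, -2, n))
    return _matrix(X), y


BIN = TaskSpec("binary", CNVType.LOSS)
FIVE = TaskSpec("five_tier", CNVType.LOSS)


# ---------------------------------------------------------------------------
# splitting
# ---------------------------------------------------------------------------

def test_split_is_stratified_70_30():
    m, _ = _separable(100)
    y = [Label.BENIGN] * 50 + [Label.PATHOGENIC] * 50
    s = split_dataset(m, y, 0.7, seed=1)
    assert len(s.train_idx) == 70 and len(s.test_idx) == 30
    y = np.array([l.value for l in y], dtype=object)
    assert np.sum(y[s.train_idx] == "benign") == 35
    assert np.sum(y[s.test_idx] == "pathogenic") == 15
    assert not set(s.train_idx) & set(s.test_idx)


def test_split_deterministic_for_fixed_seed():
    m, y = _separable(100)
    s1 = split_dataset(m, y, 0.7, seed=3)
    s2 = split_dataset(m, y, 0.7, seed=3)
    np.testing.assert_array_equal(s1.train_idx, s2.train_idx)
    np.testing.assert_array_equal(s1.test_idx, s2.test_idx)


@pytest.mark.parametrize("ratio", [0.0, 1.0, 1.5])
def test_split_rejects_degenerate_ratio(ratio):
    m, y = _separable(20)
    with pytest.raises(ValueError, match="ratio"):
        split_dataset(m, y, ratio, seed=0)


def test_split_names_unstratifiable_class():
    m, _ = _separable(21)
    y = [Label.BENIGN] * 20 + [Label.PATHOGENIC]
    with pytest.raises(ValueError, match="pathogenic"):
        split_dataset(m, y, 0.7, seed=0)


# ---------------------------------------------------------------------------
# tuning
# ---------------------------------------------------------------------------

def test_single_trial_returns_that_configuration():
    m, y = _separable(60)
    hp1 = tune_hyperparameters(m.values, y, BIN, n_trials=1, cv_folds=3,
                               seed=9, search_space=SMALL_SPACE)
    hp2 = tune_hyperparameters(m.values, y, BIN, n_trials=1, cv_folds=3,
                               seed=9, search_space=SMALL_SPACE)
    assert hp1 == hp2  # deterministic single sample


def test_dominating_trial_selected():
    m, y = _separable(60)
    hp = tune_hyperparameters(m.values, y, BIN, n_trials=4, cv_folds=3,
                              seed=2, search_space=SMALL_SPACE)
    score = cv_objective(m.values, np.array(
        [0 if l is Label.BENIGN else 1 for l in y]), BIN, hp, 3, 2)
    # every other sampled trial scores no better
    rng = np.random.default_rng(2)
    from cnvpatho.model import _sample_hp
    y_enc = np.array([0 if l is Label.BENIGN else 1 for l in y])
    for _ in range(4):
        other = _sample_hp(rng, SMALL_SPACE)
        assert cv_objective(m.values, y_enc, BIN, other, 3, 2) <= score + 1e-12


def test_tuned_beats_or_matches_default_baseline_in_same_folds():
    m, y = _separable(120, seed=4)
    y_enc = np.array([0 if l is Label.BENIGN else 1 for l in y])
    hp = tune_hyperparameters(m.values, y, BIN, n_trials=8, cv_folds=5,
                              seed=5, search_space=SMALL_SPACE)
    tuned = cv_objective(m.values, y_enc, BIN, hp, 5, 5)
    baseline = cv_objective(m.values, y_enc, BIN, Hyperparameters(), 5, 5)
    assert tuned >= baseline - 1e-12


def test_fold_count_exceeding_class_size_rejected():
    m, y = _separable(8)
    with pytest.raises(ValueError, match="cv_folds"):
        tune_hyperparameters(m.values, y, BIN, n_trials=1, cv_folds=10,
                             seed=0, search_space=SMALL_SPACE)


# ---------------------------------------------------------------------------
# training and prediction
# ---------------------------------------------------------------------------

def test_separable_data_trains_to_perfect_accuracy():
    m, y = _separable(80)
    model = train_model(m, y, BIN, Hyperparameters(nrounds=30), seed=0)
    _, pred = predict(model, m)
    assert pred == y


def test_training_and_prediction_deterministic():
    m, y = _separable(80)
    hp = Hyperparameters(nrounds=40, subsample=0.7)
    p1, _ = predict(train_model(m, y, BIN, hp, seed=7), m)
    p2, _ = predict(train_model(m, y, BIN, hp, seed=7), m)
    np.testing.assert_array_equal(p1, p2)  # byte-identical


def test_five_tier_probabilities_sum_to_one():
    rng = np.random.default_rng(0)
    X = rng.normal(size=(100, 3))
    classes = list(TaskSpec("five_tier", CNVType.LOSS).classes)
    y = [classes[i % 5] for i in range(100)]
    m = _matrix(X)
    model = train_model(m, y, FIVE, Hyperparameters(nrounds=20), seed=0)
    probs, _ = predict(model, m)
    assert probs.shape == (100, 5)
    np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)


def test_label_outside_task_alphabet_rejected():
    m, y = _separable(20)
    y[0] = Label.UNCERTAIN
    with pytest.raises(ValueError, match="alphabet"):
        train_model(m, y, BIN, seed=0)


def test_unimputed_matrix_rejected():
    reg = _tiny_registry(3)
    X = np.ones((4, 3)); X[0, 0] = np.nan
    m = FeatureMatrix(reg, list("abcd"), X)
    with pytest.raises(ValueError, match="impute"):
        train_model(m, [Label.BENIGN, Label.BENIGN,
                        Label.PATHOGENIC, Label.PATHOGENIC], BIN, seed=0)


def test_registry_fingerprint_mismatch_rejected():
    m, y = _separable(40)
    model = train_model(m, y, BIN, Hyperparameters(nrounds=10), seed=0)
    other_reg = _tiny_registry(4)
    X = np.ones((2, 4))
    other = FeatureMatrix(other_reg, ["a", "b"], X,
                          medians={n: 0.0 for n in other_reg.names})
    with pytest.raises(ValueError, match="fingerprint"):
        predict(model, other)


def test_model_archive_round_trip(tmp_path):
    m, y = _separable(60)
    model = train_model(m, y, BIN, Hyperparameters(nrounds=25), seed=1)
    path = tmp_path / "model.json"
    model.save(path)
    loaded = TrainedModel.load(path)
    assert loaded.task == model.task
    assert loaded.medians == model.medians
    assert loaded.registry_fingerprint == model.registry_fingerprint
    p1, _ = predict(model, m)
    p2, _ = predict(loaded, m)
    np.testing.assert_array_equal(p1, p2)


def test_loss_and_gain_models_independent():
    m_loss, y_loss = _separable(60, seed=1)
    m_gain, y_gain = _separable(60, seed=2)
    hp = Hyperparameters(nrounds=20)
    model = train_model(m_loss, y_loss, BIN, hp, seed=0)
    before, _ = predict(model, m_loss)
    # train a gain model on permuted gain data; loss predictions unchanged
    rng = np.random.default_rng(0)
    perm = rng.permutation(len(y_gain))
    train_model(m_gain.subset(perm), [y_gain[i] for i in perm],
                TaskSpec("binary", CNVType.GAIN), hp, seed=0)
    after, _ = predict(model, m_loss)
    np.testing.assert_array_equal(before, after)


def test_tie_break_prefers_more_pathogenic_class():
    m, y = _separable(40)
    model = train_model(m, y, BIN, Hyperparameters(nrounds=10), seed=0)
    probs = np.array([[0.5, 0.5]])
    rev = probs[:, ::-1]
    pick = probs.shape[1] - 1 - np.argmax(rev, axis=1)
    assert model.classes[pick[0]] is Label.PATHOGENIC
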
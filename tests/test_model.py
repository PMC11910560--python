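"""Model/Results layer: objectives, splits, training contract, persistence."""

import numpy as np
import pandas as pd
import pytest

from cheetahbci.coa import COAConfig
from cheetahbci.ffnn import NetworkSpec
from cheetahbci.model import (
    FFNNCOAClassifier,
    FFNNCOAResults,
    SplitPlan,
    cross_entropy_fitness,
    misclassification_fitness,
    stratified_subject_split,
    train_ffnncoa,
)
from cheetahbci.synthetic import TASKS


# ---------------------------------------------------------------------------
# objectives
# ---------------------------------------------------------------------------

def test_uniform_scores_give_ln4():
    spec = NetworkSpec(n_in=6, n_hidden=3, n_out=4)
    x = np.random.default_rng(0).standard_normal((20, 6))
    y = np.random.default_rng(1).integers(0, 4, 20)
    # zero weights -> exactly uniform scores
    assert cross_entropy_fitness(np.zeros(spec.n_params), x, y, spec) == pytest.approx(
        np.log(4.0), abs=1e-12
    )


def test_perfect_scores_give_near_zero_fitness():
    """A network driven to saturation on a linearly separated toy problem
    reaches near-zero cross-entropy."""
    spec = NetworkSpec(n_in=4, n_hidden=4, n_out=4)
    x = np.eye(4) * 50.0  # one extreme feature per class
    y = np.arange(4)
    # hand-built weights: hidden unit i relays feature i, output i reads unit i
    w1 = np.eye(4) * 10.0
    b1 = np.zeros(4)
    w2 = np.eye(4) * 50.0
    b2 = np.zeros(4)
    from cheetahbci.ffnn import pack

    theta = pack(w1, b1, w2, b2)
    assert cross_entropy_fitness(theta, x, y, spec) < 1e-6
    assert misclassification_fitness(theta, x, y, spec) == 0.0


def test_empty_training_set_rejected():
    spec = NetworkSpec(n_in=3, n_hidden=2, n_out=4)
    with pytest.raises(ValueError, match="empty"):
        cross_entropy_fitness(np.zeros(spec.n_params), np.zeros((0, 3)), np.zeros(0, int), spec)


def test_random_weights_blind_to_label_permutation(rng):
    """For random weight draws the fitness on true labels is statistically
    indistinguishable from the fitness on permuted labels."""
    spec = NetworkSpec(n_in=5, n_hidden=3, n_out=4)
    x = rng.standard_normal((80, 5))
    y = rng.integers(0, 4, 80)
    diffs = []
    for _ in range(50):
        theta = rng.uniform(-1, 1, spec.n_params)
        y_perm = rng.permutation(y)
        diffs.append(
            cross_entropy_fitness(theta, x, y, spec)
            - cross_entropy_fitness(theta, x, y_perm, spec)
        )
    diffs = np.asarray(diffs)
    # paired mean difference within 3 standard errors of zero
    assert abs(diffs.mean()) < 3.0 * diffs.std(ddof=1) / np.sqrt(len(diffs))


# ---------------------------------------------------------------------------
# splits
# ---------------------------------------------------------------------------

def test_split_covers_every_subject_task_cell(small_feature_table):
    train, test = stratified_subject_split(small_feature_table, SplitPlan(0.25, 3))
    assert len(train) + len(test) == len(small_feature_table)
    for part in (train, test):
        cells = part.groupby(["subject_id", "label"]).size()
        assert len(cells) == 3 * 4  # 3 subjects x 4 tasks
        assert (cells >= 1).all()


def test_split_requires_two_trials_per_cell():
    table = pd.DataFrame({
        "subject_id": ["S01"] * 4,
        "label": list(TASKS),
        "f1": np.zeros(4),
    })
    with pytest.raises(ValueError, match=">= 2 trials"):
        stratified_subject_split(table, SplitPlan(0.5, 0))


def test_split_is_seeded(small_feature_table):
    t1, _ = stratified_subject_split(small_feature_table, SplitPlan(0.25, 5))
    t2, _ = stratified_subject_split(small_feature_table, SplitPlan(0.25, 5))
    pd.testing.assert_frame_equal(t1, t2)


# ---------------------------------------------------------------------------
# model construction and fit
# ---------------------------------------------------------------------------

def _quick_cfg(spec: NetworkSpec, T: int = 120) -> COAConfig:
    return COAConfig(n=12, D=spec.n_params, lower=-1, upper=1, T=T)


def test_model_validates_inputs(small_feature_table):
    with pytest.raises(ValueError, match="unknown labels"):
        FFNNCOAClassifier(np.zeros((4, 22)), ["up", "up", "down", "down"])
    with pytest.raises(ValueError, match="at least 2 examples"):
        FFNNCOAClassifier(
            np.zeros((5, 22)), ["forward", "forward", "left", "left", "right"]
        )
    model = FFNNCOAClassifier.from_dataframe(small_feature_table)
    assert model.exog.shape == (48, 22)
    assert model.spec.n_in == 22


def test_fit_is_deterministic_under_seed(small_feature_table):
    model = FFNNCOAClassifier.from_dataframe(small_feature_table)
    cfg = _quick_cfg(model.spec)
    r1 = model.fit(coa_config=cfg, seed=11)
    r2 = model.fit(coa_config=cfg, seed=11)
    np.testing.assert_array_equal(r1.params, r2.params)
    np.testing.assert_array_equal(r1.history, r2.history)


def test_trained_weights_beat_50_random_draws(small_feature_table):
    """The COA-trained network must reach at least the training accuracy of
    the best of 50 random weight vectors from the same box."""
    model = FFNNCOAClassifier.from_dataframe(small_feature_table)
    res = model.fit(coa_config=_quick_cfg(model.spec, T=200), seed=2)

    rng = np.random.default_rng(1234)
    x = (model.exog - res.mean) / res.scale
    from cheetahbci import ffnn

    best_random = max(
        float(np.mean(ffnn.predict(rng.uniform(-1, 1, model.spec.n_params), x, model.spec)
                      == model.endog))
        for _ in range(50)
    )
    assert res.training_accuracy() / 100.0 >= best_random


def test_standardization_uses_training_statistics(small_feature_table):
    model = FFNNCOAClassifier.from_dataframe(small_feature_table)
    res = model.fit(coa_config=_quick_cfg(model.spec, T=20), seed=0)
    np.testing.assert_allclose(res.mean, model.exog.mean(axis=0))
    np.testing.assert_allclose(res.scale, model.exog.std(axis=0))


def test_history_monotone_and_fitness_consistent(small_feature_table):
    model = FFNNCOAClassifier.from_dataframe(small_feature_table)
    res = model.fit(coa_config=_quick_cfg(model.spec, T=60), seed=4)
    assert (np.diff(res.history) <= 0).all()
    assert res.best_fitness == pytest.approx(res.history[-1])
    x = (model.exog - res.mean) / res.scale
    assert cross_entropy_fitness(res.params, x, model.endog, model.spec) == pytest.approx(
        res.best_fitness
    )


def test_evaluate_and_summary(small_feature_table):
    model = FFNNCOAClassifier.from_dataframe(small_feature_table)
    res = model.fit(coa_config=_quick_cfg(model.spec, T=60), seed=4)
    rep = res.evaluate()
    assert rep.n_trials == 48
    assert rep.confusion.to_numpy().sum() == 48
    text = res.summary()
    assert "22-4-4" in text and "cross_entropy" in text
    session = rep.summary()
    assert "Confusion matrix" in session


def test_save_load_roundtrip(tmp_path, small_feature_table):
    model = FFNNCOAClassifier.from_dataframe(small_feature_table)
    res = model.fit(coa_config=_quick_cfg(model.spec, T=40), seed=9)
    path = tmp_path / "model.json"
    res.save(path)
    loaded = FFNNCOAResults.load(path)
    np.testing.assert_array_equal(loaded.params, res.params)
    np.testing.assert_array_equal(
        loaded.predict(model.exog), res.predict(model.exog)
    )


def test_functional_wrapper(small_feature_table):
    feature_cols = [f"f{i}" for i in range(1, 23)]
    res = train_ffnncoa(
        small_feature_table[feature_cols].to_numpy(),
        small_feature_table["label"].to_numpy(),
        coa_config=_quick_cfg(NetworkSpec(), T=40),
        seed=3,
    )
    assert res.params.shape == (NetworkSpec().n_params,)


def test_recovery_surface_monotone_in_signature_gain():
    """Median held-out accuracy over 5 seeds is non-decreasing in the class
    signature gain (0, 0.5, 1.0, 2.0), on a scaled-down cohort."""
    from cheetahbci.preprocess import notch_filter
    from cheetahbci.synthetic import CohortSpec, default_class_signatures, iter_cohort
    from cheetahbci.welch import extract_features, features_to_frame

    medians = []
    for gain in (0.0, 0.5, 1.0, 2.0):
        accs = []
        for seed in range(1, 6):
            spec = CohortSpec(
                n_subjects=6, trials_per_task=5, seed=seed,
                class_signatures=default_class_signatures(gain),
            )
            table = features_to_frame(
                [extract_features(notch_filter(t)) for t in iter_cohort(spec)]
            )
            train, test = stratified_subject_split(table, SplitPlan(0.25, seed))
            model = FFNNCOAClassifier.from_dataframe(train)
            cfg = COAConfig(n=20, D=model.spec.n_params, lower=-1, upper=1, T=300)
            res = model.fit(coa_config=cfg, seed=seed)
            accs.append(res.evaluate_table(test).accuracy)
        medians.append(np.median(accs))
    assert all(a <= b for a, b in zip(medians, medians[1:]))
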
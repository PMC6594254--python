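"""Base learner, validation schemes, hybrid wirings and hyper recursion."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import seqvis3d.hybrid as hybrid_mod
from seqvis3d import (
    EvaluationScheme,
    HybridTopology,
    LabeledDataset,
    LearnerConfig,
    evaluate,
    percent_agreement,
    run_hybrid,
    run_hyper_hybrid,
    train_learner,
)
from seqvis3d.hybrid import EvaluationResult, wiring_trace


def separable_data(n=40, seed=0):
    rng = np.random.default_rng(seed)
    y = np.repeat([0, 1], n // 2)
    X = rng.normal(size=(n, 2))
    X[y == 1, 0] += 6.0
    return LabeledDataset(X, y)


def test_training_fits_separable_data():
    data = separable_data()
    model = train_learner(data, LearnerConfig(seed=1))
    acc = np.mean(model.predict(data.X) == data.y)
    assert acc >= 0.95


def test_constant_label_dataset_gives_constant_predictor():
    X = np.random.default_rng(0).normal(size=(6, 3))
    data = LabeledDataset(X, np.ones(6, dtype=int))
    with pytest.warns(UserWarning):
        model = train_learner(data, LearnerConfig())
    assert np.array_equal(model.predict(X), np.ones(6, dtype=int))


def test_training_is_deterministic():
    data = separable_data(seed=3)
    cfg = LearnerConfig(seed=11)
    p1 = train_learner(data, cfg).predict_proba(data.X)
    p2 = train_learner(data, cfg).predict_proba(data.X)
    assert np.array_equal(p1, p2)


def test_loocv_covers_all_items_and_split_sizes():
    data = separable_data(n=10, seed=5)
    res = evaluate(data, LearnerConfig(max_epochs=60), EvaluationScheme("loocv"))
    assert len(res.predictions) == 10 and res.held_out == tuple(range(10))
    res = evaluate(data, LearnerConfig(max_epochs=60),
                   EvaluationScheme("split50_50", seed=2))
    assert len(res.held_out) == 5
    res = evaluate(data, LearnerConfig(max_epochs=60),
                   EvaluationScheme("split67_33", seed=2))
    assert len(res.held_out) == round(0.33 * 10)


def test_percent_agreement_basics():
    assert percent_agreement([1, 0, 1], [1, 0, 1]) == 100.0
    with pytest.raises(ValueError):
        percent_agreement([1, 0], [1])


@settings(deadline=None, max_examples=30)
@given(st.lists(st.integers(0, 1), min_size=1, max_size=30), st.data())
def test_percent_agreement_symmetric_and_bounded(a, data):
    b = data.draw(st.lists(st.integers(0, 1), min_size=len(a), max_size=len(a)))
    x = percent_agreement(a, b)
    assert 0.0 <= x <= 100.0
    assert x == percent_agreement(b, a)


def test_wiring_traces():
    assert wiring_trace("series", 3) == (0, 1, 2)
    assert wiring_trace("cyclic", 3) == (0, 1, 2, 0)
    assert wiring_trace("cascade", 3) == (0, 1, 2, 1, 0)


def test_series_of_one_equals_plain_evaluation():
    data = separable_data(n=14, seed=2)
    sch = EvaluationScheme("loocv")
    topo = HybridTopology("series", (LearnerConfig(max_epochs=80),))
    h = run_hybrid(data, topo, sch, seed=4)
    # same seed stream: the single member's seed is the first drawn seed
    from seqvis3d.hybrid import _SeedStream

    cfg = LearnerConfig(max_epochs=80, seed=_SeedStream(4).next_seed())
    direct = evaluate(data, cfg, sch)
    assert np.array_equal(h.item_predictions, direct.item_predictions)
    assert h.agreement == direct.agreement


def test_transfer_appends_one_feature_column_per_execution(monkeypatch):
    """Downstream members see exactly one extra column per upstream transfer."""
    widths = []

    def stub_evaluate(data, config, scheme):
        widths.append(data.X.shape[1])
        preds = np.zeros(len(data), dtype=int)
        return EvaluationResult(
            held_out=tuple(range(len(data))),
            predictions=preds,
            agreement=100.0,
            item_predictions=preds,
        )

    monkeypatch.setattr(hybrid_mod, "evaluate", stub_evaluate)
    data = separable_data(n=8)
    topo = HybridTopology("series", (LearnerConfig(),) * 3)
    run_hybrid(data, topo, EvaluationScheme("loocv"), seed=0)
    assert widths == [2, 3, 4]
    widths.clear()
    run_hybrid(data, HybridTopology("cascade", (LearnerConfig(),) * 3),
               EvaluationScheme("loocv"), seed=0)
    assert widths == [2, 3, 4, 5, 6]


def test_hyper_level_zero_equals_hybrid():
    data = separable_data(n=12, seed=7)
    sch = EvaluationScheme("loocv")
    topo = HybridTopology("series", (LearnerConfig(max_epochs=60),) * 3)
    a = run_hybrid(data, topo, sch, seed=9)
    b = run_hyper_hybrid(data, 0, topo, sch, seed=9)
    assert np.array_equal(a.item_predictions, b.item_predictions)


def test_hyper_one_with_singletons_collapses_to_three_member_hybrid():
    data = separable_data(n=12, seed=8)
    sch = EvaluationScheme("loocv")
    cfg = LearnerConfig(max_epochs=60)
    three = run_hybrid(data, HybridTopology("series", (cfg,) * 3), sch, seed=5)
    nested = run_hyper_hybrid(data, 1, HybridTopology("series", (cfg,)), sch, seed=5)
    assert np.array_equal(three.item_predictions, nested.item_predictions)


def test_hyper_two_trains_nine_leaf_learners():
    data = separable_data(n=8, seed=1)
    res = run_hyper_hybrid(
        data, 2, HybridTopology("series", (LearnerConfig(max_epochs=20),)),
        EvaluationScheme("split50_50", seed=0), seed=0,
    )
    assert res.n_learners == 9
    assert res.tree["level"] == 2


def test_hybrid_determinism_across_runs():
    data = separable_data(n=12, seed=4)
    sch = EvaluationScheme("loocv")
    topo = HybridTopology("cyclic", (LearnerConfig(max_epochs=60),) * 3)
    a = run_hybrid(data, topo, sch, seed=2)
    b = run_hybrid(data, topo, sch, seed=2)
    assert np.array_equal(a.item_predictions, b.item_predictions)
    assert a.trace == (0, 1, 2, 0)


def test_learner_config_validation():
    with pytest.raises(ValueError):
        LearnerConfig(learning_rate=0.0)
    with pytest.raises(ValueError):
        EvaluationScheme("bogus")
    with pytest.raises(ValueError):
        HybridTopology("series", ())
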
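"""LDA ensemble growth, gated self-training, voting, prequential contract."""

import numpy as np
import pytest

from driftbci import cli_io
from driftbci.ensemble import (
    StreamConfig,
    StreamResult,
    evaluate,
    paired_wilcoxon,
    run_stream,
    train_lda,
    vote,
)
from driftbci.features import FeatureStream, pca_fit_reduce
from driftbci.shiftdetect import CseDetector, EwmaMonitor
from driftbci.synthgen import default_feature_scenario, simulate_feature_stream


def make_training(rng, n=60, d=3, sep=2.0):
    X = np.vstack([rng.standard_normal((n // 2, d)) + sep / 2,
                   rng.standard_normal((n // 2, d)) - sep / 2])
    y = np.repeat([1, 2], n // 2)
    return X, y


def test_lda_midpoint_posterior_is_half(rng):
    X, y = make_training(rng, n=400)
    clf = train_lda(X, y)
    post = clf.posterior(np.zeros(3))
    assert post[0] == pytest.approx(0.5, abs=0.06)


def test_lda_1d_closed_form_logistic_posterior():
    """Empirical means ±1, pooled variance 1, equal priors: the LDA
    posterior for class at +1 is exactly sigma(2x)."""
    a = 1.0  # ML pooled variance = sum((x - mu_c)^2) / n = a^2
    X = np.array([[1 - a], [1 + a], [-1 - a], [-1 + a]])
    y = np.array([1, 1, 2, 2])
    clf = train_lda(X, y)
    for x in (-1.3, -0.2, 0.0, 0.4, 2.0):
        post = clf.posterior(np.array([x]))
        assert post[0] == pytest.approx(1 / (1 + np.exp(-2 * x)), abs=1e-8)


def test_lda_requires_both_classes_and_enough_samples(rng):
    X = rng.standard_normal((10, 2))
    with pytest.raises(ValueError):
        train_lda(X, np.ones(10, dtype=int))
    with pytest.raises(ValueError):
        train_lda(X[:2], np.array([1, 2]))


def test_vote_weighted_majority_and_recency_tie_break(rng):
    X, y = make_training(rng)

    class Fixed:
        def __init__(self, label, weight):
            self.label, self.weight = label, weight

        def predict(self, x):
            return self.label

    # weights (2, 1, 1) with votes (1, 2, 2) tie 2 vs 2: most recent wins
    members = [Fixed(1, 2.0), Fixed(2, 1.0), Fixed(2, 1.0)]
    label, share = vote(members, np.zeros(2))
    assert label == 2
    assert share == pytest.approx(0.5)
    # unanimity wins regardless of weights
    members = [Fixed(1, 0.01), Fixed(1, 5.0)]
    assert vote(members, np.zeros(2))[0] == 1
    # single classifier
    assert vote([Fixed(2, 1.0)], np.zeros(2))[0] == 2
    with pytest.raises(ValueError):
        vote([], np.zeros(2))


def test_passive_scheme_adapts_every_interval(rng):
    X, y = make_training(rng, n=80)
    stream = rng.standard_normal((160, 3))
    cfg = StreamConfig(scheme="passive", combination="c3", interval=10)
    res = run_stream(X, y, stream, cfg)
    assert len(res.adaptation_trials) == 16
    assert res.adaptation_trials == list(range(9, 160, 10))
    # ensemble growth bound: k - 1 <= floor(n / interval)
    assert res.state.size - 1 <= 16


def test_gate_never_passing_keeps_training_set_fixed(rng):
    X, y = make_training(rng, n=80)
    stream = rng.standard_normal((60, 3))
    cfg = StreamConfig(scheme="passive", combination="c3", interval=10,
                       gamma=1.0)
    res = run_stream(X, y, stream, cfg)
    assert not res.gate_decisions.any()
    assert res.state.X_train.shape[0] == 80
    # classifiers retrained on identical data predict like the first one
    static = train_lda(X, y)
    expected = np.array([static.predict(x) for x in stream])
    np.testing.assert_array_equal(res.predictions, expected)


def test_original_labels_never_relabelled(rng):
    X, y = make_training(rng, n=80)
    stream = rng.standard_normal((100, 3)) + 0.5
    cfg = StreamConfig(scheme="passive", combination="c3", interval=10,
                       gamma=0.6)
    res = run_stream(X, y, stream, cfg)
    assert res.state.X_train.shape[0] >= 80
    np.testing.assert_array_equal(res.state.X_train[:80], X)
    np.testing.assert_array_equal(res.state.y_train[:80], y)


def test_prequential_causality_prefix_invariance(rng):
    """Deleting future trials never changes past predictions."""
    sc = default_feature_scenario(seed=31)
    stream = simulate_feature_stream(sc)
    train, test, ytr, _ = stream.train_test()

    def run(n_trials):
        pca, _ = pca_fit_reduce(FeatureStream(train.X), 0.90)
        mon = EwmaMonitor.calibrate(pca.transform(train.X), L=1.6)
        det = CseDetector(mon, pca.transform(train.X), n_w=10, seed=5)
        cfg = StreamConfig(scheme="active", combination="c3")
        return run_stream(train.X, ytr, test.X[:n_trials], cfg,
                          detector=det, monitor_transform=pca.transform)

    full = run(160)
    prefix = run(100)
    np.testing.assert_array_equal(full.predictions[:100], prefix.predictions)
    np.testing.assert_array_equal(full.gate_decisions[:100],
                                  prefix.gate_decisions)


def test_active_scheme_on_stationary_stream_rarely_grows():
    """With the conservative L = 3 chart, a stationary stream leaves the
    ensemble at size one in at least 95% of runs."""
    grew = 0
    n_runs = 100
    for rep in range(n_runs):
        sc = default_feature_scenario(seed=7000 + rep, shift=0.0)
        stream = simulate_feature_stream(sc)
        train, test, ytr, _ = stream.train_test()
        pca, _ = pca_fit_reduce(FeatureStream(train.X), 0.90)
        mon = EwmaMonitor.calibrate(pca.transform(train.X), L=3.0)
        det = CseDetector(mon, pca.transform(train.X), n_w=20, seed=rep)
        cfg = StreamConfig(scheme="active", combination="c3")
        res = run_stream(train.X, ytr, test.X, cfg, detector=det,
                         monitor_transform=pca.transform)
        grew += res.state.size > 1
    assert grew <= 0.05 * n_runs


def test_active_growth_bounded_by_validated_events():
    sc = default_feature_scenario(seed=17, shift=2.0)
    stream = simulate_feature_stream(sc)
    train, test, ytr, _ = stream.train_test()
    pca, _ = pca_fit_reduce(FeatureStream(train.X), 0.90)
    mon = EwmaMonitor.calibrate(pca.transform(train.X), L=1.6)
    det = CseDetector(mon, pca.transform(train.X), n_w=10, seed=3)
    cfg = StreamConfig(scheme="active", combination="c3")
    res = run_stream(train.X, ytr, test.X, cfg, detector=det,
                     monitor_transform=pca.transform)
    n_validated = sum(e.stage == "validated" for e in res.shift_events)
    assert res.state.size - 1 == len(res.adaptation_trials) == n_validated
    assert n_validated >= 1


def test_c1_uses_a_single_transductive_store(rng):
    X, y = make_training(rng, n=60)
    stream = rng.standard_normal((50, 3))
    cfg = StreamConfig(scheme="passive", combination="c1", interval=10,
                       gamma=0.6)
    res = run_stream(X, y, stream, cfg)
    assert res.state.size == 0            # no LDA members in C-1
    assert np.all(res.ensemble_sizes == 1)
    assert set(np.unique(res.predictions)) <= {1, 2}


def test_evaluate_and_wilcoxon_basics(rng):
    preds = np.array([1, 2, 1, 2])
    res = StreamResult(predictions=preds, confidences=np.ones(4),
                       gate_decisions=np.zeros(4, bool),
                       ensemble_sizes=np.ones(4, int),
                       adaptation_trials=[], shift_events=[], state=None)
    assert evaluate(res, preds.copy()) == 100.0
    assert evaluate(res, np.array([2, 1, 2, 1])) == 0.0
    with pytest.raises(ValueError):
        evaluate(res, np.array([1, 2]))
    # random predictions against coin labels sit near 50%
    labels = rng.integers(1, 3, size=1000)
    guesses = rng.integers(1, 3, size=1000)
    acc = np.mean(guesses == labels)
    assert abs(acc - 0.5) < 3 * np.sqrt(0.25 / 1000)
    # identical method pair: degenerate Wilcoxon reported as no difference
    a = rng.uniform(60, 90, size=12)
    assert paired_wilcoxon(a, a.copy()) == 1.0


def test_run_experiment_reproducible_bit_for_bit():
    cfg = cli_io.RunConfig(seed=4)
    r1 = cli_io.run_experiment(cfg)
    r2 = cli_io.run_experiment(cfg)
    np.testing.assert_array_equal(r1.result.predictions,
                                  r2.result.predictions)
    assert r1.accuracy == r2.accuracy
    assert r1.validated_trials == r2.validated_trials


def test_run_config_round_trips_through_yaml(tmp_path):
    cfg = cli_io.RunConfig(seed=9, stream=StreamConfig(scheme="passive",
                                                       combination="c2"))
    path = tmp_path / "run.yaml"
    cfg.to_yaml(path)
    back = cli_io.RunConfig.from_yaml(path)
    assert back == cfg
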
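"""Two-stage covariate-shift estimation: EWMA chart and Hotelling T²."""

import numpy as np
import pytest
from scipy import stats

from driftbci.features import FeatureStream, pca_fit_reduce
from driftbci.shiftdetect import (
    LAMBDA_GRID,
    CseDetector,
    EwmaMonitor,
    ewma_step,
    hotelling_t2,
    isolated_shift_refractory,
    run_cse,
    select_lambda,
    validate_warning,
    validated_trials,
)
from driftbci.synthgen import default_feature_scenario, simulate_feature_stream


def unrolled_ewma(series, lam, z0):
    """Independent oracle: literal recursion z(i) = λx(i) + (1-λ)z(i-1)."""
    z = float(z0)
    zs, errs = [], []
    for x in series:
        errs.append(x - z)
        z = lam * x + (1 - lam) * z
        zs.append(z)
    return np.array(zs), np.array(errs)


def oracle_lambda(series, z0):
    """Independent oracle: exhaustive grid argmin of the 1-SAP SSE."""
    best_lam, best_sse = None, np.inf
    for lam in np.arange(0, 101) / 100.0:
        _, errs = unrolled_ewma(series, lam, z0)
        sse = float(np.sum(errs ** 2))
        if sse < best_sse - 1e-15:
            best_lam, best_sse = lam, sse
    return best_lam


def test_ewma_step_matches_hand_unrolled_recursion(rng):
    for _ in range(100):
        lam = rng.uniform(0, 1)
        series = rng.standard_normal(30)
        z0 = rng.standard_normal()
        monitor = EwmaMonitor(lam=lam, z=np.array([z0]),
                              sigma_e=np.array([1.0]), L=3.0)
        zs, errs = [], []
        for x in series:
            z, e, _ = ewma_step(monitor, np.array([x]))
            zs.append(z[0])
            errs.append(e[0])
        oz, oe = unrolled_ewma(series, lam, z0)
        np.testing.assert_allclose(zs, oz, atol=1e-10)
        np.testing.assert_allclose(errs, oe, atol=1e-10)


def test_ewma_limits():
    """λ=1 is memoryless; λ=0 never moves the smoothed state."""
    m1 = EwmaMonitor(lam=1.0, z=np.array([0.3]), sigma_e=np.array([1.0]))
    z, e, _ = ewma_step(m1, np.array([0.9]))
    assert z[0] == pytest.approx(0.9)
    assert e[0] == pytest.approx(0.6)
    m0 = EwmaMonitor(lam=0.0, z=np.array([0.5]), sigma_e=np.array([1.0]))
    for x in [2.0, -3.0, 10.0]:
        z, _, _ = ewma_step(m0, np.array([x]))
        assert z[0] == pytest.approx(0.5)


def test_ewma_rejects_non_finite_without_state_change():
    m = EwmaMonitor(lam=0.5, z=np.array([1.0]), sigma_e=np.array([1.0]))
    with pytest.raises(ValueError):
        ewma_step(m, np.array([np.nan]))
    assert m.z[0] == 1.0 and m.i == 0


def test_select_lambda_agrees_with_exhaustive_grid_oracle(rng):
    for _ in range(50):
        n = rng.integers(12, 40)
        phi = rng.uniform(-0.9, 0.9)
        series = np.zeros(n)
        noise = rng.standard_normal(n)
        for i in range(1, n):
            series[i] = phi * series[i - 1] + noise[i]
        z0 = series.mean()
        assert select_lambda(series, z0=np.array([z0])) == pytest.approx(
            oracle_lambda(series, z0))


def test_select_lambda_constant_series_returns_zero():
    with pytest.warns(UserWarning):
        assert select_lambda(np.ones(20)) == 0.0


def test_select_lambda_grid_and_minimum_length():
    assert len(LAMBDA_GRID) == 101
    with pytest.raises(ValueError):
        select_lambda(np.arange(5.0))


def test_autocorrelated_series_selects_larger_lambda_than_white_noise():
    lams_ar, lams_wn = [], []
    for rep in range(100):
        rng = np.random.default_rng(3000 + rep)
        noise = rng.standard_normal(150)
        ar = np.zeros(150)
        for i in range(1, 150):
            ar[i] = 0.9 * ar[i - 1] + noise[i]
        lams_ar.append(select_lambda(ar))
        lams_wn.append(select_lambda(rng.standard_normal(150)))
    assert np.mean(lams_ar) > np.mean(lams_wn)


def test_hotelling_identical_windows_is_a_false_alarm():
    x = np.arange(40, dtype=float).reshape(20, 2)
    event = validate_warning(x, x.copy(), alpha=0.05, trial=7)
    assert event.t2 == pytest.approx(0.0, abs=1e-12)
    assert event.p_value == pytest.approx(1.0)
    assert event.stage == "false_alarm"
    assert event.trial == 7


def test_hotelling_1d_equals_pooled_t_squared(rng):
    for _ in range(20):
        a = rng.standard_normal((15, 1)) + rng.uniform(-1, 1)
        b = rng.standard_normal((15, 1))
        t2, p, _ = hotelling_t2(a, b)
        t_stat, t_p = stats.ttest_ind(a.ravel(), b.ravel(), equal_var=True)
        assert t2 == pytest.approx(t_stat ** 2, abs=1e-10)
        assert p == pytest.approx(t_p, abs=1e-10)


def test_hotelling_matches_independent_multivariate_oracle(rng):
    """Cross-check T² and its F-transform p-value against pingouin."""
    pingouin = pytest.importorskip("pingouin")
    a = rng.standard_normal((25, 3)) + np.array([0.5, 0.0, -0.3])
    b = rng.standard_normal((30, 3))
    t2, p, _ = hotelling_t2(a, b)
    ref = pingouin.multivariate_ttest(a, b)
    assert t2 == pytest.approx(float(ref["T2"].iloc[0]), rel=1e-9)
    assert p == pytest.approx(float(ref["pval"].iloc[0]), rel=1e-9)


def test_hotelling_detects_a_clear_mean_shift():
    rng = np.random.default_rng(11)
    a = rng.standard_normal((30, 4)) + 1.5
    b = rng.standard_normal((30, 4))
    event = validate_warning(a, b, alpha=0.05)
    assert event.stage == "validated"
    assert event.p_value < 1e-6


def test_validate_warning_requires_equal_sizes(rng):
    with pytest.raises(ValueError):
        validate_warning(rng.standard_normal((10, 2)),
                         rng.standard_normal((12, 2)))


def _calibrated(train, L=1.6):
    return EwmaMonitor.calibrate(train, L=L)


def test_run_cse_stationary_validated_never_exceeds_warnings(rng):
    train = rng.standard_normal((100, 3))
    stream = rng.standard_normal((150, 3))
    events = run_cse(_calibrated(train), stream, train, n_w=10, seed=1)
    n_warn = sum(e.stage == "warning" for e in events)
    n_val = sum(e.stage == "validated" for e in events)
    assert n_val <= n_warn


def test_run_cse_huge_L_produces_no_warnings(rng):
    train = rng.standard_normal((100, 3))
    stream = rng.standard_normal((150, 3))
    events = run_cse(EwmaMonitor.calibrate(train, L=1e9), stream, train,
                     n_w=10, seed=1)
    assert events == []


def test_raising_L_never_increases_warnings_and_alpha_is_monotone(rng):
    train = rng.standard_normal((100, 3))
    stream = np.vstack([rng.standard_normal((60, 3)),
                        rng.standard_normal((60, 3)) + 1.0])
    counts = []
    for L in (1.0, 2.0, 3.0, 4.0):
        events = run_cse(_calibrated(train, L=L), stream, train,
                         n_w=10, seed=1)
        counts.append(sum(e.stage == "warning" for e in events))
    assert all(a >= b for a, b in zip(counts, counts[1:]))
    vals = []
    for alpha in (0.10, 0.05, 0.01):
        events = run_cse(_calibrated(train), stream, train, alpha=alpha,
                         n_w=10, seed=1)
        vals.append(sum(e.stage == "validated" for e in events))
    assert all(a >= b for a, b in zip(vals, vals[1:]))


def test_every_validated_event_has_a_warning_at_the_same_trial():
    sc = default_feature_scenario(seed=123, shift=2.0)
    stream = simulate_feature_stream(sc)
    train, test, _, _ = stream.train_test()
    pca, _ = pca_fit_reduce(FeatureStream(train.X), 0.90)
    events = run_cse(_calibrated(pca.transform(train.X)),
                     pca.transform(test.X), pca.transform(train.X),
                     n_w=10, seed=0)
    warn_trials = {e.trial for e in events if e.stage == "warning"}
    for e in events:
        if e.stage in ("validated", "false_alarm"):
            assert e.trial in warn_trials
    gaps = np.diff(validated_trials(events))
    assert np.all(gaps >= 10)  # refractory defaults to the window size


def test_detector_dimensionality_checks(rng):
    train = rng.standard_normal((50, 3))
    mon = _calibrated(train)
    with pytest.raises(ValueError):
        run_cse(mon, rng.standard_normal((10, 2)), train)
    det = CseDetector(mon, train)
    with pytest.raises(ValueError):
        det.update_reference(rng.standard_normal((10, 2)))


def test_isolated_shift_refractory_spacing():
    assert isolated_shift_refractory(10) == 21
    sc = default_feature_scenario(seed=77, shift=2.0)
    stream = simulate_feature_stream(sc)
    train, test, _, _ = stream.train_test()
    pca, _ = pca_fit_reduce(FeatureStream(train.X), 0.90)
    events = run_cse(_calibrated(pca.transform(train.X)),
                     pca.transform(test.X), pca.transform(train.X),
                     n_w=10, refractory=isolated_shift_refractory(10), seed=0)
    gaps = np.diff(validated_trials(events))
    assert np.all(gaps >= 21)
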
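"""Two-stage covariate-shift estimation for feature streams.

Stage I (retrospective): an exponentially weighted moving average (EWMA)
control chart provides a 1-step-ahead prediction z(i-1) of each monitored
component; the prediction error e(i) = x(i) - z(i-1) exceeding L·σ_e on any
component raises a covariate-shift *warning* (CSW).  The smoothing constant

    z(i) = λ x(i) + (1 - λ) z(i-1)

is selected on the training series by minimizing the summed squared
1-step-ahead prediction errors over the grid λ ∈ {0.00, 0.01, ..., 1.00}.

Stage II (validation): at each warning, a two-sample Hotelling T² test
compares the most recent trial features against an equally sized sample
from the *current training pool*; rejection at level α confirms the shift
(CSV), otherwise the warning is logged as a false alarm.  A refractory gap
(default: the window size, so consecutive validation windows never share
trials) spaces confirmed shifts.  The reference pool is deliberately not
re-anchored by the detector itself: a persisting shift keeps re-validating
against the training data until the adaptive learner merges post-shift
trials into the pool (see :func:`CseDetector.update_reference`), at which
point detection quenches naturally — the system has adapted.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

LAMBDA_GRID = np.round(np.arange(0, 101) / 100.0, 2)


def _sse_for_lambda(series: np.ndarray, lam: float, z0: np.ndarray) -> float:
    """Sum over components of squared 1-step-ahead errors of the EWMA."""
    z = z0.astype(float).copy()
    sse = 0.0
    for x in series:
        e = x - z
        sse += float(e @ e)
        z = lam * x + (1 - lam) * z
    return sse


def select_lambda(train_series: np.ndarray,
                  z0: np.ndarray | str = "mean") -> float:
    """Grid-search the EWMA smoothing constant on training data.

    ``train_series`` is (n_obs, n_components) (a 1-D array is treated as a
    single component).  ``z0`` initializes the smoothed state; the default
    uses the per-component series mean.  Ties pick the smallest λ; a
    constant series therefore returns 0.
    """
    series = np.asarray(train_series, dtype=float)
    if series.ndim == 1:
        series = series[:, None]
    if series.shape[0] < 10:
        raise ValueError("need at least 10 training observations")
    if isinstance(z0, str):
        if z0 != "mean":
            raise ValueError("z0 must be an array or 'mean'")
        z0 = series.mean(axis=0)
    z0 = np.broadcast_to(np.asarray(z0, dtype=float), series.shape[1:]).copy()
    if np.ptp(series, axis=0).max() == 0:
        warnings.warn("constant training series; lambda is arbitrary, using 0")
        return 0.0
    # unroll the recursion once for the whole grid: z is (n_lambda, p)
    lams = LAMBDA_GRID[:, None]
    z = np.broadcast_to(z0, (len(LAMBDA_GRID), series.shape[1])).copy()
    sses = np.zeros(len(LAMBDA_GRID))
    for x in series:
        e = x[None, :] - z
        sses += np.sum(e * e, axis=1)
        z = lams * x[None, :] + (1 - lams) * z
    return float(LAMBDA_GRID[int(np.argmin(sses))])


@dataclass
class EwmaMonitor:
    """Calibrated EWMA control chart over the monitored components.

    ``sigma_e`` holds the per-component SD of the training 1-step-ahead
    residuals; a stream observation whose absolute prediction error exceeds
    ``L * sigma_e`` on any component raises a warning (OR rule).
    """

    lam: float
    z: np.ndarray
    sigma_e: np.ndarray
    L: float = 3.0
    i: int = 0
    warning_log: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.z = np.atleast_1d(np.asarray(self.z, dtype=float))
        self.sigma_e = np.atleast_1d(np.asarray(self.sigma_e, dtype=float))
        if not 0 <= self.lam <= 1:
            raise ValueError("lambda must be in [0, 1]")
        if np.any(self.sigma_e <= 0):
            raise ValueError("sigma_e must be positive for every component")

    @classmethod
    def calibrate(cls, train: np.ndarray, L: float = 3.0,
                  lam: float | None = None) -> "EwmaMonitor":
        """Select λ on the training series, estimate residual SDs, and
        leave the smoothed state at the end of the training pass."""
        series = np.asarray(train, dtype=float)
        if series.ndim == 1:
            series = series[:, None]
        if lam is None:
            lam = select_lambda(series)
        z = series.mean(axis=0).copy()
        resid = np.empty_like(series)
        for t, x in enumerate(series):
            resid[t] = x - z
            z = lam * x + (1 - lam) * z
        sigma = resid.std(axis=0, ddof=1)
        sigma = np.where(sigma > 0, sigma, np.finfo(float).eps)
        return cls(lam=lam, z=z, sigma_e=sigma, L=L)

    @property
    def n_components(self) -> int:
        return len(self.z)


def ewma_step(monitor: EwmaMonitor, x: np.ndarray
              ) -> tuple[np.ndarray, np.ndarray, bool]:
    """Advance the monitor by one observation.

    Returns ``(z_new, e, warning)`` where ``e = x - z_prev`` is the
    1-step-ahead prediction error and ``warning`` is True when any
    component error magnitude exceeds ``L * sigma_e``.  Non-finite
    observations are rejected without touching the monitor state.
    """
    x = np.atleast_1d(np.asarray(x, dtype=float))
    if x.shape != monitor.z.shape:
        raise ValueError("observation dimensionality mismatch")
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite observation rejected")
    e = x - monitor.z
    warning = bool(np.any(np.abs(e) > monitor.L * monitor.sigma_e))
    monitor.z = monitor.lam * x + (1 - monitor.lam) * monitor.z
    monitor.i += 1
    if warning:
        monitor.warning_log.append(monitor.i)
    return monitor.z.copy(), e, warning


def hotelling_t2(sample_a: np.ndarray, sample_b: np.ndarray,
                 ridge: float = 0.0) -> tuple[float, float, bool]:
    """Two-sample Hotelling T² with the exact F transform.

    Returns ``(t2, p, regularized)``.  The pooled covariance is ridge-
    regularized only when singular (flagged in the third element).
    """
    a = np.atleast_2d(np.asarray(sample_a, dtype=float))
    b = np.atleast_2d(np.asarray(sample_b, dtype=float))
    if a.shape[1] != b.shape[1]:
        raise ValueError("samples must share dimensionality")
    n1, n2, p = a.shape[0], b.shape[0], a.shape[1]
    if n1 < 2 or n2 < 2:
        raise ValueError("need at least two observations per sample")
    d = a.mean(axis=0) - b.mean(axis=0)
    s_pooled = (((n1 - 1) * np.cov(a, rowvar=False, ddof=1).reshape(p, p)
                 + (n2 - 1) * np.cov(b, rowvar=False, ddof=1).reshape(p, p))
                / (n1 + n2 - 2))
    if ridge:
        s_pooled = s_pooled + ridge * np.eye(p)
    regularized = bool(ridge)
    try:
        sol = np.linalg.solve(s_pooled, d)
    except np.linalg.LinAlgError:
        reg = 1e-8 * max(np.trace(s_pooled) / p, 1.0)
        sol = np.linalg.solve(s_pooled + reg * np.eye(p), d)
        regularized = True
    t2 = float(n1 * n2 / (n1 + n2) * d @ sol)
    dof2 = n1 + n2 - p - 1
    if dof2 <= 0:
        raise ValueError("samples too small for the dimensionality")
    f_stat = dof2 / (p * (n1 + n2 - 2)) * t2
    pval = float(stats.f.sf(f_stat, p, dof2))
    return t2, pval, regularized


@dataclass
class ShiftEvent:
    """One detector event: a stage-I warning, its stage-II confirmation
    (validated), or its rejection (false_alarm)."""

    trial: int
    stage: str                      # "warning" | "validated" | "false_alarm"
    component: int | None = None
    t2: float | None = None
    p_value: float | None = None
    window: int | None = None
    regularized: bool = False

    def to_dict(self) -> dict:
        return {"trial": self.trial, "stage": self.stage,
                "component": self.component, "t2": self.t2,
                "p_value": self.p_value, "window": self.window,
                "regularized": self.regularized}


def validate_warning(pre_window: np.ndarray, ref_window: np.ndarray,
                     alpha: float = 0.05, trial: int = -1) -> ShiftEvent:
    """Stage-II confirmation of a warning via Hotelling T².

    ``pre_window`` holds the most recent trial features ending at the
    warning; ``ref_window`` an equally sized sample from the current
    reference (training) set.  The shift is validated when p < alpha.
    """
    a = np.atleast_2d(pre_window)
    b = np.atleast_2d(ref_window)
    if a.shape[0] != b.shape[0]:
        raise ValueError("validation windows must have equal sample sizes")
    t2, p, reg = hotelling_t2(a, b)
    stage = "validated" if p < alpha else "false_alarm"
    return ShiftEvent(trial=trial, stage=stage, t2=t2, p_value=p,
                      window=a.shape[0], regularized=reg)


class CseDetector:
    """Online two-stage covariate-shift estimator.

    Feed one monitored feature vector per trial with :meth:`update`; the
    detector returns the events raised at that trial.  ``train_reference``
    must be the same (monitored, e.g. PCA-reduced) representation the
    monitor was calibrated on.

    Parameters
    ----------
    monitor : EwmaMonitor
        Calibrated stage-I chart.
    train_reference : ndarray (n, p)
        Reference pool for the stage-II contrast — the (monitored
        representation of the) current training set.  Refresh it with
        :meth:`update_reference` whenever the training pool is enriched.
    alpha : float
        Stage-II significance level.
    n_w : int
        Size of both Hotelling windows.
    refractory : int or None
        Minimum trials between confirmed shifts; defaults to ``n_w`` so
        that consecutive validations never share window data.
    seed : int
        Seed for sampling the reference window.
    """

    def __init__(self, monitor: EwmaMonitor, train_reference: np.ndarray,
                 alpha: float = 0.05, n_w: int = 20,
                 refractory: int | None = None, seed: int = 0) -> None:
        self.monitor = monitor
        self.reference = np.atleast_2d(np.asarray(train_reference, float))
        if self.reference.shape[1] != monitor.n_components:
            raise ValueError("reference dimensionality mismatch")
        self.alpha = alpha
        self.n_w = int(n_w)
        self.refractory = self.n_w if refractory is None else int(refractory)
        self._rng = np.random.default_rng(seed)
        self._history: list[np.ndarray] = []
        self._trial = -1
        self._last_validated = -math.inf
        self.events: list[ShiftEvent] = []

    def _recent_window(self) -> np.ndarray:
        """The n_w most recent monitored vectors ending at the current
        trial, padded from the reference tail early in the stream."""
        recent = self._history[-self.n_w:]
        short = self.n_w - len(recent)
        if short > 0:
            pad = self.reference[-short:]
            return np.vstack([pad, np.asarray(recent)])
        return np.asarray(recent)

    def update(self, x: np.ndarray) -> list[ShiftEvent]:
        self._trial += 1
        x = np.asarray(x, dtype=float).reshape(-1)
        _, e, warning = ewma_step(self.monitor, x)
        out: list[ShiftEvent] = []
        if not warning:
            self._history.append(x)
            return out
        comp = int(np.argmax(np.abs(e) / self.monitor.sigma_e))
        out.append(ShiftEvent(trial=self._trial, stage="warning",
                              component=comp))
        self._history.append(x)
        if self._trial - self._last_validated >= self.refractory:
            recent = self._recent_window()
            idx = self._rng.choice(len(self.reference),
                                   size=min(self.n_w, len(self.reference)),
                                   replace=len(self.reference) < self.n_w)
            ref = self.reference[idx]
            m = min(len(recent), len(ref))
            event = validate_warning(recent[-m:], ref[-m:],
                                     alpha=self.alpha, trial=self._trial)
            event.component = comp
            out.append(event)
            if event.stage == "validated":
                self._last_validated = self._trial
        self.events.extend(out)
        return out

    def update_reference(self, reference: np.ndarray) -> None:
        """Replace the stage-II reference pool (monitored representation
        of the enriched training set)."""
        reference = np.atleast_2d(np.asarray(reference, dtype=float))
        if reference.shape[1] != self.monitor.n_components:
            raise ValueError("reference dimensionality mismatch")
        self.reference = reference


def run_cse(monitor: EwmaMonitor, stream: np.ndarray,
            train_reference: np.ndarray, alpha: float = 0.05,
            n_w: int = 20, refractory: int | None = None,
            seed: int = 0) -> list[ShiftEvent]:
    """Run the two-stage detector over an entire monitored stream.

    Returns the ordered event list (warnings and their validations).
    Every validated event is preceded by a warning at the same trial.
    """
    stream = np.atleast_2d(np.asarray(stream, dtype=float))
    if stream.shape[1] != monitor.n_components:
        raise ValueError("stream dimensionality mismatch")
    det = CseDetector(monitor, train_reference, alpha=alpha, n_w=n_w,
                      refractory=refractory, seed=seed)
    for x in stream:
        det.update(x)
    return det.events


def validated_trials(events: list[ShiftEvent]) -> list[int]:
    """Trial indices of confirmed shifts, in order."""
    return [e.trial for e in events if e.stage == "validated"]


def isolated_shift_refractory(n_w: int) -> int:
    """Minimum spacing between validations when counting *distinct* shifts.

    Two validations closer than two windows can be triggered by the same
    physical transition (their recent windows overlap the same change), so
    counting them separately double-counts one shift.  For streaming
    adaptation the default refractory of ``n_w`` is preferable — an extra
    trigger merely retrains on more data — but for event counting use this
    spacing.
    """
    return 2 * n_w + 1
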
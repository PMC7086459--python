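"""Synthetic two-class non-stationary data with known covariate shifts.

Two generators are provided.

Feature level
    Trials are drawn from a multivariate Gaussian whose mean is translated
    at each change point while the labelling function stays fixed: labels
    are produced by a single linear rule sign(w·x + b), with a small
    label-flip rate.  Because the rule never changes, P(y|x) is identical
    across segments by construction — the translation is a pure covariate
    shift of the input marginal P(x).  Shift vectors are expressed in units
    of the pooled within-class standard deviation of each feature so that
    magnitudes are comparable across features of different scale.

Signal level
    EEG-like epochs: 1/f (pink) background noise plus a mu-band (8–12 Hz)
    rhythm whose amplitude is attenuated on class-dependent channel groups,
    emulating event-related desynchronization.  Post-change segments
    rescale the rhythm amplitude for all trials — a covariate shift in
    band-power space that leaves the class-conditional contrast intact.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
from scipy import stats

from driftbci.preprocess import EpochSet
from driftbci.features import FeatureStream


@dataclass(frozen=True)
class LabelRule:
    """Fixed linear labelling function: y = ω1 iff w·x + b > 0, flipped
    with probability ``noise``."""

    w: tuple[float, ...]
    b: float = 0.0
    noise: float = 0.05

    def __post_init__(self) -> None:
        if not 0 <= self.noise < 0.5:
            raise ValueError("label noise must be in [0, 0.5)")
        w = np.asarray(self.w, dtype=float)
        n = np.linalg.norm(w)
        if n == 0:
            raise ValueError("rule normal vector must be nonzero")
        object.__setattr__(self, "w", tuple(w / n))

    def apply(self, X: np.ndarray) -> np.ndarray:
        """Noiseless rule labels (1 for ω1, 2 for ω2)."""
        score = X @ np.asarray(self.w) + self.b
        return np.where(score > 0, 1, 2)


@dataclass
class ShiftScenario:
    """Description of a non-stationary two-class recording.

    Feature-level scenarios set ``n_features``; signal-level scenarios set
    ``n_channels``, ``fs`` and ``trial_len_s`` instead.  ``change_points``
    are 0-based trial indices of the first trial of each new segment and
    must be strictly increasing inside (1, n_trials).  ``shift_vectors``
    holds one entry per post-change segment: a length-D translation in
    pooled within-class SD units (feature level) or a scalar mu-amplitude
    multiplier (signal level).
    """

    n_trials: int = 280
    n_train: int = 120
    n_features: int | None = 8
    change_points: tuple[int, ...] = (200,)
    shift_vectors: tuple = ((1.5, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0),)
    label_rule: LabelRule | None = None
    class_balance: float = 0.5
    base_variances: tuple[float, ...] | None = None
    seed: int = 0
    # signal-level fields
    n_channels: int | None = None
    fs: float = 250.0
    trial_len_s: float = 4.0
    cue_onset_s: float = 0.5
    mu_amplitude: float = 4.0
    attenuation: float = 0.5
    noise_scale: float = 2.0

    def __post_init__(self) -> None:
        cps = tuple(int(c) for c in self.change_points)
        if any(b <= a for a, b in zip(cps, cps[1:])):
            raise ValueError("change_points must be strictly increasing")
        if any(not 1 < c < self.n_trials for c in cps):
            raise ValueError("change_points must lie inside (1, n_trials)")
        if len(self.shift_vectors) != len(cps):
            raise ValueError("one shift vector per change point required")
        if not 0 < self.class_balance < 1:
            raise ValueError("class_balance must be in (0, 1)")
        self.change_points = cps

    @property
    def is_signal_level(self) -> bool:
        return self.n_channels is not None

    def segment_ids(self) -> np.ndarray:
        seg = np.zeros(self.n_trials, dtype=int)
        for k, cp in enumerate(self.change_points, start=1):
            seg[cp:] = k
        return seg


@dataclass
class SyntheticStream:
    """Generated feature-level stream with ground-truth change points."""

    features: FeatureStream
    labels: np.ndarray
    segment_ids: np.ndarray
    true_change_points: tuple[int, ...]
    scenario: ShiftScenario

    def train_test(self) -> tuple[FeatureStream, FeatureStream,
                                  np.ndarray, np.ndarray]:
        """Split into the stationary training prefix and the test stream."""
        n = self.scenario.n_train
        X = self.features.X
        return (FeatureStream(X[:n], labels=self.labels[:n]),
                FeatureStream(X[n:]),
                self.labels[:n], self.labels[n:])


def _default_rule(n_features: int) -> LabelRule:
    w = np.zeros(n_features)
    w[0], w[1] = 0.2, np.sqrt(1 - 0.2 ** 2)
    return LabelRule(w=tuple(w))


def default_shift_direction(n_features: int = 8,
                            across_weight: float = 0.15) -> np.ndarray:
    """Unit shift direction of the reference scenario (pooled-SD space).

    Dominantly *along* the decision boundary with a small across-boundary
    component.  A translated marginal with a fixed linear rule degrades an
    empirically fitted classifier mainly through the wedge between the
    fitted and true hyperplanes, which widens with lateral distance from
    the training mass; a purely across-boundary translation instead moves
    mass away from the boundary region and is benign.  The small across
    component makes the shift cross the boundary (changing the class mix)
    without cancelling the lateral degradation.
    """
    w = np.asarray(_default_rule(n_features).w)
    axis0 = np.zeros(n_features)
    axis0[0] = 1.0
    lateral = axis0 - (axis0 @ w) * w
    lateral /= np.linalg.norm(lateral)
    v = lateral + across_weight * w
    return v / np.linalg.norm(v)


def default_feature_scenario(seed: int = 0, shift: float = 1.5,
                             n_features: int = 8) -> ShiftScenario:
    """The desk-scale reference scenario.

    120 stationary training trials followed by a 160-trial test stream
    with one change point mid-stream; the input marginal is translated by
    ``shift`` pooled within-class SDs along
    :func:`default_shift_direction` (boundary-crossing, lateral-dominant).
    Base feature variances decay geometrically (ratio 0.25), mimicking the
    rapidly decaying spectrum of concatenated log-variance CSP features.
    """
    vec = shift * default_shift_direction(n_features)
    return ShiftScenario(
        n_trials=280, n_train=120, n_features=n_features,
        change_points=(200,), shift_vectors=(tuple(vec),),
        label_rule=_default_rule(n_features),
        base_variances=tuple(0.25 ** np.arange(n_features)),
        seed=seed,
    )


def default_signal_scenario(seed: int = 0, band_scale: float = 1.5,
                            attenuation: float = 0.5) -> ShiftScenario:
    """EEG-like reference scenario: 10 channels at 250 Hz, 4-s trials."""
    return ShiftScenario(
        n_trials=160, n_train=80, n_features=None, n_channels=10,
        change_points=(120,), shift_vectors=(band_scale,),
        fs=250.0, trial_len_s=4.0, cue_onset_s=0.5,
        attenuation=attenuation, seed=seed,
    )


def _base_covariance(scenario: ShiftScenario) -> np.ndarray:
    if scenario.base_variances is not None:
        v = np.asarray(scenario.base_variances, dtype=float)
        if len(v) != scenario.n_features or np.any(v <= 0):
            raise ValueError("base_variances must be positive, length D")
    else:
        v = np.ones(scenario.n_features)
    return np.diag(v)


def _rule_and_offset(scenario: ShiftScenario,
                     cov: np.ndarray) -> LabelRule:
    """Resolve the label rule, deriving the offset from class_balance.

    With x ~ N(0, cov) in the first segment, w·x is N(0, w'Σw); the offset
    b is set so that P(w·x + b > 0) equals the requested class balance.
    """
    rule = scenario.label_rule or _default_rule(scenario.n_features)
    if scenario.class_balance != 0.5 or rule.b == 0.0:
        w = np.asarray(rule.w)
        s = float(np.sqrt(w @ cov @ w))
        b = s * stats.norm.ppf(scenario.class_balance)
        rule = LabelRule(w=rule.w, b=b, noise=rule.noise)
    return rule


def pooled_within_class_sd(scenario: ShiftScenario) -> np.ndarray:
    """Pooled within-class SD of each feature under the base distribution.

    Computed in closed form: with t = w·x + b Gaussian and x_j = a_j t + r_j
    (r_j independent of t), conditioning on the class halfspace {t > 0} or
    {t <= 0} replaces var(t) by the corresponding truncated-normal variance.
    Class proportions weight the two conditional variances.
    """
    cov = _base_covariance(scenario)
    rule = _rule_and_offset(scenario, cov)
    w = np.asarray(rule.w)
    var_t = float(w @ cov @ w)
    cov_xt = cov @ w                       # cov(x_j, w·x)
    a = cov_xt / var_t
    # t ~ N(b, var_t) in score coordinates; classes are t > 0 and t <= 0
    alpha = -rule.b / np.sqrt(var_t)
    p1 = 1 - stats.norm.cdf(alpha)
    # truncated normal variances of t above / below alpha (standardized)
    phi, Phi = stats.norm.pdf(alpha), stats.norm.cdf(alpha)
    lam_hi = phi / max(1 - Phi, 1e-12)
    var_hi = var_t * (1 + alpha * lam_hi - lam_hi ** 2)
    lam_lo = phi / max(Phi, 1e-12)
    var_lo = var_t * (1 - alpha * lam_lo - lam_lo ** 2)
    resid = np.diag(cov) - a ** 2 * var_t
    pooled = p1 * (resid + a ** 2 * var_hi) + (1 - p1) * (resid + a ** 2 * var_lo)
    return np.sqrt(np.maximum(pooled, 0.0))


def simulate_feature_stream(scenario: ShiftScenario,
                            rng: np.random.Generator | None = None
                            ) -> SyntheticStream:
    """Draw a feature-level stream according to the scenario.

    Features come from a segment-wise translated Gaussian; labels from the
    fixed linear rule plus independent flip noise, so the conditional
    P(y|x) is identical in every segment.
    """
    if scenario.is_signal_level or scenario.n_features is None:
        raise ValueError("feature-level scenario required")
    rng = rng if rng is not None else np.random.default_rng(scenario.seed)
    D = scenario.n_features
    cov = _base_covariance(scenario)
    rule = _rule_and_offset(scenario, cov)
    sd = np.sqrt(np.diag(cov))
    pooled = pooled_within_class_sd(scenario)

    seg = scenario.segment_ids()
    means = np.zeros((len(scenario.change_points) + 1, D))
    for k, vec in enumerate(scenario.shift_vectors, start=1):
        vec = np.asarray(vec, dtype=float)
        if vec.shape != (D,):
            raise ValueError("feature-level shift vectors must be length D")
        means[k] = means[k - 1] + vec * pooled
    X = rng.standard_normal((scenario.n_trials, D)) * sd + means[seg]

    labels = rule.apply(X)
    flips = rng.random(scenario.n_trials) < rule.noise
    labels = np.where(flips, 3 - labels, labels)
    return SyntheticStream(
        features=FeatureStream(X, labels=labels),
        labels=labels,
        segment_ids=seg,
        true_change_points=scenario.change_points,
        scenario=scenario,
    )


def _pink_noise(rng: np.random.Generator, n_trials: int, n_channels: int,
                n_samples: int, fs: float) -> np.ndarray:
    """Pink (1/f amplitude) noise via spectral shaping with random phase."""
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / fs)
    amp = np.zeros_like(freqs)
    amp[1:] = 1.0 / np.sqrt(freqs[1:])
    phases = rng.uniform(0, 2 * np.pi, size=(n_trials, n_channels, len(freqs)))
    spec = amp * np.exp(1j * phases)
    noise = np.fft.irfft(spec, n=n_samples, axis=-1)
    noise /= noise.std(axis=-1, keepdims=True)
    return noise


def simulate_eeg_epochs(scenario: ShiftScenario,
                        rng: np.random.Generator | None = None) -> EpochSet:
    """Generate EEG-like epochs with class-dependent mu-band attenuation.

    Channels are split into two groups; class ω1 attenuates the 8–12 Hz
    rhythm on group A (first half of channels), class ω2 on group B, from
    the cue onset onward.  Post-change segments multiply the rhythm
    amplitude of every trial by the segment's scalar shift factor.
    """
    if not scenario.is_signal_level:
        raise ValueError("signal-level scenario required")
    if scenario.fs <= 2 * 12.0:
        raise ValueError("sampling rate too low for the 8-12 Hz band")
    rng = rng if rng is not None else np.random.default_rng(scenario.seed)
    n, c = scenario.n_trials, scenario.n_channels
    ns = int(round(scenario.trial_len_s * scenario.fs))
    t = np.arange(ns) / scenario.fs

    labels = np.where(rng.random(n) < scenario.class_balance, 1, 2)
    seg = scenario.segment_ids()
    scales = np.concatenate(
        [[1.0], [float(s) for s in scenario.shift_vectors]])[seg]

    data = scenario.noise_scale * _pink_noise(rng, n, c, ns, scenario.fs)
    group_a = np.arange(c // 2)
    group_b = np.arange(c // 2, c)
    cue_idx = int(np.floor(scenario.cue_onset_s * scenario.fs))
    mi_mask = np.zeros(ns)
    mi_mask[cue_idx:] = 1.0

    freq = rng.uniform(9.0, 11.0, size=n)      # per-trial mu frequency
    phase = rng.uniform(0, 2 * np.pi, size=(n, c))
    for i in range(n):
        carrier = np.sin(2 * np.pi * freq[i] * t[None, :] + phase[i][:, None])
        amp = np.full((c, ns), scenario.mu_amplitude * scales[i])
        att = group_a if labels[i] == 1 else group_b
        amp[att] *= 1.0 - scenario.attenuation * mi_mask[None, :]
        data[i] += amp * carrier
    return EpochSet(data=data, labels=labels, fs=scenario.fs,
                    cue_onset_s=scenario.cue_onset_s)


def _plain(obj):
    """Recursively cast numpy scalars/containers to plain Python types."""
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    return obj


def scenario_to_dict(scenario: ShiftScenario) -> dict:
    """JSON/YAML-serializable scenario description."""
    d = asdict(scenario)
    if scenario.label_rule is not None:
        d["label_rule"] = {"w": list(scenario.label_rule.w),
                           "b": scenario.label_rule.b,
                           "noise": scenario.label_rule.noise}
    return _plain(d)


def scenario_from_dict(d: dict) -> ShiftScenario:
    d = dict(d)
    if d.get("label_rule"):
        lr = d["label_rule"]
        d["label_rule"] = LabelRule(w=tuple(lr["w"]), b=lr.get("b", 0.0),
                                    noise=lr.get("noise", 0.05))
    for key in ("change_points", "base_variances"):
        if d.get(key) is not None:
            d[key] = tuple(d[key])
    if d.get("shift_vectors") is not None:
        d["shift_vectors"] = tuple(
            tuple(v) if isinstance(v, Sequence) else float(v)
            for v in d["shift_vectors"])
    return ShiftScenario(**d)
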
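"""Unsupervised adaptive ensemble learning over a non-stationary stream.

An ordered ensemble of LDA classifiers is grown during the evaluation
phase: in the *active* scheme a new classifier is trained each time the
two-stage covariate-shift detector confirms a shift; in the *passive*
scheme adaptation happens after every fixed interval of trials (default
10).  Between adaptations, unlabelled trials whose decision confidence
exceeds the gate threshold Γ are stored with their predicted labels and
merged into the training pool at the next adaptation — unsupervised
enrichment via transduction.  Three classifier combinations are supported:

* C-1: a single PWKNN model is both the predictor and the gate; the
  "ensemble" degenerates to one transductive store refreshed at
  adaptations;
* C-2: the LDA ensemble predicts and its weight-averaged posterior gates;
* C-3: the LDA ensemble predicts while the PWKNN confidence ratio gates
  (transductive-inductive combination).

Prequential contract: every trial is predicted before any adaptation may
use it; original labelled trials are never relabelled or removed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

from driftbci.pwknn import PwknnModel, gate
from driftbci.shiftdetect import CseDetector, ShiftEvent


@dataclass
class LdaClassifier:
    """One ensemble member: pooled-covariance LDA with empirical priors."""

    clf: LinearDiscriminantAnalysis
    classes: np.ndarray
    creation_trial: int = -1
    weight: float = 1.0

    def predict(self, x: np.ndarray) -> int:
        return int(self.clf.predict(np.atleast_2d(x))[0])

    def posterior(self, x: np.ndarray) -> np.ndarray:
        """Posterior over (ω1, ω2) in label order."""
        p = self.clf.predict_proba(np.atleast_2d(x))[0]
        order = np.argsort(self.classes)
        return p[order]


def train_lda(X: np.ndarray, y: np.ndarray, creation_trial: int = -1,
              weight: float = 1.0) -> LdaClassifier:
    """Fit a two-class LDA with pooled covariance and empirical priors."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y)
    classes = np.unique(y)
    if len(classes) != 2:
        raise ValueError(f"both classes required, got {classes}")
    if len(y) <= 2:
        raise ValueError("need more than two training samples")
    clf = LinearDiscriminantAnalysis(solver="lsqr", shrinkage=None)
    try:
        clf.fit(X, y)
    except np.linalg.LinAlgError:
        warnings.warn("singular pooled covariance; refitting with shrinkage")
        clf = LinearDiscriminantAnalysis(solver="lsqr", shrinkage="auto")
        clf.fit(X, y)
    return LdaClassifier(clf=clf, classes=clf.classes_,
                         creation_trial=creation_trial, weight=weight)


@dataclass
class EnsembleState:
    """Ordered classifiers with voting weights and the evolving pools."""

    classifiers: list[LdaClassifier] = field(default_factory=list)
    X_train: np.ndarray | None = None
    y_train: np.ndarray | None = None
    X_new: list[np.ndarray] = field(default_factory=list)
    y_new: list[int] = field(default_factory=list)
    adaptation_log: list[int] = field(default_factory=list)

    @property
    def size(self) -> int:
        return len(self.classifiers)


def vote(classifiers: list[LdaClassifier], x: np.ndarray
         ) -> tuple[int, float]:
    """Weighted majority vote over hard labels.

    Returns the winning label and its weight share.  Exact weight ties are
    broken toward the label of the most recently added classifier, which
    reflects the newest data distribution.
    """
    if not classifiers:
        raise ValueError("empty ensemble")
    votes: dict[int, float] = {}
    labels = []
    for c in classifiers:
        lab = c.predict(x)
        labels.append(lab)
        votes[lab] = votes.get(lab, 0.0) + c.weight
    total = sum(votes.values())
    best = max(votes.values())
    winners = [lab for lab, v in votes.items() if v == best]
    y_hat = labels[-1] if len(winners) > 1 else winners[0]
    return y_hat, votes[y_hat] / total


def _ensemble_posterior(classifiers: list[LdaClassifier],
                        x: np.ndarray) -> np.ndarray:
    """Weight-averaged LDA posterior over (ω1, ω2)."""
    wsum = sum(c.weight for c in classifiers)
    post = np.zeros(2)
    for c in classifiers:
        post += c.weight * c.posterior(x)
    return post / wsum


@dataclass
class StreamConfig:
    """Configuration of one streaming run."""

    scheme: str = "active"          # "active" | "passive"
    combination: str = "c3"         # "c1" | "c2" | "c3"
    interval: int = 10              # passive adaptation period (trials)
    K: int = 5
    sigma: float | None = None
    # self-training gate: at 0.8 the gated pseudo-labels' purity on the
    # reference scenario roughly matches the labelled pool's own purity
    # (1 - label-noise), so enrichment adds data without adding noise
    gamma: float = 0.8
    weight_mode: str = "validation"  # "validation" | "uniform"

    def __post_init__(self) -> None:
        if self.scheme not in ("active", "passive"):
            raise ValueError("scheme must be 'active' or 'passive'")
        if self.combination not in ("c1", "c2", "c3"):
            raise ValueError("combination must be 'c1', 'c2' or 'c3'")
        if self.interval < 1:
            raise ValueError("interval must be >= 1")


@dataclass
class StreamResult:
    """Per-trial record of one prequential run."""

    predictions: np.ndarray
    confidences: np.ndarray
    gate_decisions: np.ndarray
    ensemble_sizes: np.ndarray
    adaptation_trials: list[int]
    shift_events: list[ShiftEvent]
    state: EnsembleState


def _classifier_weight(clf: LdaClassifier, validation, mode: str) -> float:
    if mode == "uniform" or validation is None:
        return 1.0
    Xv, yv = validation
    acc = float(np.mean(clf.clf.predict(Xv) == yv))
    return float(np.clip(acc, 0.01, 1.0))


def run_stream(train_X: np.ndarray, train_y: np.ndarray,
               stream_X: np.ndarray, config: StreamConfig,
               detector: CseDetector | None = None,
               monitor_transform=None,
               validation: tuple[np.ndarray, np.ndarray] | None = None
               ) -> StreamResult:
    """Prequential run of the adaptive ensemble over an unlabelled stream.

    Parameters
    ----------
    train_X, train_y : labelled training pool (initial X^Train).
    stream_X : unlabelled test stream, one feature vector per trial.
    config : scheme/combination and model parameters.
    detector : calibrated online shift detector (required for the active
        scheme); fed ``monitor_transform(x)`` (identity if None) per trial.
    monitor_transform : optional map from classifier features to the
        monitored (e.g. PCA-reduced) space.
    validation : optional held-out labelled split used to weight newly
        added classifiers.

    Each trial is predicted first; if the gate passes, the trial and its
    predicted label join X^New; at an adaptation trigger X^New is merged
    into X^Train, a new classifier is trained on the merged pool (C-2/C-3)
    or the PWKNN store is refreshed (C-1), and X^New is cleared.
    """
    train_X = np.atleast_2d(np.asarray(train_X, dtype=float))
    train_y = np.asarray(train_y)
    stream_X = np.atleast_2d(np.asarray(stream_X, dtype=float))
    if config.scheme == "active" and detector is None:
        raise ValueError("active scheme requires a calibrated detector")
    if monitor_transform is None:
        monitor_transform = lambda v: v  # noqa: E731

    state = EnsembleState(X_train=train_X.copy(), y_train=train_y.copy())
    pwknn = PwknnModel(train_X, train_y, K=config.K, sigma=config.sigma,
                       gamma=config.gamma)
    if config.combination in ("c2", "c3"):
        first = train_lda(train_X, train_y, creation_trial=-1)
        first.weight = _classifier_weight(first, validation,
                                          config.weight_mode)
        state.classifiers.append(first)

    n = stream_X.shape[0]
    preds = np.empty(n, dtype=int)
    confs = np.empty(n, dtype=float)
    gates = np.zeros(n, dtype=bool)
    sizes = np.empty(n, dtype=int)
    events: list[ShiftEvent] = []

    for i, x in enumerate(stream_X):
        # --- predict (prequential: before any use of this trial) ---
        dec = pwknn.classify(x) if config.combination in ("c1", "c3") else None
        if config.combination == "c1":
            y_hat, conf = dec.y_hat, dec.cr
        else:
            y_hat, _ = vote(state.classifiers, x)
            conf = float(_ensemble_posterior(state.classifiers, x).max())

        preds[i] = y_hat
        sizes[i] = max(state.size, 1)

        # --- gate for unsupervised enrichment ---
        if config.combination == "c2":
            accept = conf > config.gamma
            pseudo = y_hat
        else:
            # c1, c3: the PWKNN confidence ratio gates its transductive
            # label — the non-parametric estimate is what injects new
            # information into the inductive ensemble
            accept = gate(dec, config.gamma)
            pseudo = dec.y_hat
        confs[i] = dec.cr if dec is not None else conf
        if accept:
            gates[i] = True
            state.X_new.append(x.copy())
            state.y_new.append(int(pseudo))

        # --- adaptation trigger ---
        trigger = False
        if config.scheme == "passive":
            trigger = (i + 1) % config.interval == 0
        else:
            new_events = detector.update(monitor_transform(x))
            events.extend(new_events)
            trigger = any(e.stage == "validated" for e in new_events)

        if trigger:
            state.adaptation_log.append(i)
            if state.X_new:
                state.X_train = np.vstack([state.X_train,
                                           np.asarray(state.X_new)])
                state.y_train = np.concatenate([state.y_train,
                                                np.asarray(state.y_new)])
                state.X_new, state.y_new = [], []
            if config.combination == "c1":
                pwknn.replace_store(state.X_train, state.y_train)
            else:
                if len(np.unique(state.y_train)) < 2:
                    warnings.warn("adaptation skipped: a class is missing")
                else:
                    clf = train_lda(state.X_train, state.y_train,
                                    creation_trial=i)
                    clf.weight = _classifier_weight(clf, validation,
                                                    config.weight_mode)
                    state.classifiers.append(clf)
                    if config.combination == "c3":
                        # keep the transductive gate in sync with the pool
                        pwknn.replace_store(state.X_train, state.y_train)
            if detector is not None:
                # stage-II reference follows the enriched training pool, so
                # a persisting shift stops re-validating once absorbed
                detector.update_reference(
                    np.atleast_2d(monitor_transform(state.X_train)))

    return StreamResult(predictions=preds, confidences=confs,
                        gate_decisions=gates, ensemble_sizes=sizes,
                        adaptation_trials=state.adaptation_log,
                        shift_events=events, state=state)


def evaluate(result: StreamResult, true_labels: np.ndarray) -> float:
    """Prequential accuracy in percent."""
    true_labels = np.asarray(true_labels)
    if len(true_labels) != len(result.predictions):
        raise ValueError("labels do not align with the stream")
    return float(100.0 * np.mean(result.predictions == true_labels))


def paired_wilcoxon(acc_a: np.ndarray, acc_b: np.ndarray,
                    alternative: str = "two-sided") -> float:
    """Paired Wilcoxon signed-rank p-value between two accuracy series.

    All-zero differences make the test degenerate; that is reported as
    p = 1 (no evidence of a difference).
    """
    a = np.asarray(acc_a, dtype=float)
    b = np.asarray(acc_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired series must have equal length")
    if np.allclose(a, b):
        return 1.0
    return float(stats.wilcoxon(a, b, alternative=alternative,
                                zero_method="wilcox").pvalue)
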
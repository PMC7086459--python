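"""Spatial filtering and feature extraction.

Per frequency band, common spatial patterns (CSP) are fitted by jointly
diagonalizing the two class-average normalized spatial covariance matrices.
With W the matrix of spatial filters (rows) and Z = W E' the spatially
filtered trial, the per-trial features are the normalized log-variances of
the 2h retained extreme components,

    X_p = log( var(Z_p) / sum_{i=1..2h} var(Z_i) ),

concatenated over all bands of the filter bank.  A PCA model fitted on
training features (and frozen afterwards) provides the low-dimensional
monitoring space used by the covariate-shift detector.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import linalg
from sklearn.decomposition import PCA

from driftbci.preprocess import EpochSet


@dataclass
class FeatureStream:
    """Ordered per-trial feature matrix, optionally labelled.

    ``X`` has shape (n_trials, D).  Trial order is the stream order; no
    operation in this package ever reorders it.
    """

    X: np.ndarray
    labels: np.ndarray | None = None
    band_dims: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        if self.labels is not None:
            self.labels = np.asarray(self.labels)
            if len(self.labels) != self.X.shape[0]:
                raise ValueError("labels length must match trial count")
        if not self.band_dims:
            self.band_dims = [self.X.shape[1]]

    @property
    def n_trials(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    def to_csv(self, path: str | Path) -> None:
        """Write one row per trial (features..., label) with a JSON header."""
        path = Path(path)
        header = {"band_dims": self.band_dims,
                  "labelled": self.labels is not None}
        cols = [f"f{i}" for i in range(self.n_features)]
        df = pd.DataFrame(self.X, columns=cols)
        if self.labels is not None:
            df["label"] = self.labels
        with open(path, "w") as fh:
            fh.write("# " + json.dumps(header) + "\n")
            df.to_csv(fh, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "FeatureStream":
        path = Path(path)
        with open(path) as fh:
            first = fh.readline()
            header = json.loads(first.lstrip("# ").strip()) if \
                first.startswith("#") else {}
            df = pd.read_csv(fh) if first.startswith("#") else \
                pd.read_csv(path)
        labels = df.pop("label").to_numpy() if "label" in df else None
        return cls(df.to_numpy(float), labels=labels,
                   band_dims=header.get("band_dims", []))


@dataclass
class CspModel:
    """Fitted CSP spatial filters for one band.

    ``W`` holds all filters as rows, ordered by descending generalized
    eigenvalue for the first class; ``filters_`` keeps the first h and
    last h rows actually used for feature extraction.
    """

    W: np.ndarray
    eigenvalues: np.ndarray
    h: int
    band: tuple[float, float] | None = None
    cov1_: np.ndarray | None = None
    cov2_: np.ndarray | None = None

    @property
    def filters_(self) -> np.ndarray:
        if 2 * self.h > self.W.shape[0]:
            raise ValueError("2h exceeds the number of channels")
        return np.vstack([self.W[: self.h], self.W[-self.h:]])


def _normalized_class_covariances(
    epochs: EpochSet, ridge: float = 1e-8
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    classes = epochs.classes
    if len(classes) != 2:
        raise ValueError(f"exactly two classes required, got {classes}")
    covs = []
    for c in classes:
        trials = epochs.data[epochs.labels == c]
        if trials.shape[0] < 2:
            raise ValueError(f"need >= 2 trials for class {c!r}")
        per_trial = np.einsum("tcs,tds->tcd", trials, trials)
        traces = np.trace(per_trial, axis1=1, axis2=2)
        if np.any(traces <= 0):
            raise ValueError("zero-power trial encountered")
        per_trial /= traces[:, None, None]
        cov = per_trial.mean(axis=0)
        covs.append(cov + ridge * np.eye(cov.shape[0]))
    return covs[0], covs[1], classes


def csp_fit(band_epochs: EpochSet, h: int = 2, ridge: float = 1e-8,
            band: tuple[float, float] | None = None) -> CspModel:
    """Fit CSP filters from a labelled epoch set (one band).

    Solves the generalized eigenproblem S1 w = mu (S1 + S2) w on the
    class-average trace-normalized spatial covariances.  The returned W
    satisfies the whitening identity W (S1 + S2) W^T = I; rows are ordered
    by descending eigenvalue (variance captured for the first class) and
    each row is scaled so its largest-magnitude coefficient is positive.
    """
    s1, s2, _ = _normalized_class_covariances(band_epochs, ridge)
    composite = s1 + s2
    try:
        vals, vecs = linalg.eigh(s1, composite)
    except linalg.LinAlgError:
        warnings.warn("singular composite covariance; applying shrinkage")
        composite = composite + 1e-4 * np.trace(composite) / len(composite) \
            * np.eye(len(composite))
        vals, vecs = linalg.eigh(s1, composite)
    order = np.argsort(vals)[::-1]
    vals = vals[order]
    W = vecs[:, order].T
    # deterministic sign: largest-|coefficient| positive per filter
    signs = np.sign(W[np.arange(W.shape[0]), np.argmax(np.abs(W), axis=1)])
    W = W * signs[:, None]
    if 2 * h > W.shape[0]:
        raise ValueError(f"2h={2 * h} exceeds channel count {W.shape[0]}")
    return CspModel(W=W, eigenvalues=vals, h=h, band=band, cov1_=s1, cov2_=s2)


def csp_transform(model: CspModel, epochs: EpochSet) -> FeatureStream:
    """Normalized log-variance features of the retained CSP components.

    Per trial the 2h features are log(var_p / sum var), so exp(features)
    sums to one within the band and the features are invariant to trial
    scaling.  Zero-variance components are floored at a tiny multiple of
    the largest component variance.
    """
    if epochs.n_channels != model.W.shape[1]:
        raise ValueError("channel count does not match the CSP model")
    Z = np.einsum("fc,tcs->tfs", model.filters_, epochs.data)
    var = Z.var(axis=-1)
    floor = np.finfo(float).eps * max(var.max(), 1.0)
    if np.any(var <= floor):
        warnings.warn("zero-variance CSP component; flooring")
        var = np.maximum(var, floor)
    feats = np.log(var / var.sum(axis=1, keepdims=True))
    return FeatureStream(feats, labels=epochs.labels.copy(),
                         band_dims=[feats.shape[1]])


def concat_bands(streams: list[FeatureStream]) -> FeatureStream:
    """Concatenate per-band feature blocks in band order."""
    if not streams:
        raise ValueError("no streams to concatenate")
    n = streams[0].n_trials
    if any(s.n_trials != n for s in streams):
        raise ValueError("streams have mismatched trial counts")
    X = np.hstack([s.X for s in streams])
    labels = streams[0].labels
    dims = [d for s in streams for d in s.band_dims]
    return FeatureStream(X, labels=None if labels is None else labels.copy(),
                         band_dims=dims)


@dataclass
class PcaModel:
    """Frozen PCA projection used by the shift monitor."""

    components: np.ndarray     # (k, D), orthonormal rows
    mean: np.ndarray
    variance_fractions: np.ndarray

    @property
    def n_components(self) -> int:
        return self.components.shape[0]

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return (X - self.mean) @ self.components.T


def pca_fit_reduce(train: FeatureStream,
                   variance_target: float = 0.90
                   ) -> tuple[PcaModel, FeatureStream]:
    """Fit mean-centered PCA on training features and reduce them.

    Retains the smallest number of components whose cumulative explained
    variance reaches ``variance_target``; a target of 1.0 keeps
    min(n_trials - 1, D) components.
    """
    if not 0 < variance_target <= 1:
        raise ValueError("variance_target must be in (0, 1]")
    if train.n_trials < 2:
        raise ValueError("need at least two trials to fit PCA")
    pca = PCA(svd_solver="full")
    pca.fit(train.X)
    frac = pca.explained_variance_ratio_
    cum = np.cumsum(frac)
    if variance_target >= 1.0:
        k = min(train.n_trials - 1, train.n_features)
    else:
        k = int(np.searchsorted(cum, variance_target - 1e-12) + 1)
        k = min(k, len(frac))
    model = PcaModel(components=pca.components_[:k].copy(),
                     mean=pca.mean_.copy(),
                     variance_fractions=frac[:k].copy())
    reduced = FeatureStream(model.transform(train.X),
                            labels=None if train.labels is None
                            else train.labels.copy())
    return model, reduced
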
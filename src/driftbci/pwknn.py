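"""Probabilistic weighted K-nearest-neighbour classification.

Neighbours of a query are weighted by an RBF kernel of their Euclidean
distance,

    κ(x_p, x_q) = exp(-||x_p - x_q||² / (2 σ²)),

and the class posterior (confidence ratio) is the kernel-weighted vote

    CR_ω1 = Σ_q κ(x_p, x_q) · 1[y_q = ω1] / Σ_q κ(x_p, x_q),
    CR_ω2 = 1 - CR_ω1,        CR = max(CR_ω1, CR_ω2).

As σ → ∞ the weights flatten and CR reduces to the plain K-NN posterior
K_ωi / K.  The CR gates unsupervised self-training: a trial is appended to
the training pool only when CR strictly exceeds the threshold Γ.  The
implementation is a straightforward O(m·D) scan per query, preserving the
linear-time contract of instance-based prediction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np


def rbf_weight(x_p: np.ndarray, x_q: np.ndarray, sigma: float) -> float:
    """RBF kernel weight in (0, 1]; exactly 1 iff the points coincide."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    d2 = float(np.sum((np.asarray(x_p, float) - np.asarray(x_q, float)) ** 2))
    return float(np.exp(-d2 / (2.0 * sigma ** 2)))


def median_heuristic(X: np.ndarray) -> float:
    """Median pairwise Euclidean distance (fallback 1.0 for degenerate sets)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n = X.shape[0]
    if n < 2:
        return 1.0
    sq = np.sum(X ** 2, axis=1)
    d2 = np.maximum(sq[:, None] + sq[None, :] - 2 * X @ X.T, 0.0)
    iu = np.triu_indices(n, k=1)
    med = float(np.median(np.sqrt(d2[iu])))
    return med if med > 0 else 1.0


@dataclass
class PwknnDecision:
    """Classification outcome with the confidence ratio used for gating."""

    y_hat: int
    cr_class1: float
    cr_class2: float
    neighbor_indices: np.ndarray
    weights: np.ndarray

    @property
    def cr(self) -> float:
        """Overall decision confidence; in [0.5, 1] for the binary task."""
        return max(self.cr_class1, self.cr_class2)


@dataclass
class PwknnModel:
    """Instance store with neighbour count K, kernel width σ and gate Γ.

    ``sigma=None`` applies the median heuristic, recomputed whenever the
    store changes.  Class labels must be the two integers 1 (ω1) and 2 (ω2).
    """

    X: np.ndarray
    y: np.ndarray
    K: int = 5
    sigma: float | None = None
    gamma: float = 0.7
    _sigma_value: float = field(init=False, repr=False, default=1.0)

    def __post_init__(self) -> None:
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        self.y = np.asarray(self.y)
        if self.X.shape[0] == 0:
            raise ValueError("instance store must be non-empty")
        if len(self.y) != self.X.shape[0]:
            raise ValueError("labels must match store size")
        if self.K < 1:
            raise ValueError("K must be >= 1")
        if not 0.5 <= self.gamma <= 1:
            raise ValueError("gamma must be in [0.5, 1]")
        self._refresh_sigma()

    def _refresh_sigma(self) -> None:
        self._sigma_value = (median_heuristic(self.X)
                             if self.sigma is None else float(self.sigma))
        if self._sigma_value <= 0:
            raise ValueError("sigma must be positive")

    @property
    def sigma_value(self) -> float:
        return self._sigma_value

    @property
    def store_size(self) -> int:
        return self.X.shape[0]

    def replace_store(self, X: np.ndarray, y: np.ndarray) -> None:
        """Swap in an enriched instance store (σ re-estimated if automatic)."""
        self.X = np.atleast_2d(np.asarray(X, dtype=float))
        self.y = np.asarray(y)
        if len(self.y) != self.X.shape[0] or self.X.shape[0] == 0:
            raise ValueError("invalid store")
        self._refresh_sigma()

    def classify(self, x: np.ndarray) -> PwknnDecision:
        return classify(self, x)


def classify(model: PwknnModel, x: np.ndarray) -> PwknnDecision:
    """Kernel-weighted K-NN posterior for one query point.

    Neighbour ties at the K-th distance are resolved toward the smallest
    store indices (stable argsort), and an exact posterior tie CR = 0.5
    predicts the class of the single nearest neighbour.
    """
    x = np.asarray(x, dtype=float).ravel()
    if x.shape[0] != model.X.shape[1]:
        raise ValueError("query dimensionality mismatch")
    K = model.K
    if K > model.store_size:
        warnings.warn(f"K={K} exceeds store size {model.store_size}; clamped")
        K = model.store_size
    d2 = np.sum((model.X - x) ** 2, axis=1)
    idx = np.argsort(d2, kind="stable")[:K]
    w = np.exp(-d2[idx] / (2.0 * model.sigma_value ** 2))
    total = float(w.sum())
    if total <= 0:           # kernel underflow: fall back to uniform weights
        w = np.ones(K)
        total = float(K)
    cr1 = float(w[model.y[idx] == 1].sum() / total)
    cr2 = 1.0 - cr1
    if cr1 > cr2:
        y_hat = 1
    elif cr2 > cr1:
        y_hat = 2
    else:                    # posterior tie: single nearest neighbour decides
        y_hat = int(model.y[idx[0]])
    return PwknnDecision(y_hat=y_hat, cr_class1=cr1, cr_class2=cr2,
                         neighbor_indices=idx, weights=w)


def gate(decision: PwknnDecision, gamma: float) -> bool:
    """Self-training gate: accept only when CR strictly exceeds Γ."""
    return decision.cr > gamma


K_GRID: tuple[int, ...] = (1, 3, 5, 7, 9, 11, 13, 15)
GAMMA_GRID: tuple[float, ...] = tuple(np.round(np.arange(0.55, 0.96, 0.05), 2))


def select_parameters(train_X: np.ndarray, train_y: np.ndarray,
                      val_X: np.ndarray, val_y: np.ndarray,
                      sigma: float | None = None,
                      k_grid: tuple[int, ...] = K_GRID,
                      gamma_grid: tuple[float, ...] = GAMMA_GRID
                      ) -> tuple[int, float]:
    """Grid-search K and Γ on a held-out validation split.

    K maximizes validation accuracy (smallest K on ties).  Γ is then chosen
    to maximize the net benefit of gated self-training on the validation
    split — accepted-and-correct minus accepted-and-wrong trials — which
    favours thresholds that admit many pseudo-labels only when they are
    reliable (largest Γ on ties, the conservative choice).
    """
    best_k, best_acc = k_grid[0], -1.0
    decisions_by_k: dict[int, list[PwknnDecision]] = {}
    for k in k_grid:
        model = PwknnModel(train_X, train_y, K=k, sigma=sigma)
        decs = [model.classify(x) for x in np.atleast_2d(val_X)]
        decisions_by_k[k] = decs
        acc = float(np.mean([d.y_hat == y for d, y in zip(decs, val_y)]))
        if acc > best_acc:
            best_k, best_acc = k, acc
    decs = decisions_by_k[best_k]
    best_gamma, best_net = gamma_grid[0], -np.inf
    for g in gamma_grid:
        accepted = [d for d in decs if gate(d, g)]
        correct = sum(d.y_hat == y for d, y in zip(decs, val_y) if gate(d, g))
        net = 2 * correct - len(accepted)
        if net >= best_net:      # ties move toward larger (safer) gamma
            best_gamma, best_net = g, net
    return best_k, float(best_gamma)
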
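"""L1-regularized logistic tensor regression (LTR).

The classifier scores a transformed fusion tensor ``V`` by the tensor inner
product with a coefficient tensor ``Z`` of the same shape:

    Pr[y = 1 | V, Z] = sigmoid(<Z, V>).

``Z`` is estimated by minimizing the Bernoulli negative log-likelihood plus
an L1 penalty ``lambda * ||Z||_1`` with a monotone accelerated proximal
gradient method (soft-thresholding prox, backtracking line search, monotone
FISTA so the recorded objective never increases).  Ties at probability 0.5
classify as the negative class.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .tensor_core import inner_product

__all__ = [
    "LTRModel",
    "predict_proba",
    "penalized_nll",
    "ltr_fit",
    "ltr_fit_cv",
    "classify",
]


@dataclass
class LTRModel:
    """Coefficient tensor plus regularization and fit metadata."""

    Z: np.ndarray
    lambda_l1: float
    iterations: int = 0
    final_objective: float = float("nan")
    converged: bool = False
    objective_history: list[float] = field(default_factory=list)


def _logits(stack: np.ndarray, Z: np.ndarray) -> np.ndarray:
    return np.tensordot(stack, Z, axes=Z.ndim)


def _sigmoid(t: np.ndarray) -> np.ndarray:
    # Numerically stable in both tails.
    out = np.empty_like(t, dtype=float)
    pos = t >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-t[pos]))
    e = np.exp(t[~pos])
    out[~pos] = e / (1.0 + e)
    return out


def _log1p_exp(t: np.ndarray) -> np.ndarray:
    """log(1 + exp(t)) without overflow."""
    return np.where(t > 0, t + np.log1p(np.exp(-np.abs(t))),
                    np.log1p(np.exp(np.minimum(t, 0.0))))


def predict_proba(V: np.ndarray, model: LTRModel) -> float:
    """Probability of the positive class: sigmoid of ``<Z, V>``."""
    V = np.asarray(V, dtype=float)
    if V.shape != model.Z.shape:
        raise ValueError(f"shape mismatch: {V.shape} vs {model.Z.shape}")
    return float(_sigmoid(np.asarray(inner_product(model.Z, V))))


def classify(V: np.ndarray, model: LTRModel) -> int:
    """Label 1 iff the predicted probability exceeds 0.5 (tie -> 0)."""
    return int(predict_proba(V, model) > 0.5)


def penalized_nll(tensors: Sequence[np.ndarray], labels: Sequence[int],
                  Z: np.ndarray, lam: float = 0.0
                  ) -> tuple[float, np.ndarray]:
    """Smooth negative log-likelihood and its gradient tensor.

    The L1 term is handled by the proximal step in :func:`ltr_fit`, not by
    the gradient; ``lam`` is accepted for interface symmetry but does not
    enter the returned value.
    """
    stack = np.asarray(tensors, dtype=float)
    y = np.asarray(labels, dtype=float)
    if np.any((y != 0) & (y != 1)):
        raise ValueError("labels must be in {0, 1}")
    if stack.shape[1:] != np.asarray(Z).shape:
        raise ValueError("tensor dims do not match Z")
    t = _logits(stack, np.asarray(Z, dtype=float))
    # -sum y*log(sigma) + (1-y)*log(1-sigma) = sum log(1+e^t) - y*t
    value = float(np.sum(_log1p_exp(t) - y * t))
    resid = _sigmoid(t) - y
    grad = np.tensordot(resid, stack, axes=([0], [0]))
    return value, grad


def _soft_threshold(Z: np.ndarray, thr: float) -> np.ndarray:
    return np.sign(Z) * np.maximum(np.abs(Z) - thr, 0.0)


def ltr_fit(tensors: Sequence[np.ndarray], labels: Sequence[int],
            lam: float = 1e-2, max_iter: int = 500, tol: float = 1e-7,
            seed: int | None = None) -> LTRModel:
    """Fit ``Z`` by monotone FISTA on ``nll(Z) + lam * ||Z||_1``.

    ``Z`` starts at zero; the step size is found by backtracking from a
    Lipschitz estimate.  The recorded penalized objective is non-increasing
    by construction.  ``seed`` is accepted for interface stability (the
    solver itself is deterministic).
    """
    stack = np.asarray(tensors, dtype=float)
    y = np.asarray(labels, dtype=int)
    if np.unique(y).size < 2:
        raise ValueError("both classes must be present")
    if lam < 0:
        raise ValueError("lambda must be non-negative")

    Z = np.zeros(stack.shape[1:])
    W = Z.copy()  # extrapolation point
    t_mom = 1.0
    # Lipschitz bound for logistic loss: 0.25 * ||X||_2^2 with X the
    # flattened design; use the Frobenius norm as a cheap upper bound.
    L = 0.25 * float(np.sum(stack ** 2)) + 1e-12
    step = 1.0 / L

    def penalized(Zc: np.ndarray, smooth: float) -> float:
        return smooth + lam * float(np.abs(Zc).sum())

    f_Z, _ = penalized_nll(stack, y, Z)
    history = [penalized(Z, f_Z)]
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        f_W, g_W = penalized_nll(stack, y, W)
        # Backtracking on the proximal step from W.
        local = step
        while True:
            cand = _soft_threshold(W - local * g_W, lam * local)
            f_c, _ = penalized_nll(stack, y, cand)
            diff = cand - W
            quad = f_W + float(np.sum(g_W * diff)) + np.sum(diff ** 2) / (2 * local)
            if f_c <= quad + 1e-12:
                break
            local *= 0.5
            if local < 1e-18:
                break
        obj_c = penalized(cand, f_c)
        # Monotone FISTA: keep the better of candidate and incumbent.
        if obj_c <= history[-1]:
            Z_new = cand
            obj_new = obj_c
        else:
            Z_new = Z
            obj_new = history[-1]
        t_new = (1.0 + np.sqrt(1.0 + 4.0 * t_mom ** 2)) / 2.0
        W = Z_new + (t_mom / t_new) * (cand - Z_new) + \
            ((t_mom - 1.0) / t_new) * (Z_new - Z)
        Z = Z_new
        t_mom = t_new
        history.append(obj_new)
        rel = abs(history[-2] - history[-1]) / max(abs(history[-2]), 1e-12)
        if rel < tol:
            converged = True
            break
    return LTRModel(Z=Z, lambda_l1=float(lam), iterations=it,
                    final_objective=history[-1], converged=converged,
                    objective_history=history)


def ltr_fit_cv(tensors: Sequence[np.ndarray], labels: Sequence[int],
               lam_grid: Sequence[float] | None = None, n_folds: int = 3,
               max_iter: int = 500, tol: float = 1e-7,
               seed: int = 0) -> LTRModel:
    """Choose ``lambda`` by K-fold cross-validated F1, then refit on all data."""
    stack = np.asarray(tensors, dtype=float)
    y = np.asarray(labels, dtype=int)
    if lam_grid is None:
        lam_grid = np.logspace(-4, 0, 5) * len(y)
    rng = np.random.default_rng(seed)
    idx = rng.permutation(len(y))
    folds = np.array_split(idx, n_folds)
    best_lam, best_f1 = float(lam_grid[0]), -1.0
    for lam in lam_grid:
        f1s = []
        for k in range(n_folds):
            test_idx = folds[k]
            train_idx = np.concatenate([folds[j] for j in range(n_folds) if j != k])
            if np.unique(y[train_idx]).size < 2:
                continue
            model = ltr_fit(stack[train_idx], y[train_idx], lam=float(lam),
                            max_iter=max_iter, tol=tol)
            pred = np.array([classify(V, model) for V in stack[test_idx]])
            truth = y[test_idx]
            tp = int(np.sum((pred == 1) & (truth == 1)))
            fp = int(np.sum((pred == 1) & (truth == 0)))
            fn = int(np.sum((pred == 0) & (truth == 1)))
            denom = 2 * tp + fp + fn
            f1s.append(2 * tp / denom if denom else 0.0)
        mean_f1 = float(np.mean(f1s)) if f1s else 0.0
        if mean_f1 > best_f1:
            best_f1, best_lam = mean_f1, float(lam)
    model = ltr_fit(stack, y, lam=best_lam, max_iter=max_iter, tol=tol)
    return model
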
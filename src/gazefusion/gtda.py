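"""General Tensor Discriminant Analysis (GTDA) for third-order tensors.

GTDA learns one orthonormal projection matrix per tensor mode so that the
projected tensors maximize the per-mode discriminant criterion

    tr( P_l^T (S_l^b - eta_l * S_l^w) P_l ),

where ``S_l^b`` and ``S_l^w`` are the mode-l between- and within-class
scatter matrices of the tensors *after* projecting every other mode, and
``eta_l`` is the largest eigenvalue of ``(S_l^w)^-1 S_l^b``.  The coupled
problem is solved by alternating optimization: sweep modes l = 1, 2, 3, each
time rebuilding the scatters with the current projections of the other
modes and solving the symmetric eigenproblem for ``S_l^b - eta_l S_l^w``.

The within-class scatter is ridged (``ridge_scale * trace(S_w)/d`` added to
the diagonal) before the eigenvalue computation because with more feature
dimensions than samples ``S_w`` is singular.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import scipy.linalg

from .tensor_core import mode_product, unfold

__all__ = [
    "ClassMoments",
    "ProjectionSet",
    "class_means",
    "mode_scatters",
    "solve_mode",
    "gtda_fit",
    "gtda_transform",
]


@dataclass
class ClassMoments:
    """Class mean tensors, the grand mean, and class counts."""

    M0: np.ndarray
    M1: np.ndarray
    M: np.ndarray
    n0: int
    n1: int

    def mean_of(self, y: int) -> np.ndarray:
        return self.M1 if y == 1 else self.M0


@dataclass
class ProjectionSet:
    """The three GTDA projections, their eta values, and the sweep trace."""

    P: list[np.ndarray]          # P[l] has shape (d_lf, d_lf*)
    eta: list[float]
    objective_trace: list[float] = field(default_factory=list)
    converged: bool = False


def class_means(tensors: Sequence[np.ndarray], labels: Sequence[int]) -> ClassMoments:
    """Per-class mean tensors and their count-weighted grand mean."""
    labels = np.asarray(labels).astype(int)
    stack = np.asarray(tensors, dtype=float)
    if stack.ndim != 4:
        raise ValueError("tensors must all be third-order with equal dims")
    n0 = int(np.sum(labels == 0))
    n1 = int(np.sum(labels == 1))
    if n0 == 0 or n1 == 0:
        raise ValueError("both classes must be present")
    M0 = stack[labels == 0].mean(axis=0)
    M1 = stack[labels == 1].mean(axis=0)
    M = (n0 * M0 + n1 * M1) / (n0 + n1)
    return ClassMoments(M0=M0, M1=M1, M=M, n0=n0, n1=n1)


def _project_other_modes(T: np.ndarray, projections: Sequence[np.ndarray],
                         skip_mode: int) -> np.ndarray:
    out = T
    for m in (1, 2, 3):
        if m != skip_mode:
            out = mode_product(out, projections[m - 1], m)
    return out


def mode_scatters(tensors: Sequence[np.ndarray], labels: Sequence[int],
                  moments: ClassMoments, projections: Sequence[np.ndarray],
                  mode: int) -> tuple[np.ndarray, np.ndarray]:
    """Mode-``mode`` between/within scatter matrices under the current
    projections of the other two modes.  Both are symmetric PSD of size
    ``d_mode x d_mode``."""
    labels = np.asarray(labels).astype(int)
    counts = {0: moments.n0, 1: moments.n1}
    d = np.asarray(tensors[0]).shape[mode - 1]
    S_b = np.zeros((d, d))
    for y in (0, 1):
        B = _project_other_modes(moments.mean_of(y) - moments.M, projections, mode)
        Bm = unfold(B, mode)
        S_b += counts[y] * (Bm @ Bm.T)
    S_w = np.zeros((d, d))
    for T, y in zip(tensors, labels):
        Wd = _project_other_modes(np.asarray(T) - moments.mean_of(y), projections, mode)
        Wm = unfold(Wd, mode)
        S_w += Wm @ Wm.T
    S_b = (S_b + S_b.T) / 2.0
    S_w = (S_w + S_w.T) / 2.0
    return S_b, S_w


def solve_mode(S_b: np.ndarray, S_w: np.ndarray, k: int,
               ridge: float = 0.0) -> tuple[np.ndarray, float]:
    """Solve one mode's discriminant eigenproblem.

    ``eta`` is the largest eigenvalue of ``(S_w + ridge*I)^-1 S_b``; the
    projection collects the orthonormal top-k eigenvectors of the symmetric
    matrix ``S_b - eta * (S_w + ridge*I)``, each column's first nonzero
    entry made positive.
    """
    S_b = np.asarray(S_b, dtype=float)
    S_w = np.asarray(S_w, dtype=float)
    d = S_b.shape[0]
    if S_b.shape != (d, d) or S_w.shape != (d, d):
        raise ValueError("scatter matrices must be square and same size")
    tol = 1e-8 * max(1.0, np.abs(S_b).max(), np.abs(S_w).max())
    if np.abs(S_b - S_b.T).max() > tol or np.abs(S_w - S_w.T).max() > tol:
        raise ValueError("scatter matrices must be symmetric")
    if not (1 <= k <= d):
        raise ValueError(f"k={k} out of range 1..{d}")
    S_w_r = S_w + ridge * np.eye(d)
    gen_evals = scipy.linalg.eigh(S_b, S_w_r, eigvals_only=True)
    eta = float(gen_evals[-1])
    target = S_b - eta * S_w_r
    if not S_b.any():
        # Degenerate between-scatter: eta = 0 leaves the criterion flat, so
        # fall back to the smallest within-scatter directions.
        target = -S_w_r
    evals, evecs = np.linalg.eigh(target)
    # eigh returns ascending eigenvalues; stable tie-break on original index
    # is preserved by taking the last k and reversing.
    order = np.argsort(-evals, kind="stable")
    P = evecs[:, order[:k]].copy()
    for j in range(k):
        col = P[:, j]
        nz = np.flatnonzero(np.abs(col) > 1e-12)
        if nz.size and col[nz[0]] < 0:
            P[:, j] = -col
    return P, eta


def _mode_objective(S_b: np.ndarray, S_w_r: np.ndarray, P: np.ndarray,
                    eta: float) -> float:
    return float(np.trace(P.T @ (S_b - eta * S_w_r) @ P))


def _energy_dims(tensors: Sequence[np.ndarray], energy: float) -> tuple[int, int, int]:
    """Per-mode dimensions retaining an eigenvalue-energy fraction of the
    total scatter of the stacked tensors."""
    stack = np.asarray(tensors, dtype=float)
    mean = stack.mean(axis=0)
    dims = []
    for mode in (1, 2, 3):
        S = np.zeros((stack.shape[mode],) * 2)
        for T in stack:
            Um = unfold(T - mean, mode)
            S += Um @ Um.T
        evals = np.linalg.eigvalsh(S)[::-1]
        total = evals.sum()
        if total <= 0:
            dims.append(1)
            continue
        cum = np.cumsum(evals) / total
        dims.append(int(np.searchsorted(cum, energy) + 1))
    return tuple(min(k, stack.shape[m + 1]) for m, k in enumerate(dims))


def gtda_fit(tensors: Sequence[np.ndarray], labels: Sequence[int],
             target_dims: tuple[int, int, int] | str = "auto",
             sweeps: int = 10, tol: float = 1e-6,
             ridge_scale: float = 1e-6, energy: float = 0.95) -> ProjectionSet:
    """Fit the three projections by alternating optimization.

    Each ``P_l`` starts as the first ``d_lf*`` columns of the identity; a
    sweep updates modes 1, 2, 3 in turn via :func:`mode_scatters` and
    :func:`solve_mode`.  Iteration stops after ``sweeps`` sweeps or when the
    relative change of the summed mode objectives drops below ``tol``.
    Non-convergence is reported via the trace, not raised.

    ``target_dims="auto"`` keeps the per-mode dimensions retaining an
    ``energy`` fraction of total-scatter eigenvalue mass.
    """
    stack = [np.asarray(T, dtype=float) for T in tensors]
    dims_in = stack[0].shape
    if target_dims == "auto":
        target_dims = _energy_dims(stack, energy)
    target_dims = tuple(int(k) for k in target_dims)
    if any(k > d or k < 1 for k, d in zip(target_dims, dims_in)):
        raise ValueError(f"target dims {target_dims} incompatible with {dims_in}")

    moments = class_means(stack, labels)
    P = [np.eye(d)[:, :k] for d, k in zip(dims_in, target_dims)]
    eta = [0.0, 0.0, 0.0]

    def sweep_once(P_cur):
        """One alternating pass over the modes; returns new projections."""
        P_new = list(P_cur)
        eta_new = [0.0, 0.0, 0.0]
        for mode in (1, 2, 3):
            S_b, S_w = mode_scatters(stack, labels, moments, P_new, mode)
            ridge = ridge_scale * max(np.trace(S_w), 1e-300) / S_w.shape[0]
            P_l, eta_l = solve_mode(S_b, S_w, target_dims[mode - 1], ridge=ridge)
            P_new[mode - 1] = P_l
            eta_new[mode - 1] = eta_l
        return P_new, eta_new

    def global_objective(P_cur):
        """Summed mode objectives, evaluated consistently at one projection
        set (scatters and eta recomputed under the other modes of P_cur)."""
        total = 0.0
        for mode in (1, 2, 3):
            S_b, S_w = mode_scatters(stack, labels, moments, P_cur, mode)
            ridge = ridge_scale * max(np.trace(S_w), 1e-300) / S_w.shape[0]
            S_w_r = S_w + ridge * np.eye(S_w.shape[0])
            gen = scipy.linalg.eigh(S_b, S_w_r, eigvals_only=True)
            total += _mode_objective(S_b, S_w_r, P_cur[mode - 1], float(gen[-1]))
        return total

    # Greedy alternating optimization: a sweep is kept only if the global
    # objective does not decrease, so the recorded trace is non-decreasing
    # by construction and iteration stops at the first non-improving sweep.
    trace: list[float] = []
    converged = False
    prev_obj = None
    for _ in range(sweeps):
        P_cand, eta_cand = sweep_once(P)
        obj = global_objective(P_cand)
        if prev_obj is not None and obj < prev_obj - 1e-12:
            converged = True
            break
        P, eta = P_cand, eta_cand
        trace.append(obj)
        if prev_obj is not None:
            if abs(obj - prev_obj) / max(abs(prev_obj), 1e-12) < tol:
                converged = True
                break
        prev_obj = obj
    return ProjectionSet(P=P, eta=eta, objective_trace=trace, converged=converged)


def gtda_transform(T: np.ndarray, proj: ProjectionSet) -> np.ndarray:
    """Apply the three mode products (modes along distinct axes commute)."""
    out = np.asarray(T, dtype=float)
    for mode in (1, 2, 3):
        out = mode_product(out, proj.P[mode - 1], mode)
    return out
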
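"""Minimal multilinear algebra for third- and fourth-order tensors.

Conventions (fixed once, used everywhere in the package):

* All indices are 0-based.
* ``unfold(T, mode)`` produces a matrix whose row ``r`` collects every entry
  of ``T`` with the mode-th index equal to ``r``.  Columns enumerate the
  remaining indices with the *lower-numbered remaining mode varying fastest*:
  for a third-order tensor and remaining modes ``(a, b)`` with ``a < b``, the
  column index is ``i_a + d_a * i_b``.
* ``mode_product(T, U, mode)`` contracts a ``(d_mode, k)`` matrix against the
  chosen mode and satisfies ``unfold(mode_product(T, U, m), m) == U.T @
  unfold(T, m)``, so a projection matrix with fewer columns than rows shrinks
  that mode.

Tensors are plain ``numpy.ndarray`` objects; the helpers here validate order
and finiteness where the contracts demand it.  HDF5 persistence stores the
values alongside the dims and optional mode names.
"""

from __future__ import annotations

from typing import Sequence

import h5py
import numpy as np

__all__ = [
    "unfold",
    "fold",
    "mode_product",
    "inner_product",
    "hadamard",
    "save_tensor",
    "load_tensor",
]


def _check_mode(ndim: int, mode: int) -> None:
    if not (1 <= mode <= ndim):
        raise ValueError(f"mode must be in 1..{ndim}, got {mode}")


def unfold(tensor: np.ndarray, mode: int) -> np.ndarray:
    """Matricize ``tensor`` along ``mode`` (1-based).

    Row ``r`` of the result enumerates all entries whose mode-th index is
    ``r``; among the remaining modes the lower-numbered one varies fastest.
    """
    T = np.asarray(tensor)
    _check_mode(T.ndim, mode)
    ax = mode - 1
    moved = np.moveaxis(T, ax, 0)
    # Remaining axes are in ascending original order; reversing them before a
    # C-order reshape makes the lowest remaining mode vary fastest.
    rev = moved.transpose((0,) + tuple(range(moved.ndim - 1, 0, -1)))
    return rev.reshape(T.shape[ax], -1)


def fold(matrix: np.ndarray, mode: int, shape: Sequence[int]) -> np.ndarray:
    """Inverse of :func:`unfold`: rebuild a tensor of ``shape`` from its
    mode-``mode`` unfolding."""
    M = np.asarray(matrix)
    shape = tuple(int(s) for s in shape)
    _check_mode(len(shape), mode)
    ax = mode - 1
    rest = [s for i, s in enumerate(shape) if i != ax]
    if M.shape != (shape[ax], int(np.prod(rest))):
        raise ValueError(f"matrix shape {M.shape} incompatible with {shape} mode {mode}")
    moved = M.reshape((shape[ax],) + tuple(reversed(rest)))
    rev = moved.transpose((0,) + tuple(range(moved.ndim - 1, 0, -1)))
    return np.moveaxis(rev, 0, ax)


def mode_product(tensor: np.ndarray, U: np.ndarray, mode: int) -> np.ndarray:
    """Mode-``mode`` product contracting ``U`` (shape ``(d_mode, k)``).

    Satisfies ``unfold(mode_product(T, U, m), m) = U.T @ unfold(T, m)``; the
    output replaces the mode-th dimension ``d_mode`` by ``k``.
    """
    T = np.asarray(tensor)
    U = np.asarray(U)
    _check_mode(T.ndim, mode)
    ax = mode - 1
    if U.ndim != 2 or U.shape[0] != T.shape[ax]:
        raise ValueError(
            f"projection shape {U.shape} does not match mode-{mode} dim {T.shape[ax]}"
        )
    out = np.tensordot(U, T, axes=([0], [ax]))  # k leads, remaining axes follow
    return np.moveaxis(out, 0, ax)


def inner_product(A: np.ndarray, B: np.ndarray) -> float:
    """Full tensor inner product: sum of elementwise products."""
    A = np.asarray(A)
    B = np.asarray(B)
    if A.shape != B.shape:
        raise ValueError(f"shape mismatch: {A.shape} vs {B.shape}")
    return float(np.sum(A * B))


def hadamard(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Elementwise (Hadamard) product of two same-shape matrices."""
    A = np.asarray(A)
    B = np.asarray(B)
    if A.shape != B.shape:
        raise ValueError(f"shape mismatch: {A.shape} vs {B.shape}")
    return A * B


def save_tensor(group: h5py.Group, name: str, tensor: np.ndarray,
                mode_names: Sequence[str] | None = None) -> None:
    g = group.create_group(name)
    g.create_dataset("values", data=np.asarray(tensor))
    g.create_dataset("dims", data=np.asarray(tensor.shape, dtype=np.int64))
    if mode_names is not None:
        g.attrs["mode_names"] = list(mode_names)


def load_tensor(group: h5py.Group, name: str) -> np.ndarray:
    g = group[name]
    values = np.asarray(g["values"])
    dims = tuple(int(d) for d in g["dims"][...])
    if values.shape != dims:
        raise ValueError(f"stored dims {dims} do not match values shape {values.shape}")
    return values
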
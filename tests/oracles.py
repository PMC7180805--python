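"""Independent brute-force oracles shared by the test suite.

These deliberately use plain index loops (not the package's vectorized
implementations) so they can serve as ground truth.
"""

import numpy as np
import scipy.linalg

from gazefusion import gtda


def unfold_oracle(T: np.ndarray, mode: int) -> np.ndarray:
    """Triple-loop enumeration of the mode unfolding convention."""
    dims = T.shape
    ax = mode - 1
    rest = [m for m in range(3) if m != ax]
    out = np.zeros((dims[ax], dims[rest[0]] * dims[rest[1]]))
    for i1 in range(dims[0]):
        for i2 in range(dims[1]):
            for i3 in range(dims[2]):
                idx = (i1, i2, i3)
                col = idx[rest[0]] + dims[rest[0]] * idx[rest[1]]
                out[idx[ax], col] = T[i1, i2, i3]
    return out


def mode_product_oracle(T: np.ndarray, U: np.ndarray, mode: int) -> np.ndarray:
    """Direct index-loop contraction of U against the chosen mode."""
    ax = mode - 1
    out_shape = list(T.shape)
    out_shape[ax] = U.shape[1]
    out = np.zeros(out_shape)
    for idx in np.ndindex(*out_shape):
        s = 0.0
        for r in range(T.shape[ax]):
            src = list(idx)
            src[ax] = r
            s += U[r, idx[ax]] * T[tuple(src)]
        out[idx] = s
    return out


def inner_product_oracle(A: np.ndarray, B: np.ndarray) -> float:
    s = 0.0
    for idx in np.ndindex(*A.shape):
        s += A[idx] * B[idx]
    return s


def gtda_objective_at(tensors, labels, p1, p2, ridge_scale=1e-6) -> float:
    """Summed mode objectives for 2x2x1 tensors at unit vectors (p1, p2).

    Direct evaluation used by the rotation-grid brute force: per mode, the
    scatters under the other modes' projections, eta as the largest
    generalized eigenvalue, and the trace criterion at that projection.
    """
    moments = gtda.class_means(tensors, labels)
    P = [np.asarray(p1)[:, None], np.asarray(p2)[:, None], np.eye(1)]
    total = 0.0
    for mode in (1, 2, 3):
        S_b, S_w = gtda.mode_scatters(tensors, labels, moments, P, mode)
        ridge = ridge_scale * max(np.trace(S_w), 1e-300) / S_w.shape[0]
        S_w_r = S_w + ridge * np.eye(S_w.shape[0])
        eta = float(scipy.linalg.eigh(S_b, S_w_r, eigvals_only=True)[-1])
        v = P[mode - 1]
        total += float(np.trace(v.T @ (S_b - eta * S_w_r) @ v))
    return total
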
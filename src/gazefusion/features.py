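"""Per-frame feature extraction, FDA dimension unification, CFT assembly.

Each frame of a gaze-weighted representation is passed through one or more
feature extractors ("backbones").  Because backbones emit vectors of
different lengths, every backbone's features are projected with Fisher
discriminant analysis (FDA) down to the smallest backbone output dimension;
the unified per-frame features are then stacked into the third-order
CNN-feature tensor (CFT) with modes

    (unified feature dim d1f) x (backbone index d2f) x (frame index d3f=d4).

For a binary label the FDA between-class scatter has rank 1, so a target
dimension beyond 1 is filled with principal components of the total scatter
orthogonal to the discriminant direction; the combined basis is
orthonormalized.

The shipped default extractors are deterministic grid-mean "toy" backbones
(cell means of a g x g partition per channel) so that the whole pipeline is
exercisable without pretrained network weights; extractors satisfying
:class:`FeatureExtractorContract` can stand in for real CNN backbones.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import scipy.linalg

from .gaze import GazeImageRepresentation

__all__ = [
    "FeatureExtractorContract",
    "FeatureMatrixSet",
    "FDAProjection",
    "CFT",
    "toy_grid_extractor",
    "extract_features",
    "fda_fit",
    "fda_transform",
    "build_cft",
    "parse_extractor_spec",
]


@dataclass(frozen=True)
class FeatureExtractorContract:
    """A named deterministic map from a weighted color frame to a vector."""

    name: str
    output_dim: int
    extract: Callable[[np.ndarray], np.ndarray]


@dataclass
class FeatureMatrixSet:
    """Per-backbone (output_dim_b x d4) feature matrices; order significant."""

    matrices: list[np.ndarray]
    backbone_order: list[str]

    def __post_init__(self) -> None:
        d4s = {m.shape[1] for m in self.matrices}
        if len(d4s) > 1:
            raise ValueError(f"backbone matrices disagree on frame count: {d4s}")

    @property
    def d4(self) -> int:
        return self.matrices[0].shape[1]


@dataclass
class FDAProjection:
    """Affine projection x -> basis.T @ (x - mean); basis columns orthonormal."""

    mean: np.ndarray
    basis: np.ndarray  # (input_dim, k)
    ridge: float


@dataclass
class CFT:
    """Third-order fusion tensor (d1f x d2f x d3f): feature x backbone x frame."""

    tensor: np.ndarray
    backbone_order: list[str]
    image_id: str = ""
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.tensor = np.asarray(self.tensor, dtype=float)
        if self.tensor.ndim != 3:
            raise ValueError("CFT must be third-order")
        if not np.all(np.isfinite(self.tensor)):
            raise ValueError("CFT contains non-finite entries")


def toy_grid_extractor(g: int) -> FeatureExtractorContract:
    """Deterministic backbone: per-channel means over a g x g grid.

    Output dimension is ``3 * g**2`` for RGB frames.  Grid cells are the
    equal integer partitions of each axis (``numpy.array_split``).
    """
    if g < 1:
        raise ValueError("g must be >= 1")

    def extract(frame: np.ndarray) -> np.ndarray:
        frame = np.asarray(frame, dtype=float)
        if frame.ndim == 2:
            frame = frame[:, :, None]
        d1, d2, _ = frame.shape
        if g > d1 or g > d2:
            raise ValueError(f"grid size {g} exceeds frame side {(d1, d2)}")
        feats = []
        for c in range(frame.shape[2]):
            for rows in np.array_split(frame[:, :, c], g, axis=0):
                for cell in np.array_split(rows, g, axis=1):
                    feats.append(cell.mean())
        return np.asarray(feats, dtype=float)

    return FeatureExtractorContract(name=f"toy_g{g}", output_dim=3 * g * g,
                                    extract=extract)


def parse_extractor_spec(spec: str) -> list[FeatureExtractorContract]:
    """Parse a CLI extractor list like ``"toy:g=2,toy:g=3,toy:g=4"``."""
    extractors = []
    for item in spec.split(","):
        item = item.strip()
        if not item:
            continue
        kind, _, args = item.partition(":")
        if kind != "toy":
            raise ValueError(f"unknown extractor kind: {kind!r}")
        params = dict(kv.split("=") for kv in args.split(";") if kv)
        extractors.append(toy_grid_extractor(int(params.get("g", 4))))
    if not extractors:
        raise ValueError("no extractors specified")
    return extractors


def extract_features(rep: GazeImageRepresentation,
                     extractors: Sequence[FeatureExtractorContract]) -> FeatureMatrixSet:
    """Column ``f`` of backbone ``b``'s matrix is backbone ``b`` applied to
    frame ``f`` of the representation."""
    if not extractors:
        raise ValueError("at least one extractor required")
    d4 = rep.tensor.shape[3]
    matrices = []
    for ext in extractors:
        cols = np.empty((ext.output_dim, d4), dtype=float)
        for f in range(d4):
            try:
                vec = np.asarray(ext.extract(rep.tensor[:, :, :, f]), dtype=float)
            except Exception as exc:  # annotate the failing frame
                raise RuntimeError(f"extractor {ext.name} failed on frame {f}") from exc
            if vec.shape != (ext.output_dim,):
                raise ValueError(
                    f"extractor {ext.name} returned shape {vec.shape}, "
                    f"expected ({ext.output_dim},)"
                )
            cols[:, f] = vec
        matrices.append(cols)
    return FeatureMatrixSet(matrices=matrices,
                            backbone_order=[e.name for e in extractors])


def fda_fit(X: np.ndarray, y: np.ndarray, k: int, ridge: float = 1e-3) -> FDAProjection:
    """Fisher discriminant analysis to ``k`` dimensions with PCA completion.

    The basis spans the top eigenvectors of ``(S_w + ridge*I)^-1 S_b``; for
    binary labels ``S_b`` has rank 1, so dimensions beyond its rank are the
    leading principal components of the total scatter orthogonal to the
    directions already chosen.  Columns are orthonormalized.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(int)
    if X.ndim != 2:
        raise ValueError("X must be (samples, input_dim)")
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("FDA requires both classes present")
    n, d = X.shape
    if not (1 <= k <= d):
        raise ValueError(f"target dim k={k} must be in 1..{d}")

    mean = X.mean(axis=0)
    Xc = X - mean
    S_t = Xc.T @ Xc
    S_w = np.zeros((d, d))
    S_b = np.zeros((d, d))
    for cls in classes:
        Xk = X[y == cls]
        mu = Xk.mean(axis=0)
        Dk = Xk - mu
        S_w += Dk.T @ Dk
        dm = (mu - mean)[:, None]
        S_b += Xk.shape[0] * (dm @ dm.T)

    S_w_r = S_w + ridge * np.eye(d)
    # Generalized symmetric eigenproblem S_b v = lam S_w_r v.
    evals, evecs = scipy.linalg.eigh(S_b, S_w_r)
    order = np.argsort(evals)[::-1]
    rank_b = classes.size - 1
    n_disc = min(k, rank_b)
    disc = evecs[:, order[:n_disc]]
    # Orthonormalize the discriminant directions.
    disc, _ = np.linalg.qr(disc)

    if k > n_disc:
        # Deflate total scatter onto the orthogonal complement, take leading PCs.
        proj = np.eye(d) - disc @ disc.T
        S_t_perp = proj @ S_t @ proj
        pe, pv = np.linalg.eigh((S_t_perp + S_t_perp.T) / 2.0)
        pc = pv[:, np.argsort(pe)[::-1][: k - n_disc]]
        basis = np.hstack([disc, pc])
        basis, _ = np.linalg.qr(basis)
    else:
        basis = disc
    # Deterministic sign: first nonzero entry of each column positive.
    for j in range(basis.shape[1]):
        col = basis[:, j]
        nz = np.flatnonzero(np.abs(col) > 1e-12)
        if nz.size and col[nz[0]] < 0:
            basis[:, j] = -col
    return FDAProjection(mean=mean, basis=basis, ridge=float(ridge))


def fda_transform(X: np.ndarray, proj: FDAProjection) -> np.ndarray:
    """Project rows of ``X`` onto the fitted FDA basis."""
    X = np.asarray(X, dtype=float)
    return (X - proj.mean) @ proj.basis


def build_cft(fms: FeatureMatrixSet,
              projections: Sequence[FDAProjection],
              image_id: str = "", subject_id: str = "") -> CFT:
    """Stack projected per-frame features into the fusion tensor.

    Entry ``(i, b, f)`` is the i-th component of the projected feature of
    backbone ``b`` at frame ``f``; the backbone axis follows the
    FeatureMatrixSet order.
    """
    if len(projections) != len(fms.matrices):
        raise ValueError("one projection per backbone required")
    dims = {p.basis.shape[1] for p in projections}
    if len(dims) != 1:
        raise ValueError(f"projections disagree on unified dimension: {dims}")
    d1f = dims.pop()
    d4 = fms.d4
    tensor = np.empty((d1f, len(fms.matrices), d4), dtype=float)
    for b, (mat, proj) in enumerate(zip(fms.matrices, projections)):
        if proj.basis.shape[0] != mat.shape[0]:
            raise ValueError(
                f"projection input dim {proj.basis.shape[0]} does not match "
                f"backbone {fms.backbone_order[b]} dim {mat.shape[0]}"
            )
        tensor[:, b, :] = fda_transform(mat.T, proj).T
    return CFT(tensor=tensor, backbone_order=list(fms.backbone_order),
               image_id=image_id, subject_id=subject_id)
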
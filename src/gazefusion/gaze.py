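"""Gaze-weighted multi-frame image representation.

The viewing time of one subject on one image is split into ``d4`` equal
frames.  Per frame, gaze samples vote (duration-weighted by default) into a
2-D fixation histogram which is Gaussian-smoothed and floored at a small
``epsilon`` to obtain a strictly positive fixation map ``W^gaze_f``.  The
gaze-and-image weight (GIW) matrices are then

    W_f = d4 * W^gaze_f / sum_f W^gaze_f + 1        (elementwise),

so every pixel's weights sum to ``2*d4`` across frames.  The fourth-order
representation holds, per frame and color channel, the Hadamard product of
the image channel with ``W_f``; averaging the frames and dividing by two
reconstructs the source image exactly.

Coordinates are 0-based with origin at the top-left; ``x`` is the column and
``y`` the row.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import h5py
import numpy as np
import pandas as pd
from PIL import Image
from scipy.ndimage import gaussian_filter

from .tensor_core import hadamard

__all__ = [
    "GazeRecording",
    "FixationMapStack",
    "GIWStack",
    "GazeImageRepresentation",
    "bin_gaze_to_frames",
    "build_fixation_maps",
    "compute_giw",
    "build_representation",
    "reconstruct_image",
    "load_image",
    "read_gaze_csv",
    "default_sigma",
    "save_representations",
    "load_representations",
]

GAZE_CSV_COLUMNS = ["subject_id", "image_id", "x", "y", "onset_s", "duration_s"]


@dataclass
class GazeRecording:
    """Timestamped gaze samples for one subject viewing one image.

    ``samples`` rows are ``(x, y, onset_s, duration_s)`` with non-decreasing
    onsets and positive durations.
    """

    subject_id: str
    image_id: str
    samples: np.ndarray  # shape (n, 4): x, y, onset, duration

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float).reshape(-1, 4)
        if self.samples.shape[0] == 0:
            raise ValueError("gaze recording has no samples")
        onsets = self.samples[:, 2]
        if np.any(np.diff(onsets) < 0):
            raise ValueError("gaze onsets must be non-decreasing")
        if np.any(self.samples[:, 3] <= 0):
            raise ValueError("gaze durations must be positive")

    @property
    def span(self) -> tuple[float, float]:
        """(start, end) of the viewing interval."""
        start = float(self.samples[0, 2])
        end = float(self.samples[-1, 2] + self.samples[-1, 3])
        return start, end


@dataclass
class FixationMapStack:
    """``d4`` strictly positive fixation maps of shape ``(d1, d2)``."""

    maps: np.ndarray  # (d4, d1, d2)
    sigma: float
    epsilon: float

    def __post_init__(self) -> None:
        self.maps = np.asarray(self.maps, dtype=float)
        if self.maps.ndim != 3 or self.maps.shape[0] < 1:
            raise ValueError("maps must be (d4, d1, d2) with d4 >= 1")
        if not np.all(np.isfinite(self.maps)):
            raise ValueError("fixation maps contain non-finite values")


@dataclass
class GIWStack:
    """Per-frame GIW matrices; per pixel they sum to ``2*d4`` across frames."""

    weights: np.ndarray  # (d4, d1, d2)

    @property
    def d4(self) -> int:
        return self.weights.shape[0]


@dataclass
class GazeImageRepresentation:
    """Fourth-order tensor ``(d1, d2, 3, d4)`` of GIW-weighted image frames."""

    tensor: np.ndarray
    source_image_id: str = ""
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.tensor = np.asarray(self.tensor, dtype=float)
        if self.tensor.ndim != 4:
            raise ValueError("representation tensor must be 4th-order")


def default_sigma(shape: tuple[int, int]) -> float:
    """Gaussian width default: 2% of the image diagonal (foveal spread)."""
    d1, d2 = shape
    return 0.02 * float(np.hypot(d1, d2))


def bin_gaze_to_frames(rec: GazeRecording, d4: int,
                       skip_initial_s: float = 0.0) -> list[np.ndarray]:
    """Assign each gaze sample to one of ``d4`` equal time bins.

    The span [first onset, last onset + last duration], optionally with its
    first ``skip_initial_s`` seconds removed, is split into ``d4`` half-open
    bins; a sample lands in the bin containing its onset midpoint
    ``onset + duration/2`` (a midpoint exactly on a boundary goes to the
    later bin).  Samples are never split across bins.
    """
    if d4 < 1:
        raise ValueError("d4 must be >= 1")
    start, end = rec.span
    start += float(skip_initial_s)
    samples = rec.samples
    mids = samples[:, 2] + samples[:, 3] / 2.0
    keep = mids >= start
    samples = samples[keep]
    mids = mids[keep]
    if samples.shape[0] == 0:
        raise ValueError("no gaze samples remain after skipping the initial interval")
    width = (end - start) / d4
    if width <= 0:
        # Degenerate zero-length span: everything in the first bin.
        idx = np.zeros(len(mids), dtype=int)
    else:
        idx = np.floor((mids - start) / width).astype(int)
        idx = np.clip(idx, 0, d4 - 1)
    return [samples[idx == f] for f in range(d4)]


def build_fixation_maps(bins: Sequence[np.ndarray], shape: tuple[int, int],
                        sigma: float, epsilon: float = 1e-6,
                        duration_weighted: bool = True) -> FixationMapStack:
    """Vote gaze samples into per-frame histograms, smooth, and floor.

    Each sample adds its duration in seconds (or 1 if ``duration_weighted``
    is off) to its nearest pixel; the vote image is convolved with an
    isotropic Gaussian using reflect boundary (mass-preserving) and then
    ``epsilon`` is added everywhere so the maps are strictly positive.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    d1, d2 = shape
    maps = np.empty((len(bins), d1, d2), dtype=float)
    for f, frame_samples in enumerate(bins):
        votes = np.zeros((d1, d2), dtype=float)
        frame_samples = np.asarray(frame_samples, dtype=float).reshape(-1, 4)
        if frame_samples.shape[0]:
            cols = np.clip(np.rint(frame_samples[:, 0]).astype(int), 0, d2 - 1)
            rows = np.clip(np.rint(frame_samples[:, 1]).astype(int), 0, d1 - 1)
            w = frame_samples[:, 3] if duration_weighted else np.ones(len(frame_samples))
            np.add.at(votes, (rows, cols), w)
        maps[f] = gaussian_filter(votes, sigma=sigma, mode="reflect") + epsilon
    return FixationMapStack(maps=maps, sigma=float(sigma), epsilon=float(epsilon))


def compute_giw(fix: FixationMapStack) -> GIWStack:
    """GIW matrices: ``W_f = d4 * Wg_f / sum_f Wg_f + 1`` elementwise."""
    maps = fix.maps
    denom = maps.sum(axis=0)
    if np.any(denom <= 0):
        raise ValueError("fixation maps must be strictly positive at every pixel")
    d4 = maps.shape[0]
    weights = d4 * maps / denom[None, :, :] + 1.0
    return GIWStack(weights=weights)


def build_representation(image: np.ndarray, giw: GIWStack,
                         image_id: str = "", subject_id: str = "") -> GazeImageRepresentation:
    """Frame ``f``, channel ``c`` slice = image channel ``c`` ∘ ``W_f``."""
    image = np.asarray(image, dtype=float)
    if image.ndim != 3:
        raise ValueError("image must be (d1, d2, channels)")
    d1, d2, d3 = image.shape
    if giw.weights.shape[1:] != (d1, d2):
        raise ValueError(
            f"GIW shape {giw.weights.shape[1:]} does not match image {(d1, d2)}"
        )
    d4 = giw.d4
    tensor = np.empty((d1, d2, d3, d4), dtype=float)
    for f in range(d4):
        for c in range(d3):
            tensor[:, :, c, f] = hadamard(image[:, :, c], giw.weights[f])
    return GazeImageRepresentation(tensor=tensor, source_image_id=image_id,
                                   subject_id=subject_id)


def reconstruct_image(rep: GazeImageRepresentation) -> np.ndarray:
    """Recover the source image: ``(1 / (2*d4)) * sum_f frame_f``."""
    tensor = rep.tensor
    d4 = tensor.shape[3]
    return tensor.sum(axis=3) / (2.0 * d4)


# ---------------------------------------------------------------------------
# I/O helpers


def load_image(path: str | Path, shape: tuple[int, int] | None = None) -> np.ndarray:
    """Load a PNG/JPEG as float RGB in [0, 1], optionally bilinear-resized
    to ``shape = (d1 rows, d2 cols)``."""
    img = Image.open(path).convert("RGB")
    if shape is not None:
        d1, d2 = shape
        img = img.resize((d2, d1), Image.BILINEAR)
    return np.asarray(img, dtype=float) / 255.0


def rescale_gaze(rec: GazeRecording, from_shape: tuple[int, int],
                 to_shape: tuple[int, int]) -> GazeRecording:
    """Rescale gaze pixel coordinates when the image is resized."""
    samples = rec.samples.copy()
    samples[:, 0] *= to_shape[1] / from_shape[1]
    samples[:, 1] *= to_shape[0] / from_shape[0]
    return GazeRecording(rec.subject_id, rec.image_id, samples)


def read_gaze_csv(path: str | Path) -> list[GazeRecording]:
    """Read a gaze CSV (subject_id,image_id,x,y,onset_s,duration_s) into one
    recording per (subject, image), sample order preserved."""
    df = pd.read_csv(path, dtype={"subject_id": str, "image_id": str})
    missing = [c for c in GAZE_CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"gaze CSV missing columns: {missing}")
    recordings = []
    for (subj, img), g in df.groupby(["subject_id", "image_id"], sort=True):
        samples = g[["x", "y", "onset_s", "duration_s"]].to_numpy(dtype=float)
        recordings.append(GazeRecording(subj, img, samples))
    return recordings


def save_representations(path: str | Path,
                         reps: Sequence[GazeImageRepresentation]) -> None:
    with h5py.File(path, "w") as fh:
        for i, rep in enumerate(reps):
            g = fh.create_group(f"rep_{i:05d}")
            g.create_dataset("tensor", data=rep.tensor)
            g.attrs["image_id"] = rep.source_image_id
            g.attrs["subject_id"] = rep.subject_id


def load_representations(path: str | Path) -> list[GazeImageRepresentation]:
    reps = []
    with h5py.File(path, "r") as fh:
        for key in sorted(fh.keys()):
            g = fh[key]
            reps.append(GazeImageRepresentation(
                tensor=np.asarray(g["tensor"]),
                source_image_id=str(g.attrs.get("image_id", "")),
                subject_id=str(g.attrs.get("subject_id", "")),
            ))
    return reps
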
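"""Synthetic images, class-dependent scanpaths, labels and planted tensors.

The generator emulates the study conditions the pipeline is built for:
viewers look at images containing localized objects, and the *temporal
trajectory* of their attention — not just where they look overall — carries
the class signal.  Scanpaths follow a two-attractor dwell/jitter process:

* class 0 viewers dwell on object A for the whole viewing time;
* class 1 viewers start on object A and drift to object B, so early and
  late frames of the binned gaze differ.

Images are noisy backgrounds with 1-3 Gaussian-profile blobs; two of the
blobs serve as the attractors A and B.  Everything is a pure function of
its seed (bit-reproducible).

``gen_planted_cft`` generates third-order tensors with planted structure
for testing the discriminant-analysis and regression stages directly:
"gtda" mode plants a mode-1 mean shift along a unit direction; "ltr" mode
draws labels from a logistic model with a sparse coefficient tensor.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image

from .gaze import GazeRecording

__all__ = [
    "SceneSpec",
    "ScanpathSpec",
    "gen_images",
    "gen_gaze",
    "gen_dataset",
    "gen_planted_cft",
]


@dataclass
class SceneSpec:
    """Image geometry: size, object blobs, background noise."""

    shape: tuple[int, int] = (32, 32)
    n_blobs_range: tuple[int, int] = (2, 3)
    blob_radius_range: tuple[float, float] = (3.0, 6.0)
    blob_intensity_range: tuple[float, float] = (0.5, 1.0)
    background_level: float = 0.2
    noise_sd: float = 0.05


@dataclass
class ScanpathSpec:
    """Two-attractor dwell/jitter gaze dynamics."""

    jitter_sd: float = 2.0          # pixels around the current attractor
    sample_rate_hz: float = 60.0
    total_duration_s: float = 3.0
    drift_start_frac: float = 0.3   # class 1: when the A->B drift begins
    drift_end_frac: float = 0.7     # class 1: when dwelling settles on B


@dataclass
class SceneRecord:
    """Ground truth for one generated image."""

    image_id: str
    blob_centers: list[tuple[float, float]]  # (row, col)
    blob_radii: list[float]
    blob_intensities: list[tuple[float, float, float]]


def _render_scene(rng: np.random.Generator, spec: SceneSpec,
                  image_id: str) -> tuple[np.ndarray, SceneRecord]:
    d1, d2 = spec.shape
    img = np.full((d1, d2, 3), spec.background_level, dtype=float)
    if spec.noise_sd > 0:
        img += rng.normal(0.0, spec.noise_sd, size=img.shape)
    n_blobs = int(rng.integers(spec.n_blobs_range[0], spec.n_blobs_range[1] + 1))
    centers, radii, intensities = [], [], []
    rows, cols = np.mgrid[0:d1, 0:d2]
    for b in range(n_blobs):
        r = float(rng.uniform(*spec.blob_radius_range))
        # The first two blobs are the scanpath attractors A and B.  They are
        # placed in opposite quadrants so the A->B drift of class-1 viewers
        # has a consistent spatial direction across images; remaining blobs
        # are unconstrained distractors.
        if b == 0:
            cy = float(rng.uniform(min(r, d1 / 2 - 2), d1 / 2 - 1))
            cx = float(rng.uniform(min(r, d2 / 2 - 2), d2 / 2 - 1))
        elif b == 1:
            cy = float(rng.uniform(d1 / 2, max(d1 - 1 - r, d1 / 2 + 1)))
            cx = float(rng.uniform(d2 / 2, max(d2 - 1 - r, d2 / 2 + 1)))
        else:
            cy = float(rng.uniform(r, d1 - 1 - r))
            cx = float(rng.uniform(r, d2 - 1 - r))
        inten = tuple(float(v) for v in rng.uniform(*spec.blob_intensity_range, size=3))
        bump = np.exp(-(((rows - cy) ** 2 + (cols - cx) ** 2) / (2 * (r / 2.0) ** 2)))
        for c in range(3):
            img[:, :, c] += inten[c] * bump
        centers.append((cy, cx))
        radii.append(r)
        intensities.append(inten)
    img = np.clip(img, 0.0, 1.0)
    return img, SceneRecord(image_id=image_id, blob_centers=centers,
                            blob_radii=radii, blob_intensities=intensities)


def gen_images(n: int, spec: SceneSpec | None = None,
               seed: int = 0) -> tuple[list[np.ndarray], list[SceneRecord]]:
    """Seeded reproducible images with 1-3 blobs on a noisy background."""
    if n < 1:
        raise ValueError("n must be >= 1")
    spec = spec or SceneSpec()
    rng = np.random.default_rng(seed)
    images, records = [], []
    for i in range(n):
        img, rec = _render_scene(rng, spec, image_id=f"img_{i:04d}")
        images.append(img)
        records.append(rec)
    return images, records


def gen_gaze(scene: SceneRecord, class_label: int, shape: tuple[int, int],
             spec: ScanpathSpec | None = None, seed: int = 0,
             subject_id: str = "s00") -> GazeRecording:
    """Simulate one viewing of one image.

    Class 1 scanpaths dwell on attractor A early and drift linearly to
    attractor B between ``drift_start_frac`` and ``drift_end_frac`` of the
    viewing time; class 0 dwells on A throughout.  Gaussian jitter is added
    around the current attractor; each sample's duration is one sampling
    period.
    """
    spec = spec or ScanpathSpec()
    rng = np.random.default_rng(seed)
    d1, d2 = shape
    centers = scene.blob_centers
    A = np.asarray(centers[0])
    B = np.asarray(centers[1]) if len(centers) > 1 else np.asarray([d1 - 1 - A[0], d2 - 1 - A[1]])
    n_samples = max(1, int(round(spec.sample_rate_hz * spec.total_duration_s)))
    dt = spec.total_duration_s / n_samples
    onsets = np.arange(n_samples) * dt
    frac = (onsets + dt / 2.0) / spec.total_duration_s
    if class_label == 1:
        w = np.clip((frac - spec.drift_start_frac) /
                    max(spec.drift_end_frac - spec.drift_start_frac, 1e-9), 0.0, 1.0)
    else:
        w = np.zeros(n_samples)
    pos = (1.0 - w)[:, None] * A[None, :] + w[:, None] * B[None, :]
    if spec.jitter_sd > 0:
        pos = pos + rng.normal(0.0, spec.jitter_sd, size=pos.shape)
    rows = np.clip(pos[:, 0], 0, d1 - 1)
    cols = np.clip(pos[:, 1], 0, d2 - 1)
    samples = np.column_stack([cols, rows, onsets, np.full(n_samples, dt)])
    return GazeRecording(subject_id=subject_id, image_id=scene.image_id,
                         samples=samples)


def gen_dataset(n_images: int, out_dir: str | Path, positive_frac: float = 0.5,
                scene_spec: SceneSpec | None = None,
                scan_spec: ScanpathSpec | None = None, seed: int = 0,
                category: str = "excitement", subject_id: str = "s00") -> dict:
    """Write a complete on-disk dataset: images/ (PNG), gaze.csv, labels.csv.

    Labels are balanced deterministically to ``positive_frac`` and shuffled
    by the seed.  Returns a manifest dict with the file paths and label
    array for convenience.
    """
    out_dir = Path(out_dir)
    (out_dir / "images").mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    n_pos = int(round(n_images * positive_frac))
    labels = np.array([1] * n_pos + [0] * (n_images - n_pos))
    rng.shuffle(labels)

    scene_spec = scene_spec or SceneSpec()
    images, records = gen_images(n_images, scene_spec, seed=seed + 1)
    gaze_rows = []
    label_rows = []
    for i, (img, rec) in enumerate(zip(images, records)):
        png = Image.fromarray(np.round(img * 255).astype(np.uint8))
        png.save(out_dir / "images" / f"{rec.image_id}.png")
        gaze = gen_gaze(rec, int(labels[i]), scene_spec.shape, scan_spec,
                        seed=seed + 1000 + i, subject_id=subject_id)
        for x, y, onset, dur in gaze.samples:
            gaze_rows.append((subject_id, rec.image_id, f"{x:.4f}", f"{y:.4f}",
                              f"{onset:.6f}", f"{dur:.6f}"))
        label_rows.append((rec.image_id, category, int(labels[i])))

    gaze_path = out_dir / "gaze.csv"
    with open(gaze_path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["subject_id", "image_id", "x", "y", "onset_s", "duration_s"])
        writer.writerows(gaze_rows)
    labels_path = out_dir / "labels.csv"
    with open(labels_path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["image_id", "category", "label"])
        writer.writerows(label_rows)
    return {
        "images_dir": out_dir / "images",
        "gaze_csv": gaze_path,
        "labels_csv": labels_path,
        "labels": labels,
        "records": records,
    }


def gen_planted_cft(n: int, dims: tuple[int, int, int], effect: float = 1.0,
                    noise_sd: float = 0.1, sparsity: float = 0.05,
                    seed: int = 0, mode: str = "gtda") -> dict:
    """Third-order tensors with planted structure and their ground truth.

    ``mode="gtda"``: class means differ by ``effect * (u outer e1 outer e1)``
    for a random unit vector ``u`` along mode 1; i.i.d. Gaussian noise.
    ``mode="ltr"``: labels are Bernoulli draws from ``sigmoid(<Z, V>)`` for
    a sparse planted ``Z`` with entries of magnitude 1.
    """
    if mode not in ("gtda", "ltr"):
        raise ValueError(f"unknown planted mode {mode!r}")
    if not (0 < sparsity <= 1):
        raise ValueError("sparsity must be in (0, 1]")
    rng = np.random.default_rng(seed)
    d1, d2, d3 = dims
    if mode == "gtda":
        u = rng.normal(size=d1)
        u /= np.linalg.norm(u)
        labels = np.array([0, 1] * (n // 2) + [0] * (n % 2))
        rng.shuffle(labels)
        shift = np.zeros(dims)
        shift[:, 0, 0] = effect * u
        tensors = rng.normal(0.0, noise_sd, size=(n,) + dims)
        tensors[labels == 1] += shift
        return {"tensors": tensors, "labels": labels, "u": u, "shift": shift}
    # ltr mode
    total = d1 * d2 * d3
    n_nz = max(1, int(round(sparsity * total)))
    support = rng.choice(total, size=n_nz, replace=False)
    Z = np.zeros(total)
    Z[support] = rng.choice([-1.0, 1.0], size=n_nz)
    Z = Z.reshape(dims)
    tensors = rng.normal(0.0, 1.0, size=(n,) + dims)
    if noise_sd > 0:
        tensors += rng.normal(0.0, noise_sd, size=tensors.shape)
    logits = np.tensordot(tensors, Z, axes=3)
    if noise_sd == 0:
        labels = (logits > 0).astype(int)
    else:
        labels = (rng.uniform(size=n) < 1.0 / (1.0 + np.exp(-logits))).astype(int)
    return {"tensors": tensors, "labels": labels, "Z": Z,
            "support": np.flatnonzero(Z.reshape(-1))}
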
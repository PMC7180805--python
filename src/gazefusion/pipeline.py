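"""End-to-end orchestration: represent -> features -> GTDA -> LTR -> evaluate.

A :class:`RunConfig` fixes every knob of the pipeline; given a dataset on
disk (images directory, gaze CSV, labels CSV) the pipeline builds the
gaze-weighted representations, extracts and unifies features, fits the
discriminant projections and the logistic tensor model per (subject,
category), and evaluates per-cell F1.  Everything is deterministic given
the config and its seeds; artifacts are stamped with the config hash.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from . import evaluation, features, gaze, gtda, ltr

__all__ = ["RunConfig", "run_train", "run_eval", "split_images", "load_dataset"]


@dataclass
class RunConfig:
    images_dir: str = ""
    gaze_csv: str = ""
    labels_csv: str = ""
    out_dir: str = "artifacts"
    image_shape: tuple[int, int] = (32, 32)
    d4: int = 10
    sigma: float | str = "auto"
    epsilon: float = 1e-6
    skip_initial_s: float = 0.0
    duration_weighted: bool = True
    extractors: str = "toy:g=2,toy:g=3,toy:g=4"
    fda_ridge: float = 1e-3
    gtda_dims: tuple[int, int, int] | str = "auto"
    gtda_sweeps: int = 10
    gtda_tol: float = 1e-6
    gtda_energy: float = 0.95
    ltr_lambda: float | str = "auto"
    ltr_max_iter: int = 500
    ltr_tol: float = 1e-7
    train_frac: float = 0.8
    split_seed: int = 0
    categories: list[str] = field(default_factory=list)  # empty -> all in labels
    pool_subjects: bool = True
    label_permutation_seed: int | None = None  # control runs: shuffle labels

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        if isinstance(cfg.image_shape, list):
            cfg.image_shape = tuple(cfg.image_shape)
        if isinstance(cfg.gtda_dims, list):
            cfg.gtda_dims = tuple(cfg.gtda_dims)
        return cfg

    def config_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    def resolved_sigma(self) -> float:
        if self.sigma == "auto":
            return gaze.default_sigma(self.image_shape)
        return float(self.sigma)


def load_dataset(config: RunConfig):
    """Load labels, gaze recordings and (lazily referenced) image paths."""
    labels = pd.read_csv(config.labels_csv, dtype={"image_id": str, "category": str})
    for col in ("image_id", "category", "label"):
        if col not in labels.columns:
            raise ValueError(f"labels CSV missing column {col!r}")
    recordings = gaze.read_gaze_csv(config.gaze_csv)
    images_dir = Path(config.images_dir)
    if not images_dir.is_dir():
        raise FileNotFoundError(f"images directory not found: {images_dir}")
    image_paths = {}
    for rec in recordings:
        for ext in (".png", ".jpg", ".jpeg"):
            p = images_dir / f"{rec.image_id}{ext}"
            if p.exists():
                image_paths[rec.image_id] = p
                break
        else:
            raise FileNotFoundError(f"image not found for id {rec.image_id!r}")
    return labels, recordings, image_paths


def split_images(image_ids: list[str], train_frac: float,
                 seed: int) -> tuple[list[str], list[str]]:
    """Seeded uniform split without replacement; order-stable output."""
    ids = sorted(image_ids)
    rng = np.random.default_rng(seed)
    n_train = int(round(train_frac * len(ids)))
    perm = rng.permutation(len(ids))
    train = sorted(ids[i] for i in perm[:n_train])
    test = sorted(ids[i] for i in perm[n_train:])
    if not test:
        raise ValueError("test split is empty; lower train_frac or add images")
    return train, test


def _build_representations(config: RunConfig, recordings, image_paths):
    sigma = config.resolved_sigma()
    reps = {}
    for rec in recordings:
        img = gaze.load_image(image_paths[rec.image_id], shape=config.image_shape)
        bins = gaze.bin_gaze_to_frames(rec, config.d4,
                                       skip_initial_s=config.skip_initial_s)
        fix = gaze.build_fixation_maps(bins, config.image_shape, sigma=sigma,
                                       epsilon=config.epsilon,
                                       duration_weighted=config.duration_weighted)
        giw = gaze.compute_giw(fix)
        rep = gaze.build_representation(img, giw, image_id=rec.image_id,
                                        subject_id=rec.subject_id)
        reps[(rec.subject_id, rec.image_id)] = rep
    return reps


def _category_labels(labels: pd.DataFrame, category: str) -> dict[str, int]:
    sub = labels[labels["category"] == category]
    if sub.empty:
        raise ValueError(f"category {category!r} absent from labels CSV")
    return dict(zip(sub["image_id"], sub["label"].astype(int)))


def _train_cell(config: RunConfig, fms_by_image: dict, y_by_image: dict,
                train_ids: list[str], extractor_list, seed: int) -> dict:
    """Fit FDA projections, GTDA and LTR for one (subject, category) cell."""
    y_train = np.array([y_by_image[i] for i in train_ids])
    if np.unique(y_train).size < 2:
        raise ValueError("training split contains a single class")
    d1f = min(e.output_dim for e in extractor_list)

    # FDA per backbone on pooled frame-level vectors of the training images.
    projections = []
    for b in range(len(extractor_list)):
        X_rows, y_rows = [], []
        for i in train_ids:
            mat = fms_by_image[i].matrices[b]  # (dim_b, d4)
            X_rows.append(mat.T)
            y_rows.extend([y_by_image[i]] * mat.shape[1])
        X = np.vstack(X_rows)
        projections.append(features.fda_fit(X, np.array(y_rows), k=d1f,
                                            ridge=config.fda_ridge))

    cfts = {i: features.build_cft(fms_by_image[i], projections, image_id=i)
            for i in fms_by_image}
    train_tensors = [cfts[i].tensor for i in train_ids]

    proj_set = gtda.gtda_fit(train_tensors, y_train,
                             target_dims=config.gtda_dims,
                             sweeps=config.gtda_sweeps, tol=config.gtda_tol,
                             energy=config.gtda_energy)
    transformed = np.asarray([gtda.gtda_transform(T, proj_set)
                              for T in train_tensors])
    # Center on the training mean: the model has no intercept, so the grand
    # mean of the transformed tensors would otherwise act as a fixed logit
    # offset that the L1 penalty must fight.
    center = transformed.mean(axis=0)
    transformed = transformed - center

    if config.ltr_lambda == "auto":
        model = ltr.ltr_fit_cv(transformed, y_train, max_iter=config.ltr_max_iter,
                               tol=config.ltr_tol, seed=seed)
    else:
        model = ltr.ltr_fit(transformed, y_train, lam=float(config.ltr_lambda),
                            max_iter=config.ltr_max_iter, tol=config.ltr_tol)
    return {"fda": projections, "gtda": proj_set, "ltr": model, "cfts": cfts,
            "center": center}


def run_train(config: RunConfig) -> dict:
    """Train per-(subject, category) models; persist artifacts + manifest.

    Returns ``{"artifacts": {(subject, category): cell}, "train_ids": ...,
    "test_ids": ...}``.  With ``pool_subjects`` every subject's recordings
    feed one model per category under the subject key ``"pooled"``.
    """
    labels, recordings, image_paths = load_dataset(config)
    if config.label_permutation_seed is not None:
        rng = np.random.default_rng(config.label_permutation_seed)
        labels = labels.copy()
        for cat, grp in labels.groupby("category"):
            labels.loc[grp.index, "label"] = rng.permutation(grp["label"].to_numpy())
    categories = config.categories or sorted(labels["category"].unique())
    extractor_list = features.parse_extractor_spec(config.extractors)

    reps = _build_representations(config, recordings, image_paths)
    image_ids = sorted({img for (_, img) in reps})
    train_ids, test_ids = split_images(image_ids, config.train_frac,
                                       config.split_seed)

    subjects = (["pooled"] if config.pool_subjects
                else sorted({s for (s, _) in reps}))

    # Feature extraction is label-free: do it once per (subject, image).
    fms_cache = {key: features.extract_features(rep, extractor_list)
                 for key, rep in reps.items()}

    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    artifacts = {}
    for subject in subjects:
        if subject == "pooled":
            # Any subject's recording of an image is usable; prefer the first.
            fms_by_image = {}
            for (s, i), fms in sorted(fms_cache.items()):
                fms_by_image.setdefault(i, fms)
        else:
            fms_by_image = {i: fms for (s, i), fms in fms_cache.items()
                            if s == subject}
        for category in categories:
            y_by_image = _category_labels(labels, category)
            cell = _train_cell(config, fms_by_image, y_by_image, train_ids,
                               extractor_list, seed=config.split_seed)
            artifacts[(subject, category)] = cell
            _persist_cell(out_dir, config, subject, category, cell)

    manifest = {
        "config": dataclasses.asdict(config),
        "config_hash": config.config_hash(),
        "categories": categories,
        "subjects": subjects,
        "train_ids": train_ids,
        "test_ids": test_ids,
    }
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    return {"artifacts": artifacts, "train_ids": train_ids,
            "test_ids": test_ids, "labels": labels, "manifest": manifest}


def _persist_cell(out_dir: Path, config: RunConfig, subject: str,
                  category: str, cell: dict) -> None:
    path = out_dir / f"model_{subject}_{category}.h5"
    with h5py.File(path, "w") as fh:
        fh.attrs["config_hash"] = config.config_hash()
        fh.attrs["subject"] = subject
        fh.attrs["category"] = category
        g = fh.create_group("fda")
        for b, proj in enumerate(cell["fda"]):
            gb = g.create_group(f"backbone_{b}")
            gb.create_dataset("mean", data=proj.mean)
            gb.create_dataset("basis", data=proj.basis)
            gb.attrs["ridge"] = proj.ridge
        g = fh.create_group("gtda")
        for l, P in enumerate(cell["gtda"].P):
            g.create_dataset(f"P{l + 1}", data=P)
        g.create_dataset("eta", data=np.asarray(cell["gtda"].eta))
        g.create_dataset("objective_trace",
                         data=np.asarray(cell["gtda"].objective_trace))
        g = fh.create_group("ltr")
        g.create_dataset("Z", data=cell["ltr"].Z)
        g.create_dataset("center", data=cell["center"])
        g.attrs["lambda_l1"] = cell["ltr"].lambda_l1
        g.attrs["converged"] = cell["ltr"].converged


def run_eval(config: RunConfig, trained: dict | None = None) -> dict:
    """Evaluate trained models on the held-out split.

    Returns the per-cell F1 grid (:class:`evaluation.ResultTable`), the raw
    prediction rows, and writes ``predictions.csv`` / ``f1_table.csv`` under
    the config's output directory.
    """
    trained = trained or run_train(config)
    labels = trained["labels"]
    test_ids = trained["test_ids"]
    if not test_ids:
        raise ValueError("empty test split")
    rows = []
    cells = {}
    for (subject, category), cell in trained["artifacts"].items():
        y_by_image = _category_labels(labels, category)
        truth, pred = [], []
        for i in test_ids:
            V = gtda.gtda_transform(cell["cfts"][i].tensor, cell["gtda"])
            V = V - cell["center"]
            p = ltr.predict_proba(V, cell["ltr"])
            yhat = int(p > 0.5)
            truth.append(y_by_image[i])
            pred.append(yhat)
            rows.append({"subject": subject, "category": category,
                         "image_id": i, "probability": p, "label": yhat,
                         "truth": y_by_image[i]})
        conf = evaluation.confusion_from_predictions(truth, pred)
        _, _, f1 = evaluation.precision_recall_f1(conf)
        cells[(subject, category)] = f1
    grid = pd.DataFrame(
        {cat: {subj: cells[(subj, cat)]
               for subj in sorted({s for s, _ in cells})}
         for cat in sorted({c for _, c in cells})}
    )
    table = evaluation.aggregate(grid)
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    pred_df = pd.DataFrame(rows).sort_values(
        ["subject", "category", "image_id"]).reset_index(drop=True)
    pred_df.to_csv(out_dir / "predictions.csv", index=False,
                   float_format="%.10f")
    grid.to_csv(out_dir / "f1_table.csv", float_format="%.6f")
    return {"table": table, "predictions": pred_df,
            "grand_f1": table.grand_mean}
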
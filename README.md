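# gazefusion

Emotional-category classification of images from *where and when* viewers
look at them. The package is for researchers in affective computing and
psychophysiology who record eye gaze while subjects view images (e.g.
abstract paintings annotated with emotion categories such as *awe*, *fear*
or *excitement*) and want a classifier that exploits the temporal dynamics
of visual attention rather than image content alone.

## The method

Given an image `X ∈ R^{d1×d2×3}` and one subject's gaze samples on it, the
viewing time is split into `d4` frames and a smoothed, duration-weighted
fixation map `W^gaze_f` is built per frame. The **gaze-and-image weight
(GIW)** matrices

    W_f = d4 · W^gaze_f / Σ_f W^gaze_f + 1

blend attention with uniform image content; per pixel, `Σ_f W_f = 2·d4`, so
the fourth-order representation `X⁴ᵗʰ[:, :, c, f] = X[:, :, c] ∘ W_f`
(Hadamard product per color channel) reconstructs the original image
exactly via `X = (1 / 2d4) Σ_f X⁴ᵗʰ[:, :, :, f]`.

Each frame is fed to several feature extractors ("backbones") of differing
output dimension; Fisher discriminant analysis unifies the dimensions to
the smallest one, and the per-frame, per-backbone features are stacked into
a third-order **CNN-feature tensor (CFT)** `V ∈ R^{d1f×d2f×d3f}`
(feature × backbone × frame). **General Tensor Discriminant Analysis
(GTDA)** then learns one orthonormal projection per mode by alternating
maximization of `tr(P_lᵀ(S_l^b − η_l S_l^w)P_l)`, with `η_l` the largest
eigenvalue of `(S_l^w)⁻¹S_l^b`, and the transformed tensor `V̂ = V ×₁P₁
×₂P₂ ×₃P₃` is classified by **logistic tensor regression (LTR)**:

    Pr[y = 1 | V̂, Z] = 1 / (1 + exp(−⟨Z, V̂⟩)),

with the coefficient tensor `Z` fit under an L1 penalty by a monotone
accelerated proximal gradient method. Per-category binary models give
multi-label predictions; performance is summarized by precision, recall and
F1, aggregated per subject and per category, with Welch's t-test for
method comparison.

The shipped default extractors are deterministic grid-mean "toy" backbones,
so the whole pipeline runs with no pretrained weights; any callable
matching `FeatureExtractorContract` (e.g. a CNN's last pooling layer) can
be plugged in.

## Worked example

The synthetic generator emulates the study setting end to end: images with
localized object blobs, class-dependent scanpaths (class 1 drifts from
attractor A to attractor B over the viewing time; class 0 dwells on A), and
per-category binary labels.

```python
from pathlib import Path
from gazefusion import synthetic, pipeline

data = synthetic.gen_dataset(200, Path("demo"), seed=7)
cfg = pipeline.RunConfig(images_dir="demo/images", gaze_csv="demo/gaze.csv",
                         labels_csv="demo/labels.csv", out_dir="demo/artifacts",
                         d4=10, train_frac=0.75, split_seed=7)
result = pipeline.run_eval(cfg)
print(f"held-out F1: {result['grand_f1']:.3f}")
```

prints

```
held-out F1: 0.979
```

i.e. on a 150/50 split of 200 simulated viewings the pipeline recovers the
attention-dynamics class almost perfectly, while a label-permuted control
run (`label_permutation_seed=...`) stays at the ~0.5 chance baseline.
`demo/artifacts/` then holds the per-cell models (HDF5), `predictions.csv`
(per-image probability and label) and `f1_table.csv`.

The same flow is available from the shell:

```bash
gazefusion simulate --n 200 --seed 7 --out demo
gazefusion run --config run.yaml
gazefusion ttest --a tableA.csv --b tableB.csv
```

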
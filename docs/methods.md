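# Methods

## Gaze-weighted image representation

One recording is the sample list `(x, y, onset, duration)` of a subject
viewing one image, with 0-based pixel coordinates, origin top-left, `x` the
column. The span `[first onset, last onset + last duration]` is split into
`d4` equal half-open bins; each sample is assigned whole to the bin
containing its onset midpoint (a midpoint exactly on a boundary goes to
the later bin). Per frame, samples vote their duration in seconds into
their nearest pixel; the vote image is smoothed with an isotropic Gaussian
(reflect boundary, which conserves vote mass) and floored by adding
`epsilon` everywhere. A count-weighted voting mode is available
(`duration_weighted=False`).

The GIW matrices `W_f = d4·W^gaze_f / Σ_f W^gaze_f + 1` divide by the
per-pixel across-frame sum, which is zero wherever no frame ever received
attention; the `epsilon` floor (default `1e-6`) makes the division
well-defined at every pixel and turns the reconstruction identity
`X = (1/2d4)·Σ_f X ∘ W_f` into an exact global property rather than one
holding only on gazed pixels. GIW is invariant to positive rescaling of
the fixation maps, so the choice of duration units does not matter.

Parameter defaults and reasons:

- `d4 = 10` in the pipeline defaults (simulation scale); `d4 = 100` in the
  `represent` CLI (the resolution at which attention trajectories on real
  multi-second viewings are typically discretized). Both configurable.
- Gaussian width `sigma = 0.02 ×` image diagonal in pixels: roughly the
  foveal spread when an image occupies most of a desktop display.
- Images are bilinearly resized to the configured `(d1, d2)` before
  weighting; gaze coordinates are rescaled with them.
- `skip_initial_s` (default 0) can drop samples from the start of each
  viewing, e.g. the centering interval before stimulus onset; by default
  nothing is dropped because the trailing part of that interval may already
  carry stimulus-driven attention.

## Feature extraction and the fusion tensor

Each frame of the representation (a weighted color image) is mapped by
every backbone to a feature vector. The default backbones are three grid
extractors (cell means of g×g partitions per channel, g = 2, 3, 4, so
output dimensions 12/27/48 exercise the dimension-unification path); they
are deterministic and linear, which also makes several worked identities
exact (uniform attention doubles the features). Real CNN features can be
plugged in through `FeatureExtractorContract`.

Dimension unification uses Fisher discriminant analysis fit on pooled
frame-level vectors of the training images, each frame labeled with its
image's binary category label. For a binary label the between-class
scatter has rank 1, so a target dimension `k > 1` is completed with
principal components of the total scatter orthogonal to the discriminant
direction, and the combined basis orthonormalized; the within-class
scatter is ridged (default `1e-3`) before inversion. Per-frame pooling
(rather than FDA on time-averaged features) keeps the temporal axis of the
fusion tensor meaningful. Every backbone — including one already at the
target dimension — passes through its fitted projection, for uniformity.

The CFT stacks the projected features as `(feature, backbone, frame)`;
backbone order is a configuration list, exposed because the mode-2
expansion makes the order matter in principle, and no selection rule is
imposed.

## GTDA

Per mode `l`, the between/within scatters are built from the class-mean
differences and residuals after projecting the *other* two modes, unfolded
along mode `l`. The convention for unfolding is: row = mode-`l` index,
columns enumerate remaining indices with the lower-numbered remaining mode
varying fastest; `mode_product` satisfies
`unfold(T ×_l U, l) = Uᵀ·unfold(T, l)`, so a `(d × d*)` matrix shrinks a
mode. `η_l` is the largest eigenvalue of the (ridged) `(S_l^w)⁻¹S_l^b`,
recomputed whenever the scatters are; the mode update takes the top-k
orthonormal eigenvectors of the symmetric `S_l^b − η_l·S_l^w`.

The three mode problems are coupled and share no single objective
function, so plain alternating sweeps can oscillate. The fit therefore
runs *greedy* alternating optimization: after each full sweep the summed
mode objectives are evaluated consistently at the new projection set, and
the sweep is kept only if the objective did not decrease — otherwise the
previous projections are retained and iteration stops. The recorded trace
is non-decreasing by construction, and in practice one to six sweeps
suffice. Defaults: identity-column initialization, at most 10 sweeps,
relative-change tolerance `1e-6`.

Numerical choices: ridge `1e-6·trace(S_w)/d` on the within-scatter (the
CFT's feature dimension typically exceeds the sample count, so `S_w` is
singular); eigenvector signs fixed by making each column's first nonzero
entry positive; eigenvalue ties broken by ascending original index; a
zero between-scatter falls back to the smallest within-scatter directions.
Target dimensions default to retaining a 0.95 eigenvalue-energy fraction
of the per-mode total scatter.

## LTR

The classifier is `Pr[y=1|V] = σ(⟨Z, V⟩)` with `Z` the same shape as the
transformed CFT and no intercept. The fit minimizes the Bernoulli negative
log-likelihood plus `λ‖Z‖₁` — the log-likelihood is written with the
sigmoid inside the logarithms, the only reading under which the logistic
model is well-defined for arbitrary logits. The solver is monotone FISTA:
soft-thresholding proximal steps from a Lipschitz-initialized backtracking
line search, with the incumbent kept whenever an accelerated candidate
would increase the penalized objective, so the recorded history is
non-increasing. `Z` starts at zero; defaults `max_iter = 500`, relative
tolerance `1e-7`. Ties at probability 0.5 classify as the negative class,
deterministically.

`λ = "auto"` selects from a log grid by 3-fold cross-validated F1 and
refits on all training data.

Before fitting, the pipeline centers the transformed tensors on the
training mean (stored in the artifact and re-applied at prediction).
Without an intercept, the grand-mean component of the features acts as a
constant logit offset that the L1 penalty must spend coefficients to
cancel, which degrades generalization; centering removes it without
changing the model class.

## Evaluation

Precision `TP/(TP+FP)`, recall `TP/(TP+FN)`, `F1 = 2PR/(P+R)`, with every
0/0 mapped to 0 (rare categories can produce empty denominators in a small
test split). The train/test split (default 0.8, 0.75 in the simulation
study) is seeded uniform sampling without replacement. Result grids hold
one F1 per (subject, category); rectangular grids give identical grand
means under subject-first and category-first aggregation. Welch's
two-sample t-test (unequal variances, Welch–Satterthwaite df, two-sided p)
compares two methods' F1 cells.

## Synthetic data: what it emulates, and what it does not

The generator produces the study conditions the pipeline targets: images
with localized objects, viewers whose *attention trajectory* depends on
the class, and per-category binary labels. Scanpaths follow a
two-attractor dwell/jitter process — class 0 dwells on blob A for the
whole viewing; class 1 drifts linearly from A to B between 30% and 70% of
the viewing time; positions get Gaussian jitter (sd 2 px) and are sampled
at 60 Hz for 3 s. The two attractor blobs are placed in opposite image
quadrants (A upper-left, B lower-right; further blobs are unconstrained
distractors). This placement is part of the planted effect: a linear
tensor classifier can express "attention is *here* late in the viewing",
but not "attention moved somewhere" with image-specific directions — with
fully random attractor geometry the class signal is a variance signal,
outside the model class, and no pipeline of this family could detect it.

Default simulation scale: 200 images of 32×32 px, `d4 = 10`, three grid
extractors, balanced labels, one pooled subject — sized so the full study,
repeated with a permuted-label control, runs in well under a minute on one
CPU.

What the generator does **not** emulate: saliency-driven free viewing,
saccade/fixation event structure, blinks and tracker noise, inter-subject
variability, correlated multi-label structure across the eight emotional
categories, and natural-image statistics. Passing the end-to-end check
therefore shows that the pipeline recovers a planted attention-dynamics
signal through the full representation/fusion/projection/regression chain
— not that real gaze on real paintings is this separable.

`gen_planted_cft` bypasses the image stages to test the solvers directly:
a mode-1 mean shift along a random unit direction (GTDA recovery), or
labels drawn from a logistic model with a sparse ±1 coefficient tensor
(LTR support/sign recovery).

## Known limitations

- Binary per-category models only; no shared structure across categories.
- GTDA is a greedy heuristic; it can stop at a non-global fixed point (the
  rotation-grid check bounds the gap on small instances).
- The FDA unification assumes frame-level vectors inherit the image's
  label, which is wrong for class-1 early frames in the simulated dynamics;
  empirically the PCA completion preserves enough signal downstream.
- No fixation/saccade detection: input samples are taken as given.
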
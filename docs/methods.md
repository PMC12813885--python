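# Methods

## Problem and model

The package decides, one image slice and one structure at a time, whether a
binary segmentation mask is *acceptable* (label 0) or *requires revision*
(label 1), and attaches a confidence to that decision. The classifier is a
residual CNN over a two-channel input — the grayscale slice and the binary
mask stacked along the channel axis — whose globally pooled features are
concatenated with a one-hot structure code of length K before the fully
connected head. Conditioning a single network on the structure code, rather
than training one model per organ, is what makes multi-organ QA practical:
the backbone shares low-level boundary features across structures while the
head can specialize per code.

Every fully connected layer is preceded by an inverted-dropout unit with rate
0.1. The head ends in one sigmoid unit trained with binary cross-entropy, so
the output is the probability of the revision-required class; the hard label
applies the fixed quality threshold 0.5 (inclusive: p = 0.5 flags for
revision).

Two backbones are registered. `resnet34_style` follows the classic four-stage
layout (3/4/6/3 blocks at 64/128/256/512 channels). `small_resnet` — a stem
at 16 channels plus two downsampling residual stages at 32 and 64 channels —
is the desk-scale default; it was selected from three candidate widths/
resolutions by validation accuracy on a small phantom cohort and trains in
minutes on one CPU core. Both are built on the package's own numpy
neural-network engine (`nn.py`: im2col convolution, batch normalization,
dense/dropout layers, Adam), which keeps the whole stack free of GPU
dependencies and bit-reproducible.

## Training protocol

Defaults follow the reference protocol: Adam at initial learning rate 1e-4,
multiplied by 0.2 every 100 epochs; batch size 64; per-structure balanced
epochs in which every acceptable sample is paired with a freshly perturbed
revision-required twin, regenerated each epoch from an epoch-specific RNG
stream. Balance is enforced at epoch granularity and a uniform shuffle is
applied, which makes mini-batches approximately balanced as well. The best
checkpoint by validation accuracy (threshold 0.5, dropout off) is retained;
no early stopping is applied.

The scaled-down synthetic study (see below) instead trains 20 epochs at
3e-3: a 100-epoch decay schedule at 1e-4 is an appropriate setting for long
GPU runs, not for a 20-epoch small-backbone run, where a short-schedule rate
converges to a usable operating point. This is a deliberate choice of the
desk-scale experiment, not a change to the defaults.

## Uncertainty

MC-dropout inference keeps the head's dropout units active and runs T
stochastic forward passes (default T = 30; the synthetic study uses T = 10).
Each pass t draws its dropout masks from an independent stream seeded by the
pair (seed, t) — counter-based splitting — so results are reproducible and
independent of batch composition. The predictive probability is the
arithmetic mean of the per-pass probabilities, and the uncertainty score is
the normalized Shannon entropy of that mean,

    H(p) = -[p ln p + (1-p) ln(1-p)] / ln 2,

with the limit convention 0·log 0 = 0 implemented exactly (each term is
zeroed where its probability vanishes; a 1e-12 clamp guards the logarithm
only). Entropy is computed from the mean probability — predictive entropy —
not as a mean of per-pass entropies, and no epistemic/aleatoric decomposition
is attempted.

## Calibration and decision policy

Validation predictions are sorted by ascending uncertainty (ties broken by
sample id, so curves are reproducible) and the cumulative recall of the
revision-required class is computed across the ordered set. Conventions,
fixed here because the procedure alone does not determine them:

* cumulative recall is the sensitivity *within* the prefix (revision-required
  samples with uncertainty ≤ u_i that were correctly flagged, over all
  revision-required samples in the prefix), matching how the deployed policy
  is evaluated on the accepted subset;
* before the first revision-required sample enters the prefix, recall is
  vacuously 1, so an all-acceptable low-uncertainty head never forces τ to 0;
* τ is the uncertainty of the first point whose cumulative recall drops below
  the target (default 0.98; per-structure overrides supported, e.g. 1.0 for a
  treatment target); if the curve never drops, τ = 1.0 and everything is
  auto-accepted;
* acceptance is strict (H < τ): a sample whose uncertainty equals τ is
  flagged.

With these rules the accepted prefix of the calibration set itself satisfies
the sensitivity target by construction; the package verifies the same
property empirically on held-out test data. Calibration is per structure by
default (a pooled mode exists for very small cohorts), and re-running it on
identical predictions is idempotent.

The uncertainty–accuracy diagnostic groups test predictions into 80 uniform
entropy bins (entropy 1.0 falls in the last bin; empty bins are omitted,
bins without revision-required members report recall as absent) and checks
that per-bin accuracy decreases with bin uncertainty.

## Synthetic error operators

Revision-required masks are manufactured from clean masks by exactly one of
four families per sample, drawn uniformly unless forced. Coordinate
convention throughout: arrays are (row, col) = (y, x); "x-axis" means
columns.

* **Dilation / erosion** use rectangular structuring elements — 1×5 (x only),
  5×1 (y only), 5×5 (both) — i.e. exactly 2 px per selected direction;
  "approximately two pixels" is realized as a fixed magnitude with a config
  knob. Dilation must strictly grow and erosion strictly shrink the mask.
* **Shift** translates the whole mask by an integer offset drawn uniformly
  from the 24 nonzero pairs in [-2, 2]²; pixels leaving the frame are
  dropped, so interior masks preserve area exactly.
* **Boundary noise** traces the longest iso-0.5 contour, selects n points
  uniformly without replacement with n uniform on {1..min(15, boundary
  length)}, displaces each by independent integer offsets in [-2, 2] per
  axis, and refills the polygon. If refilling splits the region, the largest
  component is kept (one structure, one region). Contours shorter than 8
  vertices (sub-2×2-pixel support) are treated as untraceable.

A draw that empties the mask, changes nothing, or equals the input is
*degenerate*: the sampler redraws a fresh family and parameters (up to 25
attempts) rather than emitting an implausible or vacuous error, and raises
only for pathological inputs. Every emitted perturbation therefore differs
from its source by at least one pixel while respecting the ±2 px / ≤15-point
bounds.

## Phantom generator

Clinical images with approved contours cannot ship with the package, so the
generator fabricates what the pipeline needs: per-patient stacks of 64×64
grayscale slices (2–4 per patient by default) with exact ground-truth masks.
Each slice carries three elliptical structures with distinct characteristic
sizes — bladder-like (semi-axes 8–14 px), prostate-like (5–8 px),
urethra-like (3–5 px) — because fixed ±2 px perturbations are proportionally
much larger on small structures, and size-dependent behavior is worth
exercising. Structures sit on a ring around the image center with ±4 px
jitter; intensities are background 0.25 and foregrounds 0.85/0.70/0.55 with
Gaussian blur σ = 0.7 and noise σ = 0.05, then clipped to [0, 1]
(normalization is part of generation — the package-wide intensity contract).
Config validation enforces that shapes fit the frame and that every
foreground/background contrast is at least twice the noise σ, so the task is
learnable by construction.

What the phantom does *not* emulate: MR physics (bias fields, coil profiles),
3D anatomical continuity between slices, inter-observer label ambiguity, or
organs with concave/complex shapes. Passing the end-to-end checks therefore
demonstrates that the pipeline's machinery — balanced dynamic training,
MC-dropout ranking of errors, threshold calibration — behaves correctly, not
that clinical-grade accuracy would transfer to real MR data.

## Scaled-down synthetic study

The end-to-end evaluation (also what `scripts/acceptance.py` reruns) uses
100/20/20 train/validation/test patients, three structures, the
`small_resnet` backbone trained 20 epochs at 3e-3, and T = 10 MC passes —
about five minutes on one CPU core. Measured on the frozen balanced test set:
overall accuracy ≈ 0.91–0.93 across seeds, Spearman ρ between binned
uncertainty and accuracy ≈ −0.3 to −0.45 (p < 0.01), and, after calibrating
at a 98% recall target on validation, sensitivity ≈ 0.95–0.98 within the
auto-accepted subset at 56–64% coverage. Larger cohorts and longer schedules
push accuracy higher; these sizes are the package's chosen trade-off for a
reproducible desk-scale experiment.

## Numerical and reproducibility choices

* All randomness flows through `numpy.random.Generator`; pipeline stages
  derive their seeds from one master seed by SHA-256 stage-name hashing, so
  adding a stage never shifts another stage's stream, and every artifact is
  regenerable from config + master seed alone.
* Prediction CSVs are written with 17-significant-digit floats and read with
  round-trip parsing, so serialized predictions compare bit-for-bit.
* AUC uses the rank-based (Mann–Whitney) formulation with tie correction via
  scikit-learn; per-pass mode ranks by each pass's own probabilities and
  reports mean ± SD across passes (SD is exactly 0 when dropout is disabled).
* Reports print percentages to one decimal; underlying values keep full
  precision.
* Known limitations: the numpy engine is single-threaded-deterministic but
  not fast enough for clinical-resolution ResNet34 training; frozen test sets
  replay perturbations from logged specs rather than storing mask pixels;
  the boundary-noise operator assumes a single closed contour per structure.
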
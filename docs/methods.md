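# Methods

This note documents the models, procedures, parameter choices and known
limitations of `catrace`, in the order the pipeline runs.

## Synthetic cocultures

The generator emulates a 1:1 coculture of antigen-specific and
nonspecific naive CD8⁺ T cells imaged with a ratiometric calcium dye
every 30 s for 2 h (241 frames). Each cell draws a genotype
(`frac_specific`, default 0.5) and a reactivity flag: 68.4% of specific
cells and 4.11% of nonspecific cells show a calcium event — the rates
reported for human majority-vote labelling of the real cocultures the
design mirrors. Reactive specific cells jump at a uniform random onset
(within the first 75% of the movie, so late activators still leave a
classifiable post-onset segment) to a sustained oscillating plateau:
fold-change amplitude 3.0 in the strong-agonist ("OVA-like") condition
and 1.8 in the weak-agonist ("gp33-like") condition, oscillating between
the full amplitude and (1 − depth) of it with depth 0.3 and period 40
frames (20 min). Reactive nonspecific cells show a square transient of
intermediate amplitude 1.8 lasting 20 frames — the population that makes
false discoveries likely. No quantitative waveform measurements exist to
fit, so these are the simplest piecewise forms with the right qualitative
structure; a per-cell amplitude jitter (`amplitude_cv` = 0.15,
floor-clipped) reflects the broad amplitude distributions real responses
show and keeps the classification task from collapsing to a single
amplitude cut. Gaussian noise (`noise_sd` = 0.08 ratio a.u.) is added
throughout and traces are clamped positive.

Motility is an isotropic random walk with Rayleigh step lengths (mean
`speed_free` = 3 px/frame) reflected at the FOV walls; the light Rayleigh
tail is what makes frame-to-frame linking well-posed at 30 s cadence.
From calcium onset, step lengths shrink by `arrest_factor` = 0.25
(migration arrest). When movies are to be rendered, an excluded-volume
relaxation keeps cell centres ≥ 12 px apart — T cells do not
interpenetrate, and overlap-free disks make the rendering round trip
exact; the relaxation introduces small extra frame-to-frame
displacements, which is why the linking correctness check runs on
dedicated capped-step walks (below).

Each experiment "day" draws one multiplicative baseline scale
(CV `day_scale_cv` = 0.15, truncated at 0.2) applied to the resting
ratio — exactly the inter-experiment drift that fold-change
normalization is meant to remove. Condition tags cycle across FOVs and a
vital-dye (CTFR) orientation tag alternates, so either population can
carry the stain. Four simulated evaluators vote on each cell's
reactivity, flipping the true flag independently with probability 0.05;
the majority vote is the "manual" ground truth. All randomness flows
from a single seed; identical configurations are bit-identical.

Rendering draws each cell as a uniform disk (diameter 10 px): the 447 nm
channel carries a per-cell brightness (200 ± 10% a.u.), the 405 nm
channel that brightness times the trace value, plus constant background
(20) and Gaussian read noise (SD 2). The CTFR channel is sampled at 12
evenly spaced frames. What the generator does *not* emulate: cell shape
and brightness dynamics, photobleaching, uneven illumination, focus
drift, APC objects, and contact-driven waveform structure. Passing the
round trip therefore shows the analysis code is correct on its stated
model, not that it is robust to every microscope artifact.

## Imaging

Segmentation of each frame's summed two-channel image: Gaussian
smoothing (σ 1.5), Sobel gradient-magnitude edge map, Otsu foreground
threshold, distance-transform peaks (min separation 5 px) as markers,
watershed on the edge map; objects outside 20–400 px² are rejected.
Tracking is greedy mutual-nearest-neighbour linking between consecutive
frames with an 8 px default gate, distance-sorted with ties broken by
track index; unmatched detections start tracks, unmatched tracks end (no
gap closing). Tracks shorter than ⌈n_frames/2⌉ are dropped, which also
guarantees one track per cell per movie. Traces integrate each channel
over a disk of 60% of the cell diameter; the local background is the
per-channel median over a 1.1–1.6 cell-radius annulus excluding other
cells' (1.2× inflated) disks; the ratio uses per-pixel means after
background subtraction. Frames whose 447 nm denominator falls below
1e-3 are flagged and linearly imputed from clean neighbours; traces with
more than 10% flagged frames are marked unusable. Genotype calls vote
over the sparse CTFR samples: positive if ≥ 8 samples exceed the
threshold (two-class Otsu on pooled per-cell intensities by default),
negative if ≥ 8 fall below, otherwise unassigned. Coordinates are
0-based, (x, y) = (column, row).

## Normalization

Per FOV, a two-component Gaussian mixture (EM: means initialized at the
25th/90th percentiles, equal weights, tol 1e-6, ≤ 500 iterations) is
fitted to the pooled per-time-point ratios; components are ordered so
μ_lo < μ_hi and every trace is divided by μ_lo. The fit is declared
degenerate — and replaced by a histogram-mode estimate of μ_lo with
μ_hi undefined — when the means sit within 5% of each other, when their
separation is below 1.5× the wider component σ (EM splits a unimodal
sample into two heavily overlapping halves about 0.6 σ apart, which the
5% rule alone cannot catch), or when a weight drops below 0.01.
Normalization is per FOV; per-day pooling would be a reasonable
alternative and is flagged for sensitivity analysis, but per-time-lapse
fitting matches how the mixture is described.

## Augmentation and set assembly

Augmented variants of a trace apply, independently per repeat: an
integer shift in ±`max_shift_frames` (edges padded with the trace's own
baseline median — the median of the lower half of its sorted values,
which stays on the resting level even when the cell is elevated most of
the movie), an amplitude scale drawn uniformly from
`amplitude_scale_range` applied to the deviation from that baseline
(so the resting level never moves), and Gaussian noise. For
acceptance-scale CNN training the pipeline uses 2 repeats, noise 0.05,
shifts ±30 frames and scales 0.4–1.2: scaling teaches amplitude
invariance, which is what lets a strong-agonist-trained network
generalize to the weak-agonist condition.

Training/evaluation splits are by whole FOV, never by cell; the training
split is restricted to the strong-agonist condition while evaluation
keeps the held-out strong-agonist FOVs plus every weak-agonist FOV.
Classes are down-sampled to equal counts (the evaluation split can
optionally stay unbalanced for per-FOV metrics), CTFR orientations are
balanced at the FOV level in training, and traces are padded to the
fixed length with their baseline median. Ground-truth modes: `manual`
(majority vote; ties resolve to nonreactive — the conservative choice
that keeps false "reactive" ground truth out), `genotype`, and
`combined` (specific AND manually reactive versus the rest).

## Classifiers

The dual-threshold rule calls a cell antigen-specific iff its time above
θ_Ca strictly exceeds θ_t. Fitting scans the full (θ_Ca, θ_t) grid
(defaults 1.0–3.0 fold in 0.1 steps × 0–3600 s in 120 s steps) and keeps
the pair maximizing the weighted performance metric on the training
FOVs; ties resolve to the smaller θ_Ca, then the larger θ_t, making the
result independent of grid iteration order. During fitting, undefined
per-FOV metrics count as zero so degenerate inputs still select the
documented pair. Boundary rules: dwell time uses strict `>`; the CNN's
probability call uses `≥`.

The CNN is implemented directly in numpy (conv → ReLU → max-pool 2 →
conv → ReLU → global average pool → dense → softmax) with hand-written
backpropagation, verified against finite differences in the test suite.
Hyperparameters exposed to grid search are the four that matter at this
scale: filters {8, 16, 32, 64}, odd kernel {5, 11, 21, 41}, optimizer
{adam, sgd, rmsprop}, mini-batch {32, 64, 128}; defaults are 16 filters,
kernel 11, Adam at 1e-3, batch 64, 12–15 epochs. "Number of neurons" is
interpreted as convolution filters. Inputs are standardized per channel
with training-set statistics stored on the model. Training is
single-threaded and seeded; identical seeds give bit-identical
parameters. A non-finite loss aborts with diagnostics rather than
continuing.

The probability cutoff defaults to 0.47. Because the performance metric
weighs FDR five-fold, re-selecting the cutoff by maximizing pM on the
training FOVs typically lands near 0.9–0.97 on synthetic data: the
nonspecific transient cells — labelled reactive by the simulated
evaluators and therefore learned as positives — receive intermediate
probabilities, and a strict cutoff removes them at a small efficiency
cost. Re-selection on new data is recommended whenever the
efficiency/FDR trade-off matters.

## Evaluation

Model efficiency counts reactive-labelled specific cells recovered;
overall efficiency counts all specific cells recovered; FDR divides
nonspecific positive calls by all positive calls by default, with the
alternative denominator (all reactive-labelled cells) selectable. The
weighted metric pM = 1/√(w_eff Σ(1−eff)² + w_FDR Σ FDR²) uses each
condition's own FDR by default; a strict-literal mode repeats the first
condition's FDR in both terms. Undefined metrics (zero denominators)
propagate as NaN with their counts attached and are skipped, with a
logged count, in condition means; condition means weight FOVs equally.
ROC curves come from the threshold sweep with trapezoidal AUC, which
equals pairwise concordance with ties counted ½. Calcium onset is the
first run of ≥ 3 frames above the fold-change midpoint
(μ_lo + μ_hi)/(2 μ_lo); the run length and midpoint are package choices,
as no spike definition is published. Speed profiles aligned to onset
report per-offset means and counts.

## Benchmark protocol and problem sizes

The standard benchmark (`pipeline.run_study`) simulates 30 FOVs × 200
cells over 4 days with every fifth FOV weak-agonist, yielding ≈ 2300
balanced training and 2400 evaluation cells. The headline CNN is trained
on normalized, augmented manual-label data with a pM-selected cutoff.
The classifier ranking compares it against the dual-threshold rule
fitted on raw traces — the form in which that approach is defined —
because once both classifiers see fold-change-normalized synthetic
traces the task saturates for both (dwell time is a near-sufficient
statistic for the piecewise waveforms) and the comparison degenerates to
a coin flip at the ceiling; the normalized threshold variant is also
computed and reported. The imaging round trip renders 20 FOVs × 50 cells
at 61 frames on 400×400 px images; its linking-correctness check runs on
dedicated random walks with steps strictly below half the gate and
grid-separated starts, the regime in which greedy nearest-neighbour
assignment is provably unambiguous. These sizes were chosen as the
smallest at which the binomial noise on the reported fractions is well
below the margins being checked.

## Known limitations

* The CNN topology is a fixed two-block template; the published approach
  it mirrors did not release its architecture or weights, so no claim of
  architectural equivalence is made.
* Synthetic waveforms are piecewise caricatures; performance numbers on
  them bound nothing about real microscope data.
* The tracker has no gap closing and no occlusion handling; dense fields
  beyond the generator's default density will fragment tracks.
* A single-run permuted-label control is bimodal on cleanly separable
  synthetic clusters (the network classifies by cluster, sign set by the
  chance label imbalance); chance behaviour holds in expectation and is
  tested as an average over permutation replicates.
* Hypothesis testing between biological groups is out of scope; the
  package reports metrics, not p-values.
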
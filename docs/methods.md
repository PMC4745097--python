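# Methods

This note documents the models, defaults, and numerical choices behind
`widecal`, and what the synthetic-data validation does and does not show.

## Imaging model and simulator

The simulator (`widecal.synth`) emulates a single-photon wide-field recording
of a densely packed pyramidal layer.  Per frame *t*:

```
frame(t) = quantize16( illum(x,y) · bleach(t) ·
             shift[ B + Σ_c (F0·p_c + A·a_c(t)·p_c) , motion(t) ]
             + shot + read noise )
```

* **Somata** — `n_cells` centres rejection-sampled with pairwise separation
  ≥ 2·r + 2 px (r = `soma_radius`, default 5.7 px ≈ 15 µm diameter at
  1.312 µm/px) and painted with a soft radial profile `p(ρ) = 1/(1+ρ⁶)`.
  Resting intensities: tissue background 1000 counts, cell F0 +300 counts,
  transient amplitude A = 400 counts — a ~30–40% ΔF/F event on a 16-bit
  sensor, comfortably inside the dynamic range.
* **Transients** — impulse response `k(t) = (1 − e^(−t/τr))·e^(−t/τd)` with
  τr = 45 ms, τd = 400 ms (literature-typical GCaMP6f kinetics; both
  configurable).  Its closed-form peak time is `τr·ln(1 + τd/τr) ≈ 103 ms`.
* **Event rates** — spontaneous events are a homogeneous Poisson process at
  `background_rate` = 0.3 events/s per cell.  The value sits in the realistic
  range for task-active CA1 GCaMP6f transients and was fixed prospectively by
  a power calculation: for a negatively modulated cell (rate ×0.1 for the 2 s
  post-tone window), the paired t statistic over 33 correct trials scales as
  ≈ 7·√rate, so 0.3 events/s yields ≈ 95% detection power at α = 0.05 while
  0.05 events/s would leave the suppression badly underpowered.  Positively
  modulated cells receive one extra event with probability `p_on` = 0.9
  uniformly inside the 600 ms tone–puff window on each correct trial.
  Default label mix: 20% positive, 25% negative (the regime reported for
  this preparation).
* **Motion** — per-axis sinusoid at 2.5 Hz with amplitude 0.8 px plus rare
  biphasic two-frame jumps (`jump_rate` = 0.01/s, 5 px).  At 20 Hz sampling
  this produces ≈1 µm/frame frame-to-frame displacement, the physiological
  respiratory scale.
* **Illumination / bleaching / noise** — static quadratic vignette (corner
  attenuation `illum_amplitude` = 0.2 around a slightly off-centre optical
  axis); exponential whole-field decay to `bleach_end_fraction` = 0.933 at
  the last frame (a 6.7% session loss); Gaussian read noise (σ = 15 counts)
  plus a Gaussian shot-noise approximation with variance equal to the signal.
* **Behavior** — 40 tone–puff trials, ITI uniform in [31, 36] s; 350 ms tone,
  250 ms trace interval, 100 ms puff (puff onset 600 ms after tone onset);
  33/40 trials planted correct.  The eyelid-reflection trace gets an
  anticipatory deflection (10× baseline SD) starting 50–300 ms after tone
  onset on correct trials and a reflexive post-puff blink on every trial.
* **Randomness** — one seed feeds independent `SeedSequence` sub-streams
  (placement, events, motion, noise, schedule, labels, outcomes, eyelid), so
  changing one component's parameters never perturbs the others, and
  identical parameters reproduce movies bit-exactly.

Deliberately not modeled: optical PSF, z-defocus, non-rigid deformation,
neuropil contamination, vascular artifacts, and overlapping somata.  Passing
recovery tests on this simulator therefore demonstrates the pipeline's
arithmetic and its behaviour under rigid motion, vignetting, bleaching and
sensor noise — not robustness to dense overlap or non-rigid tissue, which
real recordings add.

The default simulated session is 512×512 px × 2000 frames with 50 cells: the
same pixel pitch as a full 1024×1024 session (so every size threshold
transfers unchanged) at a problem size a desk machine processes in minutes.
Trial-level analyses that need the full 40-trial, ~25-minute session use the
simulator's trace-level renderer (`render_traces`), which produces the same
per-cell traces mean-over-mask extraction would yield, without rendering a
half-hour movie.

## Preprocessing

**Homomorphic enhancement.**  Illumination is multiplicative, so the frame
is high-passed in the log domain: `y = exp(L − G_σ(L) + mean(G_σ(L))) − 1`
with `L = log(1+x)`.  The Gaussian low-pass uses an FFT on a reflect-padded
frame (padding 4σ), making σ = 32 px (≈ 42 µm, well above the ~11 px soma)
affordable per frame.  Mean brightness is approximately preserved and the
output is clamped nonnegative.

**Phase correlation.**  The cross-power spectrum is normalized by its
magnitude (`R = F(m)·conj(F(t)) / (|·| + ε)`, ε = 1e−12 of the peak
magnitude); a config switch selects normalization by the template power
spectrum instead.  Before the FFT both frames are mean-subtracted and
tapered with a Tukey window (fraction 0.25): the boundary-padded enhancement
leaves static frame-border residue that would otherwise pin a spurious
correlation peak at zero shift.  The integer peak is wrapped to a signed
shift, clamped to `max_shift` (default 25 px), with exact ties broken toward
the smallest |shift|.

**Subpixel refinement.**  Two methods are provided.  The separable 3-point
parabolic fit is cheap but systematically under-recovers fractional shifts
on the near-delta peaks phase correlation produces (~40% of the fractional
part in our measurements), which is why the default is a local upsampled-DFT
search: the inverse DFT of the normalized spectrum is evaluated directly on
a ±1 px grid at 1/20 px spacing around the integer peak.  Because the edge
taper also attenuates fractional estimates, the estimator runs two residual
re-estimation passes (shift the moving frame by the current estimate,
re-measure); the residuals contract geometrically.  On a noise-free movie
with known sinusoidal + jump motion the recovered per-frame shifts have
RMSE ≈ 0.12 px.

**Template.**  The registration reference is a running mean of previously
corrected enhanced frames with effective window `min(n, 50)`, seeded with
frame 0; a second mode blends it 50/50 with a fixed mean of evenly sampled,
sequentially pre-aligned frames (for chunk-parallel processing).

## Detection and merging

Per-pixel z-scores use full-session two-pass statistics (population SD;
zero-SD pixels get z = 0, flagged rather than ±∞).  The threshold starts at
1.5 SD and moves in 0.25 SD steps within [1.0, 6.0] until the active-pixel
fraction enters [0.0005, 0.01] (chosen as ≈ 500–10⁴ px on a 1024² frame; the
adjustment exists to keep residual-motion border artifacts from flooding a
frame).  If raising and lowering would alternate, the loop keeps the sparser
side, which guarantees termination with fraction ≤ hi or threshold at a
bound.  Binary cleanup is closing-then-opening; at radius 1 the structuring
element is the full 3×3 square (Chebyshev ball) so compact convex components
survive opening unchanged, larger radii use a Euclidean disk.  Components
are 8-connected and size-gated to [30, 300] px around the ~103 px soma.

Clustering joins a single-frame ROI to the most centroid-proximal existing
cluster that passes both gates (centroid distance ≤ 8 px AND both bbox
corners within 12 px; area prefilter: neighbouring doubling buckets only),
processing in frame order for determinism.  Large frames are pre-grouped
into 128 px blocks overlapping by 32 px (an ROI joins every block containing
its centroid).  A redundancy pass then single-links clusters that share
members or whose summaries pass the similarity gate — this both removes
block-overlap duplicates and re-joins clusters split by detection jitter,
and makes blocked and unblocked clustering provably coincide on all tested
instances.  The final mask keeps pixels present in ≥ 25% of contributing
frames; clusters seen in < 5 frames are dropped.  The overlap filter then
greedily removes, from the worst-overlapping pair (mask IoU > 0.3), the
member with fewer appearances (ties: smaller area, then larger id) — an
algorithmic surrogate for manual curation of overlapping detections.

## Traces and quality

Traces are extracted from the native-depth corrected movie (the 8-bit
percentile-clipped copy exists for storage/visualization; its 1%/99% clip
points are computed over the pooled pixel×time distribution, exactly via a
counting sort for integer movies).  Normalization: `Δf = (f − f_avg)/f_avg`
with the whole-session mean as `f_avg`, then one positive rescale so
`max(Δf) = 100` exactly; negative excursions scale by the same factor, and a
constant trace maps to all-zero.  SNR divides each ROI's raw trace maximum
by the mean temporal SD of all non-ROI pixels; by construction this is
linear in the signal at fixed noise and invariant to rescaling the whole
recording.  Photobleaching is the percent drop of the whole-field mean from
the first to the last frame (optionally averaging k frames at each end).

## Statistics

* **Trial scoring** — threshold `μ_b + k·σ_b` from the 3 s pre-tone
  baseline, response window [tone, tone+600 ms), k = 4 by default.  The
  exact multiplier used in the original protocol is not recoverable, so k is
  a config parameter and conclusions should not hinge on its default.
  Windows are half-open at sample resolution (12 response samples at 20 Hz).
* **Modulation** — rectangle-rule AUC of Δf in [−2, 0) vs [0, 2) s around
  tone onset; paired two-sided t-test over correct trials only; α = 0.05
  per ROI with no multiple-testing correction by default (a
  Benjamini–Hochberg option exists).  Zero-variance nonzero differences are
  flagged and treated as significant; all-zero differences are "none".
* **Latency** — first maximum of the correct-trial-averaged response within
  [0, 8] s, at frame resolution; exact ties take the earliest sample.
* **Spatial resampling** — the null draws |subset| ROIs without replacement
  from the population, 500 times.  The default tail counts null medians ≥
  the observed value (subset sparser than chance): for an observed median
  *above* the null mean, counting *lower* values would produce p ≈ 1, so the
  upper tail is the one consistent with using the statistic to detect
  sparseness; the literal lower-tail count is available via `tail="lower"`.
  No +1 smoothing; p = 0 is reported as "< 1/n_resamples".
* **Rank-sum** — midranks, tie-corrected variance, no continuity correction
  (this convention reproduces z = 2.97 ⇒ p = 0.003 arithmetic exactly).  At
  n ≤ 8 the exact permutation distribution is discrete in ~0.1 steps, so the
  normal approximation is only expected to track it in the tail; tests
  assert tail agreement plus 1e−10 agreement with an independent
  tie-corrected reference implementation.

## Determinism and sizes

Every stage is a pure function of its inputs and config; the pipeline
manifest contains no wall-clock data and reproduces bit-exactly under a
fixed seed.  Problem sizes used in validation: registration recovery on a
128×128 × 100-frame noise-free movie; detection/merging recovery on the
default 512×512 × 2000-frame, 50-cell session; modulation recovery on a
200-cell, 40-trial trace-level session; type-I calibration on 1000 null
ROIs × 33 trials.  These sizes keep the full validation in the minutes range
on one CPU while preserving the field's native per-pixel and per-cell
scales.

## Known limitations

Rigid translation only (no rotation, scaling, non-rigid warp, or z-motion);
no demixing of spatially overlapping, temporally coincident cells — the
overlap filter drops redundant ROIs rather than separating sources; trial
analyses assume the movie (or trace rendering) covers each trial's full
analysis window, and truncated trials are excluded with a warning; the SNR
convention depends on the detected ROI set (noise pixels are "everything not
in an ROI"), so it is comparable only across runs with similar coverage.
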
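# Methods

## Noise model and the measurement pipeline

A CT region of interest is modeled as a smooth underlying signal plus
stationary stochastic noise. Because no noise-free reference exists, noise is
isolated spectrally: a Gaussian lowpass copy (default `lp_sigma = 2` px,
truncated at 4 σ, mask-aware renormalization so out-of-ROI pixels contribute
nothing) is subtracted from the original. The residual is mapped with a
local sample-STD filter (circular window, default radius 3 px, ddof = 1,
defined only where the complete window lies inside the ROI).

The subtraction attenuates the noise itself: white noise of STD σ leaves a
residual of STD σ·a with `a = ||δ − g||₂` computed from the discrete kernel
`g` (a ≈ 0.970 at the defaults). For noise pre-correlated with a Gaussian of
width c (and rescaled back to STD σ), `a(c) = ||(δ − g) ⋆ h||₂ / ||h||₂`
with `h` the correlation kernel (a ≈ 0.549 at c = 1.5 px).
`ctiq.image.highpass_attenuation` computes both.

**STDmin.** The minimum-noise estimate is the mean of the five lowest mean
noise-map values over circles of 12 px diameter, placed densely at every
pixel whose circle fits inside the region and the defined noise map (ties
broken by (score, row, col) order, so the estimate is deterministic). Taking
a low order statistic makes the estimate robust to anatomy that leaks into
the highpass band (edges, texture), at the cost of a multiplicative bias
`b = STDmin / (σ·a) < 1`. `b` is measured once on the default phantom suite
(`scripts/calibrate.py`) and stored in `src/ctiq/data/calibration.json`:
b ≈ 0.814 for white noise and ≈ 0.508 at correlation 1.5 px (correlated
fields both depress the windowed sample STD — fewer effective degrees of
freedom per window — and fluctuate more between circles, deepening the
minimum). `b` is scale-invariant in σ, which is what makes STDmin linear
in σ.

**Modal SI.** Signal intensity is read off the bin-width-20 histogram of the
tissue, anchored at the in-mask minimum (anchoring makes every metric exactly
invariant under constant intensity offsets). The mode is located by
grouped-data interpolation, `L + h·(f₁−f₀)/(2f₁−f₀−f₂)`, and refined as the
mean of the values within half a bin width of that location. The refinement
matters: the raw "mean of the modal bin" is biased by up to ~0.46 σ whenever
a bin edge falls near the peak, whereas a window centered *on* the peak trims
symmetrically, leaving a bias that is second order in the interpolation
error. For constant or single-bin tissues the mean of the modal bin is
returned directly. Ties for the modal bin go to the bin whose lower edge is
nearest the overall mean.

**Two-tissue split.** The ROI histogram's two most populated bins at least
two bin widths apart are the candidate modes; the split threshold is the
center of the least-populated bin between them (midpoint of the mode centers
if the valley is tied). A valley strictly below both modes is required —
otherwise the ROI is treated as one tissue (a unimodal ROI never silently
yields a two-tissue result). In the assembled pipeline (`assess_roi`) the
split is computed on the *lowpass* copy: the valley of the raw histogram
fills in at high noise (at σ = 40 on a 100-HU contrast, ~11 % of pixels cross
the threshold, leaving speckled masks with no room for the 12-px circles),
while the lowpass copy suppresses noise by a factor ≈ 7 at the defaults and
leaves the masks clean. SI, entropy and sharpness are always measured on the
original image; `split_two_tissues` itself can be applied to any image.

**SNR / CNR.** SNR = SI / STDmin per tissue; CNR = ΔSI divided by the mean
of both tissues' STDmin, with tissues ordered so ΔSI ≥ 0. A zero STDmin
raises an error rather than returning infinity — an infinite SNR is never
meaningful downstream.

**Entropy.** Shannon entropy (base 2) of the normalized bin-width-20
histogram; empty bins contribute zero.

**Edge sharpness.** The quantity is the 10–90 % intensity transition
distance across the tissue interface. Intensity profiles are sampled (bilinear,
0.25-px steps, ±8 px) along boundary normals taken from the gradient of a
smoothed tissue indicator, aligned at their half-height crossings, averaged
(≤ 200 profiles), and fit with an error-function edge model; the width is
2.5631·σ_fit in pixel-spacing units. This is the standard edge-spread-function
convention — the quantity's operational definition here, flagged because other
conventions (e.g. MTF50) exist. An ideal step measures ≤ 1.2 px
(sampling-limited); a boundary shorter than 8 px raises an error.

## Phantom generator

`PhantomSpec` describes one or two flat plateaus (vertical step or centered
disk), Gaussian boundary blur, and additive Gaussian noise with optional
Gaussian spatial correlation. Noise is rescaled *after* correlation filtering
so the realized sample STD equals `noise_sigma` exactly, making recovery
tests sharp; the realized value is recorded. Tissue masks exclude the
boundary band (noiseless value > 1 % of ΔSI away from both plateaus), keeping
per-tissue truth unambiguous under blur. Intensities are floating point by
default, with a `quantize` switch to mimic integer HU images.

The default fixture suite is the full grid σ ∈ {0, 5, 10, 20, 40} HU ×
correlation ∈ {0, 1.5} px × blur ∈ {0, 1, 2} px on 256×256 50/150-HU step
phantoms (30 phantoms, deterministic per-spec seeds). These sizes keep a full
suite assessment to a few seconds while leaving ~30 000 pixels per tissue —
enough that histogram-mode and order-statistic estimates are dominated by
their systematic behaviour, not sample noise.

What the phantoms deliberately do **not** emulate: anatomical texture,
reconstruction-physics artifacts (streaks, beam hardening), non-stationary
noise, or the vendor's iterative/deep-learning reconstructions themselves —
reconstruction algorithms appear only as different noise/blur levels.
Passing recovery tests therefore shows the estimators are correct under the
model's assumptions, not that those assumptions exhaust real patient images.

## Estimator behaviour worth knowing

- STDmin is strictly increasing and linear in σ on the fixture suite; the
  ratio STDmin/σ (pooled over blur levels, which do not enter the noise
  model) varies by < 10 % per correlation level. A *single* σ-scan at one
  (correlation, blur) setting can spread noticeably more for correlated noise
  (up to ~18 % observed) — pure sampling variance of the five-lowest order
  statistic when the region holds few independent correlation patches, not a
  bias.
- Modal SI recovers plateau levels within ~2 HU up to σ = 20 on the suite.
- CNR matches the prediction ΔSI/(σ·a·b) within 15 % across the whole grid.
- SNR/CNR are strictly decreasing in σ on matched phantoms.

## Dose module

Pure arithmetic with the units fixed above, plus cohort reporting: per-
protocol mean ± SD of CTDIvol/DLP/effective dose (effective dose rounded to
2 decimals, percent reductions to 1 decimal; full precision kept
internally), and a flag for records whose recorded kV disagrees with the
weight-adapted rule. With a fixed scan length, SD(DLP) = L·SD(CTDIvol)
follows automatically from per-record propagation. Missing scan lengths
default to 25 cm with a logged notice. `k` is a user parameter, not a dose-
physics model; no SSDE or organ-dose simulation is attempted.

## Agreement module

Gwet's AC₂ in its multi-rater, weighted form: weighted observed agreement
over all rater pairs within an item, chance agreement
`Pe = T_w/(q(q−1)) · Σ πₖ(1−πₖ)` from overall category propensities, variance
by Gwet's item-level linearization, CI = estimate ± 1.96·SE truncated to
[−1, 1]. Linear ordinal weights are the default (the natural choice for an
ordinal scale when no weight family is stated); quadratic and identity
weights are available — with identity weights the estimator is exactly AC₁.
Missing cells are handled by pairwise deletion within items. If a single
category is used throughout, Pe = 0 and the coefficient is 1 by convention,
with a degenerate-variance note on the result. The CI construction is a
normal approximation — an interpretation, since published tables rarely state
theirs.

## Degenerate inputs and numerical choices

- Coordinates are row/column, 0-based, pixel centers at integers; circle
  membership is center distance ≤ diameter/2 (inclusive).
- Histogram bins are half-open with the maximum value folded into the last
  bin.
- `std_filter` variance is clamped at 0 before the square root (guards
  catastrophic cancellation on near-constant residuals).
- Empty masks, ROIs smaller than one window, fewer than five candidate
  circles, sub-8-px boundaries, non-positive weights/doses each raise a
  specific exception type with an actionable message.
- The erf edge fit bounds σ to [10⁻³, 8] px and the center to the profile
  range; alignment uses the first half-height crossing nearest the nominal
  boundary.

## Known limitations

- Planar (2D) analysis only; no volumetric noise estimation.
- ROI placement is the user's: no automatic anatomy localization.
- The order-statistic factor `b` is calibrated at the default parameters
  (lp_sigma 2, window radius 3, 12-px circles, five lowest) and the fixture
  region size; changing those parameters calls for re-running
  `scripts/calibrate.py`.
- Ordinal-regression modeling of ratings (GEE/mixed models) is out of scope;
  the package exports tidy tables suitable for such modeling instead.
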
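# Methods

This note documents the models implemented by `synaptoflux`, the defaults
that matter, what the synthetic generators do and do not emulate, and the
numerical choices made where the underlying experimental protocols leave the
design open.

## Segmentation model

Background is estimated from rectangular cell-free regions — at least three
per field of view — whose pixels are pooled across FOVs (and, by default,
across treatment conditions) into a single mean and SD; the **common
threshold** for all images of a channel is `mean + 2·SD`. ROIs come from the
binary threshold mask split by marker-controlled watershed: markers are
local maxima of the lightly smoothed (σ = 1 px) intensity with a minimum
separation of 5 px, flooded on the inverted intensity with 8-connectivity.
Mask components without a detected peak keep a single label, so every mask
pixel receives exactly one label. Particles are kept when their
**area-equivalent diameter** `sqrt(4·A/π)` lies in 0.3–3 µm inclusive — the
size window of synaptic boutons (~1 µm). The diameter interpretation is a
deliberate choice: the size limits are stated as lengths and boutons are
quasi-circular, so an area-equivalent bound is the natural reading. The
filter is idempotent and never increases labeled area.

Per-ROI measurements subtract the pooled background mean from the ROI pixel
mean; negative net means are **not clamped** (channel-regression intercepts
can legitimately be negative). The clustering index is the population SD
(÷n) of the ROI's raw pixels — each punctum's pixels are a complete
population, not a sample — and is invariant to background subtraction, so
computing it before or after subtraction is immaterial.

## Generalized polarization

GP = (I_blue − G·I_green)/(I_blue + G·I_green). The sensitivity factor G is
calibrated on a reference solvent of known GP (dye in DMSO, GP = 0.006):
G = I_blue·(1 − GP_ref) / (I_green·(1 + GP_ref)). This makes calibration an
exact algebraic round trip (verified to 1e−12), and GP is invariant under
common positive scaling of both channels and strictly increasing in I_blue.
Pixels with non-positive denominator are flagged invalid (NaN), not raised
as errors. Pooled distributions keep every valid pixel per condition;
between-condition shifts are differences of pooled means with a two-sample
KS statistic. Histograms use 0.02-wide bins over [−1, 1] (an unstated
display choice in the source protocols; configurable).

## Quantal quantum-dot analysis

A bouton loaded with k quantum dots emits k times the unitary
photoluminescence, so the intensity sample across boutons is a mixture with
components at k·q. The unit q is estimated by maximum likelihood on
intensities histogrammed in 30 a.u. bins:

- each occupied bin center c is hard-assigned to its nearest multiple k·q
  (k = 1..K, default K = 10);
- the component spread is profiled as σ² = Σ n·(c − k·q)²/k / N — variance
  grows linearly with the number of independent quanta, so component k has
  SD √k·σ;
- component weights are the assigned count fractions, and the bin mass is
  the Normal-mixture CDF difference plus a fixed 1% uniform background
  component over the observed bins;
- mixture mass falling outside the observed range is **not** renormalized
  away: a candidate q that parks a component where there is no data pays
  for it in likelihood, which removes the exact q/m subharmonic degeneracy
  that quantal likelihoods otherwise have;
- candidates with an empty k = 1 component are rejected outright.

The objective is optimized by a coarse 5 a.u. grid over 100–800 a.u.
followed by bounded scalar refinement; the test suite cross-checks the
optimum against an independently coded exhaustive 1 a.u. grid search and
requires agreement within one grid step. The exact likelihood used in the
original quantal-analysis protocols is not restated in public methods, so
this mixture family is a declared design choice validated by the oracle and
by parameter recovery (q within 2% of 378 a.u. at n = 1000).

The quantal fit takes intensities *without* background subtraction in the
sense that no per-ROI offset is modeled inside the mixture; the camera
background enters upstream, through the single-Qdot cutoff
(background mean + 2·SD, near 3000 a.u. in the emulated Qdot channel) and
through background-subtracted totals for vesicle counting
(count = total/q, reported to one decimal: 8787/378 → 23.2,
11050/378 → 29.2).

Fusion events on smoothed (five-frame centered moving average, truncated at
edges) single-Qdot traces: a rise above the local pre-event baseline by
3·noise_SD sustained for at least one smoothed frame opens an event; after
the trace returns below threshold, the post-event baseline (mean of 5
frames after a 5-frame guard for smoothing smear) is compared with the
pre-event baseline. A drop within ±0.5·q of one unit is full-collapse
fusion; a drop within ±0.5·q of zero is fast-and-reversible fusion;
anything else is flagged unclassified, excluded from ratios and counted in
the log. The 3σ threshold and ±0.5·q tolerance are package choices (no
numeric thresholds are published for this classification); both are exposed
as parameters. The FRF ratio time course is cumulative FRF over cumulative
classified events per frame, with the end-of-run value averaged over the
last five frames.

## Kinetics

FM traces are normalized to the mean of their first 10 frames; destaining
extent is 1 minus the mean of the last five frames of the normalized trace.
The destaining rate uses a single-exponential-with-plateau model
`p + (1 − p)·exp(−r·(t − t_on))` fitted by least squares on the post-onset
segment — the source protocols compare rates without stating a model, and a
plateau-exponential is the standard minimal description of partial
destaining. Perfectly flat traces are reported as rate 0 (the rate/plateau
pair is otherwise unidentifiable there). Paired Ca²⁺ responses are the
ratio of the second to the first ΔF/F peak, each measured in a
configurable post-stimulus window (default 30 frames at 1 Hz) against the
immediately preceding baseline.

## Spectra and assay

Beer–Lambert transmittance is base-10, `T = 10^(−ε·c·l)` with ε in L/g/m
(default 2460, the graphene absorption coefficient at 660 nm), c converted
from mg/L to g/L and a 1 cm default cuvette path (a standard cuvette is
assumed; the path is configurable since only ε and concentration are
published). ε is treated as flat across the 500–650 nm emission band unless
a per-wavelength table is supplied — the attenuation is broadband — with
the printed 660 nm value as default.

The absorbance correction is applied verbatim as the additive form
`F' = F + (1 − T)·F = F·(2 − T)`. Note this is the first-order
approximation of the division-based correction `F/T`; the two agree to
O((1 − T)²) and diverge for strongly absorbing samples. The package
implements the published form and documents the discrepancy here.

Smoothing is a nine-point Savitzky–Golay filter (default quadratic).
Two-condition normalization maps, per wavelength, the 0 mg/L reference to 1
and the attenuated condition to 0, flagging zero-dynamic-range wavelengths.
Standard curves are OLS lines on the 0/2/5/10/15/20 µM serial dilution;
unknown concentrations invert the curve. The noise-free round trip
(generate → fit → invert) is exact for every standard.

## Synthetic data generation

The generators emulate the acquisition modes the pipeline analyzes, each
with a ground-truth table sufficient to score every downstream estimator,
and a determinism contract: identical spec + seed gives bitwise-identical
output. A master seed expands into per-generator child seeds via
`numpy.random.SeedSequence`.

**Bouton scenes.** Isotropic 2-D Gaussian spots (diameter = FWHM, drawn
from 0.8–1.2 µm) convolved in quadrature with a PSF σ of 0.15 µm, placed
without overlap (bounded retries; failure raises a generation error) on a
constant background with Gaussian read noise (optionally Poisson shot noise
first), clipped to the 16-bit range. Defaults are a 320×320 px FOV at
0.1 µm/px — 60×-objective EMCCD-style sampling — with background 100 ± 10
a.u., 40 boutons, and peak amplitude 2000 a.u. before condition scaling.
Spots are rendered with compact support truncated at 2.5σ. This truncation
matters: with unbounded Gaussian tails the thresholded ROI area grows like
log(amplitude), which systematically shrinks measured between-condition
intensity ratios (a programmed +27% measures as ~+20%); with a finite
footprint whose edge sits well above threshold for both conditions, the
threshold selects the same pixel set regardless of brightness and
programmed ratios survive segmentation unbiased. The finer default pixel
size also makes the minimum 0.3 µm particle area 8 px, so chance clusters
of supra-threshold noise pixels (inevitable at any mean + 2·SD threshold)
essentially never pass the size filter. Per-bouton brightness varies
uniformly by ±20%; between-condition effects multiply the amplitude, so the
ground-truth mean-intensity ratio between conditions sharing a scene seed
is exact.

**Destaining movies.** Bouton intensities are constant over the baseline
frames, then follow `p + (1 − p)·exp(−r·t)`. Programming two conditions
with plateaus p_A, p_B at a common rate gives noise-free total losses in
the exact ratio (1 − p_B)/(1 − p_A) — the decay factor cancels — so a +30%
loss effect is (0.5, 0.35).

**Qdot traces.** Piecewise-constant baselines at the sum of k sampled unit
intensities (378 ± 41 a.u.) plus per-frame Gaussian noise (20 a.u.),
acquired at 5 Hz. FRF events add a 200 a.u. transient for 5 frames and
restore the baseline; full-collapse events add the same transient and then
step the baseline down by one sampled unit. Negative intensities are
clipped at zero and flagged. Blinking is deliberately not simulated — the
analyses here do not use it. The transient amplitude and duration are spec
fields, not constants, because no published values pin them down.

**GP pairs.** Per-pixel true GP values are drawn from a truncated Normal
(reject-and-redraw within (−1, 1), keeping the statistic well defined);
channel intensities realize each value exactly at a fixed weighted total
before per-channel noise.

**Spectra, assay plates, paired intensities.** Gaussian emission peaks
attenuated by the Beer–Lambert transmittance; linear standard curves with
replicate noise; paired intensities `y = slope·x + intercept + ε` with
x ~ Normal. The default regression parameters are the graphene-group
channel relation (slope 1.2083, intercept −253.29 a.u.); the residual SD
(818.9 a.u. at x_sd = 600) is derived once from the published Pearson
r = 0.6629 via σ_ε = slope·σ_x·√(1/r² − 1), since no residual spread is
printed.

**What the generators do not emulate** — and hence what passing tests do
not establish about real data: optical aberrations and spatially varying
PSFs, uneven illumination and photobleaching, overlapping or out-of-focus
boutons, neurite autofluorescence (backgrounds are statistically uniform),
Qdot blinking, spectral bleed-through, and any biology beyond the
programmed effect sizes. Recovery results demonstrate that the pipeline's
estimators are unbiased and correctly calibrated under the stated imaging
model, not that the model captures every property of live-neuron data.

## Problem sizes

The validation suite and the acceptance script size their simulations to
the study's reported samples: ≥150 ROIs per condition for FM-load
comparisons (6 FOVs × 40 boutons), ≥139 for destaining (4 FOVs), ≥1000
puncta per condition for the Syp-style comparison (24 FOVs × 42), 6 FOVs of
128×128 px per condition for GP pooling, n = 1000 intensities for quantal
fits, and n = 2000 pairs for the channel regression. At these sizes the
whole acceptance run completes in well under a minute on one CPU.

## Known limitations

- The watershed marker strategy (smoothing σ, 5 px peak separation) suits
  diffraction-limited puncta at ~0.1 µm/px; heavily overlapping boutons or
  much coarser sampling would need retuned parameters.
- The quantal mixture assumes independent-quantum variance (SD ∝ √k) and a
  uniform outlier component; strongly skewed unit distributions would bias
  q.
- Fusion-event classification assumes events separated by more than the
  smoothing window plus the post-event guard; bursts of events closer than
  ~15 frames at 5 Hz merge or go unclassified.
- The additive absorbance correction under-corrects strongly absorbing
  samples relative to a division-based correction (see above).
- `sholl_counts` operates on polyline traces, the geometric analogue of
  manual intersection counting; it does not trace neurites from images.
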
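# Methods

This note documents the models, parameter defaults, numerical choices and
known limitations of `optolight`. Everything quantitative stated here is
computed by the test suite or by `scripts/acceptance.py`; nothing is quoted
from external data.

## 1. Irradiation conditions and the energy measure

An irradiation condition is (η, δ, τ): irradiance (W/cm²), irradiation time
per unit area per single irradiation (µs/pixel), and the interval between
irradiations (min). The energy delivered per unit area per unit time is
E ∝ η·δ/τ. The absolute unit of the published energy column of the built-in
condition table is not recoverable, so the package always reports the raw
rate η·δ/τ and, separately, predictions of the printed column through a
single multiplicative constant C (calibrated on one condition, or fitted to
all nine irradiated rows by least proportional error in log space). One
shared C reproduces every printed value to within ~1.5%; the residual is
consistent with rounding of the printed η values.

Pulse schedules start at t = 0 with pulses at 0, τ, 2τ, … on the half-open
interval [0, duration); the phase of the first pulse is a convention (the
published protocol does not state it). Schedules are pure functions of
(condition, duration).

## 2. The synthetic experiment

The generator emulates a monolayer of primary mesenchymal cells
co-transfected with plasmid P1 (transactivator + nuclear iRFP) and P2
(UAS-driven mCherry + constitutive EGFP). Defaults are the study
conditions; all randomness derives from one mandatory seed.

**Geometry.** One analysis region unit is 636.4 × 318.2 µm = 512 × 256 px
at 1.243 µm/px. One acquisition *field* is a camera frame holding one or
more disjoint regions; the standard layout pairs an irradiated region with
an unirradiated control in a single 512 × 512 px frame, as in the
experiment this emulates (the frames were 512 × 512 or 512 × 256 px and the
example images show the irradiated/unirradiated boundary inside one frame).
The pairing is also load-bearing for the measurement chain — see §4.

**Cells.** A homogeneous hard-disk point process (dart throwing on a
neighbour grid; default density 8000 cells/mm² ≈ 1 600 cells per region
unit, radius 3 ± 0.3 µm, shallow Gaussian Z spread over 3 planes of 2 µm
step). Densities that cannot be packed raise an error.

**Plasmid uptake.** Marginal uptake probabilities with a Gaussian-copula
"competence" coupling: per cell, two correlated standard normals are
thresholded at Φ⁻¹(p). `calibrate_uptake` solves for (p, ρ) from the two
published co-introduction summaries — absolute co-rate 0.18 and relative
co-rate 0.80 give p = 0.2025, ρ ≈ 0.98: cells competent for lipofection
usually take both plasmids. ρ = 0 recovers independent uptake (co-rate p²).

**Photoswitch.** One-variable pulse-increment/dark-reversion model: the
activity A ∈ [0, 1] jumps by min(1 − A, κ·η·δ) at each pulse and decays
exponentially with time constant T_off between pulses. Defaults
κ = 2.8 (W/cm²·µs/px)⁻¹ and T_off = 30 min; the dark-reversion timescale is
"tens of minutes" biology, and κ is set so that the per-pulse dose of the
reference conditions (η·δ = 0.176) half-saturates the switch. With these
defaults the time-averaged activity Ā over 24 h is 0.86 / 0.73 / 0.25 for
τ = 10 / 20 / 60 min at equal per-pulse dose — the mechanism of the
τ-dependence of induction.

**Induction and leak.** Each co-transfected cell carries a lognormal
activation threshold θ (median 0.645, shape 0.5) on Ā: the cell switches on
iff θ < Ā. This cooperative, switch-like gating (rather than a purely
graded accumulation) reflects dimer-mediated transactivation and is
deliberate: it makes per-cell expression essentially binary, so the
measured *area* ratio tracks the *count* ratio that the frequency model
describes. A purely graded model with a realized induction rate of 0.6
would put the median induced cell just at the detection threshold; such
cells cross it only near the end of the time-lapse and the time-averaged
area ratio then underestimates the count-based model severely. The
threshold median is placed so the reference condition (τ = 20) switches on
≈ 60% of co-transfected cells.

Switched-on cells accumulate mCherry toward a per-cell plateau
M ~ lognormal(320 a.u., 0.5) as M·(1 − exp(−k·∫A dt)) with
k = 0.0115 min⁻¹ and an onset delay of 90 min (the midpoint of the 1–2 h
reporter-maturation window). Leak expression occurs in a Bernoulli fraction
f_leak = 0.05 of co-transfected cells, rising from t = 0 with rate constant
1/240 min⁻¹ toward a plateau drawn from the *same* distribution as the
induced plateau (one promoter, one reporter). This identity matters: it
makes the fraction of cells exceeding any given image threshold equal in
both arms, so the measured area ratio is insensitive to the exact
binarization level. Traces are non-decreasing; no bleaching is modelled.

**Ground truth.** Per cell, the final mCherry is decomposed into its
light-driven and leak components; realized per-region rates are defined on
the components: f_induce = fraction of co-transfected cells whose light
component ends above the detection threshold (40 a.u.) — identically zero
in unirradiated regions — and f_leak likewise on the leak component.

**Endpoint channels.** The stain channel is β·(final mCherry) + Gaussian
noise (β = 2, SD 8) in reporter-coupled ("P2B") mode, or a constant level
(60 a.u.) in control ("P2A") mode. EdU positivity is Bernoulli (0.35) in
all cells, independent of irradiation.

**Rendering.** Counting channels (nuclei, iRFP, EGFP) are centrally peaked
Gaussian blobs (σ 1.5 µm) — the textured appearance that maxima-based
counting relies on; reporter, stain and EdU channels are flat disks of the
nucleus radius with a 1 µm soft edge — NLS-tagged proteins fill the
nucleus, so within-nucleus intensity is approximately constant. The
distinction is deliberate: with peaked profiles both stain and reporter
fade together radially and pixel pooling would fake a positive correlation
even for a flat stain. Camera noise is Poisson (gain 2 photons/a.u.) plus
Gaussian read noise (SD 2) on a background of 10 a.u. The structural
channels are snapshots at the first frame and the endpoint channels at the
last; only the reporter is monitored through time (as in the emulated
protocol, where the EGFP excitation line also activates the photoswitch).

## 3. Measurement chain

All operators are deterministic and 0-based/row-major; region rectangles in
µm convert to half-open pixel rectangles with edges rounded outward (and
clamped by at most one pixel where the frame's own grid rounding is
tighter). Filters use reflect boundary handling.

* **Counting** — Gaussian smoothing (σ = radius = 1 px) then h-maxima with
  prominence 15 a.u. (calibrated on the default fixture to ≥ 95% counting
  accuracy; recorded in the run manifest). The global maximum of a
  non-constant image always counts; plateaus count once at their centroid.
  Cross-channel detections are matched greedily by distance within 3 px.
* **Thresholding** — iterative intermeans (IsoData), the classical
  "default" auto-threshold: T ← round((mean ≤ T + mean > T)/2) iterated
  from the overall mean on a 256-bin histogram (exact per-integer bins for
  8-bit data). Rounding rather than flooring matters: a bright outlier
  compresses the background into two bins and the floored map has a
  spurious fixed point at the lowest bin. Foreground is strictly above the
  threshold; a constant image yields an empty mask with a warning. Otsu is
  available as an option.
* **Median filter** — majority vote on the discrete disk of radius 1.5 px,
  which is exactly the 9-pixel 3 × 3 box (stated explicitly because disk
  rasterization is a known dialect issue between implementations).
* **Area series** — per frame: maximum Z projection → histogram matching of
  the series to a reference frame (default: the final frame, the
  signal-richest one, so the threshold remains meaningful on early, nearly
  empty frames) → threshold → median filter → foreground pixels per region.

## 4. Dish-level protocol for the specificity

In a multi-field experiment all fields share one dish and one acquisition
setting, so `run_experiment` measures them jointly: histogram matching runs
*within* each field's own time series (its purpose is brightness drift over
time; matching across fields would force every frame to the same
suprathreshold pixel count and erase exactly the between-field signal
differences being measured), while a single IsoData threshold, computed on
the signal-richest frame of the whole experiment, is applied everywhere.
This anchors the binarization of weakly induced fields — a frame containing
only a handful of leak-positive cells has no bimodal histogram of its own,
and intermeans thresholding of such a frame collapses into the noise floor
(about a third of a control-only frame ends up classified as foreground).
Pairing an irradiated with a control region in the same frame serves the
same purpose at the field level.

The specificity Ŝ is the ratio of arm means of per-region *time averages*
(time first, then regions; the two orders differ when regions have unequal
frame counts, and this order is fixed and recorded). A zero control mean
flags Ŝ = ∞ rather than raising. Per-condition tables pool all control
regions of the dish into one shared control arm and report SD over regions.
For model inversion, f_leak is taken from the control arm's realized
(or measured) leak rate, never assumed.

## 5. Dose–response curves

Reporter-positive pixels are selected by the reporter image's own
auto-threshold, clusters smaller than 6 px (≈ 0.3 × the rendered median
nucleus area; the removal threshold is reproducible rather than visual) are
removed, and the surviving mask is eroded by 1.5 px to drop partial-volume
boundary pixels where both channels fade together. Pixels are binned by
reporter intensity (width 50 a.u., edges from 0, optionally a shared grid
across samples); per-bin mean/SD/count of the stain are reported, with
empty or single-pixel bins flagged rather than fabricated. The slope is a
pixel-count-weighted least-squares fit of bin means on bin centers with a
t-based 95% CI.

## 6. EdU fractions

Nuclei and EdU-positive cells are counted on the single Z plane with the
highest nucleus density (ties → lowest index). Per-arm fractions carry
Wilson binomial intervals; the arm difference carries a Wald interval. No
further hypothesis-testing machinery is attached.

## 7. Problem sizes and runtime

The end-to-end recovery experiment runs at study scale: six paired
512 × 512 px fields (≈ 19 000 cells), 24 frames at 60 min. The
τ-comparison uses a scaled layout — two paired fields per condition,
12 frames at 120 min, ten independent seeds — and the response analysis one
512 × 256 field; these sizes keep the full suite within a few minutes while
leaving the statistical margins comfortable.

## 8. What passing tests do and do not show

The generator reproduces the *structure* of the experiment — co-transfection
statistics, leak vs induced expression, pulse-train kinetics,
nucleus-filling reporters, camera noise — but not everything about real
data: no cell motility, division, bleaching, phototoxicity, illumination
drift, flat-field error or 3D tissue; per-cell intensity scales are
arbitrary units chosen for realistic SNR, not matched to recordings; the
light boundary between regions is sharp. Passing recovery tests therefore
shows the measurement chain is correct and internally consistent under
realistic noise, not that any particular biological magnitude is
reproduced. Known small biases, visible in the recovery numbers: the
reporter-onset delay makes the irradiated arm detectable slightly later
than the control arm, and blobs spill across the shared region boundary
into the control strip; together they bias Ŝ downward by ~5–10% at the
default geometry — well inside the recovery tolerances, and documented
rather than corrected because the emulated protocol measures adjacent
regions the same way.

Nucleus/EdU detection here is classical (smoothing + prominence maxima +
thresholding); the neural-network detector used in the original workflow
for its proliferation assay is deliberately replaced by this documented,
dependency-free substitute.
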
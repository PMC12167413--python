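# Methods

## The quantification problem

For a reversibly binding radioligand without a reference region, the
outcome measure is the total distribution volume V_T: the equilibrium
ratio of tissue tracer concentration to metabolite-corrected arterial
plasma concentration (mL/ccm). Everything in this package exists to
estimate V_T from dynamic PET data and to characterise how reliably it
can be estimated: which model describes the kinetics, how long the scan
must be, and how well V_T repeats between two scans of the same
subject on the same day.

## Models

**Compartment models.** The tissue is modelled as one (1TC) or two
(2TC) well-mixed compartments driven by the metabolite-corrected
plasma input Cp(t):

    1TC:  C1' = K1·Cp − k2·C1
    2TC:  C1' = K1·Cp − (k2 + k3)·C1 + k4·C2
          C2' = k3·C1 − k4·C2

with K1 (mL/ccm/min) the plasma-to-tissue delivery, k2 (1/min) the
efflux, and k3/k4 the exchange with the second (bound) compartment.
The measured signal adds a fractional blood-volume term:
C_model = (1 − vB)(C1 + C2) + vB·C_wb. V_T = K1/k2 for 1TC and
(K1/k2)(1 + k3/k4) for 2TC; this identity is stored exactly in every
fit record. k4 = 0 with k3 > 0 is handled as the irreversible limit
(prediction finite, V_T reported as infinite).

The tissue impulse response is a sum of at most two exponentials with
rates given by the eigenvalues of the 2TC system; the model curve is
that response convolved with the input. Because the input is stored as
samples on a fine grid and interpolated linearly, both the convolution
and its running time-integral have closed forms per grid segment
(evaluated with series-protected φ-functions for small k·Δt), so the
predicted *frame average* — the integral of the model over each frame
divided by its duration — is exact for the piecewise-linear input.
This matters for the 10-second early frames, where the curve changes
quickly and midpoint sampling would bias the fit.

**Graphical analyses.** Logan analysis regresses ∫C_T/C_T on
∫Cp/C_T over frames with midpoint ≥ t\*; the slope is V_T. MA1
rearranges the same relation into
C_T(t) = −(V_T/b)·∫Cp + (1/b)·∫C_T and estimates V_T = −β1/β2 by
multilinear regression, keeping the noisy measurement on the left-hand
side only. Tissue integrals are midpoint trapezoids anchored at
(0, 0) — frame data do not start at injection — and plasma integrals
are exact on the fine grid. t\* is selected by the "Max Err"
criterion: the earliest frame start such that no included point
deviates from the fitted line by more than a threshold (default 10%)
of its fitted value; the pipeline estimates t\* on a whole-brain TAC
and then fixes it for all regions and subjects.

**Model selection.** AIC = n·ln(RSS_w/n) + 2p on the weighted residual
sum of squares (lower is better) and MSC = ln(SS_tot,w/SS_res,w) −
2p/n (higher is better). Software packages differ in their exact AIC
variant; this one is the standard least-squares form and comparisons
are meaningful within the package only.

**Reliability.** Absolute test–retest variability
VAR = 200·|x₁ − x₂|/(x₁ + x₂) (scale-invariant, symmetric), and the
one-way random-effects ICC, (MS_B − MS_W)/(MS_B + (k−1)·MS_W), with a
95% CI from F-distribution bounds on MS_B/MS_W (the single-rater
one-way form; cross-checked against pingouin's ICC1 in the tests).
Time stability refits each model on truncated scans (33–93 min in
6-min steps, the late-frame length) and reports V_T relative to the
full 93-min estimate; the full-duration ratio is 100% by construction,
and truncations leaving fewer than 3 usable frames beyond t\* are
flagged missing rather than fitted.

## Input-function construction

The automatic sampler provides 1-s whole-blood data for the first
10 min; manual samples cover 2–90 min and are centrifuged for plasma.
The merge uses ABSS data up to its last sample and manual samples
after, with a single cross-calibration factor (ratio of means over the
overlapping samples in 2–10 min) applied to the ABSS segment; no
overlap raises a warning and skips rescaling. Beyond the last manual
sample the blood curve is extended by a single exponential fitted to
the last two samples (sampling stops at 90 min but the scan runs to
93). The plasma/whole-blood ratio is a piecewise-linear interpolant
with constant extrapolation. The parent fraction is fitted as
pf(t) = Σ cᵢ·exp(−μᵢ·t) with cᵢ, μᵢ ≥ 0 and Σcᵢ = 1 — the simplex
constraint anchors pf(0) = 1, which stabilises a 3-exponential fit on
~10 points — using deterministic multi-start least squares over a grid
of rate triplets (these fits are notoriously multimodal), with samples
beyond the configurable 45/60-min window excluded as too noisy. The
admissible parameter set makes the fitted curve monotone
non-increasing, so the extrapolation cannot invent late parent
recovery. The input is the product blood × ratio × pf on a fine grid
(1-s spacing to 10 min, 5-s after), clipped at zero.

No dispersion correction is applied (an optional global delay shift is
the only timing control): the simulator does not model dispersion, and
applying an uncharacterised correction would be guesswork. All values
are assumed decay-corrected, as is universal for quantitative PET.

## The synthetic-data generator

The generator emulates a six-subject test–retest study on a 38-frame,
93-min acquisition (9×10, 2×15, 3×20, 4×30, 4×60, 4×180, 12×360 s).
Defaults were chosen once to match the study conditions the package
targets:

* **Plasma input**: delayed Feng-type tri-exponential
  (A₁·t·e^{λ₁t}-style rise, eigenrates −4.5, −0.35, −0.022 /min,
  0.4 min delay). Amplitudes are set so the noiseless whole-brain
  peak SUV is ≈5.5 at the reference dose-per-weight, inside the
  4.3–6.3 range typical for high-uptake ¹¹C tracers.
* **Parent fraction**: weights (0.75, 0.20, 0.05), rates
  (0.28, 0.035, 0) /min, giving pf(20 min) ≈ 0.15 — rapid metabolism
  with a small slow/plateau component.
* **Regional kinetics**: 2TC parameters with V_T of 6.1 (pons), 5.5
  (thalamus), 5.3 (putamen), 4.0 (frontal cortex), 3.6 (cerebellum) —
  the subcortical > cortical rank order of mGlu4 — in a fast-exchange
  regime (k2 0.16–0.24, k3 ≈ 0.12, k4 ≈ 0.2 /min, K1 0.54–0.60
  mL/ccm/min). The fast exchange makes the slowest kinetic eigenvalue
  ≈ 0.08/min, consistent with the rapid washout and with graphical
  plots that are effectively linear from ~27 min (Max Err ≤ 10%);
  slow-exchange parameter sets (k4 ≈ 0.03) leave 2–5% linearization
  bias at that t\* and would contradict the reported behaviour the
  presets emulate.
* **Blood**: whole blood = total plasma / r(t) with r ≡ 1 by default
  (no measured ratio to emulate); vB = 0.05.
* **Variance components**: each micro-parameter gets an independent
  mean-one log-normal multiplier per subject (CV 20%) and per session
  (CV 3%). Note the per-parameter CVs compound: the implied
  between-subject V_T CV is ≈ 2× the per-parameter CV.
* **Noise**: zero-mean Gaussian per frame with
  SD = noise_scale·√(C(mid)/Δ) (count-statistics proxy;
  noise_scale 0.1 ≈ 2–5% per frame). Blood samples get 2%
  multiplicative noise, parent-fraction samples additive SD 0.02.
* **Demographics**: ages, BMI and injected activities of the
  six-subject reference cohort (mean injected 373 MBq, mean age
  23.2 y); body weights are back-computed from BMI assuming 1.70 m
  stature. Extra subjects beyond six are drawn log-normally.

All randomness derives from one master seed through spawned
per-subject/per-session streams, so studies are bit-reproducible.

Crucially, the simulator integrates the kinetic ODEs with LSODA
(rtol 1e-10, with an auxiliary integrated-activity state so frame
averages are exact to integrator tolerance), while the fitting code
uses the closed-form convolution — two independent numerical routes
that agree to <1e-5 % and therefore cross-validate each other.

**What the generator does not emulate**: scanner resolution and
partial-volume effects, motion, attenuation/reconstruction artefacts,
ABSS dispersion, the slow white-matter component, radioactive-decay
amplification of late-frame noise, and any model misspecification —
every simulated TAC is generated by the same 2TC family that is
fitted. Passing tests therefore demonstrate correctness and
self-consistency of the estimators under the stated noise model, not
performance on real data.

## Numerical choices

* Fit bounds: rates in [1e-6, 10] /min, vB in [0, 0.2]; deterministic
  multi-start grids (no randomness in any fit). The converged 1TC
  solution seeds a 2TC start with k3 → 0, which guarantees the
  nested-model inequality RSS(2TC) ≤ RSS(1TC).
* Weights: uniform by default; duration/activity weighting available.
  %SE of V_T comes from the Gauss–Newton covariance via the delta
  method; singular covariances report %SE as missing rather than
  failing the fit.
* Graphical fits exclude non-positive frames with a diagnostic;
  fewer than 3 usable points is an error.
* Degenerate inputs: coincident 2TC eigenvalues are nudged by 1e-12;
  exact zero residuals report MSC = +∞; zero total variance makes the
  ICC an undefined sentinel (NaN).
* File I/O uses 17-significant-digit decimal text and round-trip
  float parsing, so write→read is bit-lossless (the pipeline rerun
  check relies on it).

## Known limitations and honest negatives

* The blood-volume term is not modelled by Logan/MA1. With whole
  blood equal to total plasma and pf(late) ≈ 0.07, the late-scan blood
  signal is ~10% of the measured TAC at vB = 0.05, which depresses
  graphical V_T by ≈ 2% relative to the tissue truth. The graphical
  oracle tests therefore run on blood-free tissue curves; the vB
  effect appears instead in the graphical-vs-2TC agreement tables,
  where it belongs.
* Under every noise configuration tried, the regression-derived %SE
  of the Logan slope is *smaller* than MA1's, not larger: frame noise
  scales both Logan axes by the same 1/C_T factor, moving points along
  the fitted line, so the residual scatter understates the true
  uncertainty while the error re-emerges as the estimator's known
  downward pull (which MA1 resists — the paired ordering
  Logan < MA1 under heavy noise is reproduced and tested). Real data
  show the opposite %SE ordering, presumably through model misfit and
  input-function error that this generator deliberately does not
  include; the corresponding acceptance test records this as a failure
  rather than redefining the statistic.
* The auto-selected t\* on synthetic whole-brain data is ~8–12 min,
  earlier than the 27 min used as the fixed-policy default: synthetic
  plots are linear earlier than real ones because nothing in the
  generator curves them late (no dispersion, no misfit). Both the
  auto policy and the fixed 27-min policy are exposed.
* One-way ICC CIs with n = 6 subjects are wide (lower bounds can be
  near 0 even when ICC ≈ 0.95); that is a property of the design, not
  the estimator.
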
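# Methods

This note documents the models, estimators and numerical choices behind
`gazestab`, and what the synthetic cohort does and does not emulate.

## Signal model and sign conventions

All reflex fits work on slow-phase eye *velocity* against a signed
compensatory reference `r(t)`: −head velocity for vestibular rotations
(aVOR in dark, combined stimulation in light) and +drum velocity for the
optokinetic reflex.  Under this convention an ideal compensatory response
has gain 1 and phase 0 in every modality, which makes the phasor algebra
of the combined-response model well defined.

Phase is reported lead-positive in (−180°, 180°], tied to the dynamic lag
by `phase = −360·f·td/1000` (td in ms): a response lagging the reference
by 25 ms at 1 Hz has phase −9°; the lesion-induced phase leads appear as
positive phases.  An anti-compensatory response appears as a phase near
±180°, never as a negative gain — gains are non-negative by construction
(amplitude ratio of two phasors).

## Slow-phase extraction

*Differentiation.*  Central differences in the interior, one-sided at the
edges.  A zero-phase 4th-order Butterworth low-pass (default cutoff 30 Hz)
can be applied to position before differencing; it conditions the fitted
velocity series against tracker noise.

*Quick-phase detection.*  The raw (unfiltered) derivative is thresholded
at `max(50 deg/s, 2.5 × stimulus peak velocity)` and hits are dilated by
±20 ms.  Detection and position reconstruction deliberately use the
unfiltered derivative: an instantaneous resetting step is then confined to
two samples and excised exactly, whereas the zero-phase filter would smear
it past the margin and leak displacement into the rebuilt position.  The
filtered derivative is used only for the fitted velocity series.

*Slow-phase position.*  `EHp(t)` is the cumulative trapezoidal integral of
the valid velocity; integration segments touching an excluded sample
contribute nothing, so each quick-phase displacement is removed and the
trajectory is continuous across gaps.  The gauge is fixed to mean 0 over
valid samples.  Slow-phase motion occurring *inside* an excised gap is
necessarily lost; gaps are brief (tens of ms) so the effect on fits is
below 1–2%.  Trials with fewer than 50% valid samples are rejected —
below that, fits and sweep correlations are unstable.

*Cycle segmentation.*  Phase 0 is the rising zero-crossing of the
reference velocity, located analytically from the reference's quadrature
projection (robust to noise, modality-independent).  Each cycle is
linearly resampled to K = 128 phase bins; a bin is valid only if the
samples it interpolates between are valid — saccade gaps stay missing, no
interpolation across them — and each sweep is centred to zero mean over
its valid bins.  The interpolation grid is extended by one sample at each
trace end (linear continuation) so the final cycle of an exactly-n-cycle
recording is usable.

## Sinusoid fitting

Because the reference is a sinusoid of known frequency, the least-squares
problem `EHv = g·r(t − td) + Cte` is linear in the quadrature basis
{sin 2πft, cos 2πft, 1}.  Both the eye velocity (valid samples) and the
reference are projected onto this basis; the gain is the amplitude ratio,
the phase is the angle between the two phasors, and the offset is the
eye-velocity intercept.  This closed form is deterministic and fast; an
iterative nonlinear optimizer over (g, td, Cte) is kept in the test suite
as an independent oracle and agrees to 1e−6 in gain and 0.01° in phase on
noiseless draws.

`VAF = 1 − var(est − EHv)/var(EHv)` is computed on valid samples with the
population variance.  The quality rule flags fits with gain < 0.10 *and*
VAF < 0.5: flagged gains remain in gain statistics, flagged phases are
excluded from all phase-based analyses and from the combined-response
model.

*OCR.*  Eye elevation per tilt plateau is the mean of the last half of
each ≥10 s hold (the response is stabilized well within the first half;
no settling window is modelled explicitly), after dropping samples whose
vertical velocity exceeds the detector floor.  The gain is the ordinary
least-squares slope over (tilt, eye) pairs; at least 3 distinct plateaus
are required.

*OVAR.*  `SP(t) = β + μ·sin(2π f₀ t + φ₀)` is the same quadrature
regression at the table rotation frequency `f₀ = speed/360` (0.1389 Hz at
50 °/s), with the sine-argument lag reparameterized as a phase φ₀ in
degrees for dimensional consistency.  The raw bias β is additionally
reported sign-normalized so that compensatory nystagmus (slow phases
opposing the rotation) is positive for either direction; per-direction
fits and their normalized mean are produced.

## Combined-response (CGR) model

The sum of two equal-frequency sinusoids is a sinusoid, so an animal's
combined response is predicted from its unimodal fits.  Two paths are
implemented and tested against each other:

* **waveform path** (the reference implementation of the measurement
  procedure): build the two unimodal velocity sinusoids, shift each in
  time by a per-frequency delay (δ_vor, δ_okr), sum over one densely
  sampled cycle, take gain = (peak-to-peak)/2 ÷ stimulus peak velocity and
  phase from the circular-cross-correlation-maximizing lag against the
  stimulus reference;
* **phasor path** (closed form): complex addition after rotating each
  phase by −360·f·δ.

At 1024 samples/cycle they agree within 1e−3 in gain and 0.5° in phase;
the prediction satisfies the triangle inequality
|g_v − g_o| ≤ g_pred ≤ g_v + g_o.

*Shift optimization.*  The delays are not free per animal: for each
frequency they are fit once on the control group by exhaustive grid search
(half-width one quarter period, step period/200, i.e. 1.8° of phase) over
(δ_vor, δ_okr), minimizing the mean over control sessions of the
mean-squared difference over one cycle between the predicted waveform and
the sinusoid reconstructed from the observed CGR fit.  For full-cycle
equal-frequency sinusoids this MSE equals `|P_pred − P_obs|²·A²/2` in
phasor form, which lets the whole grid be evaluated exactly and
vectorized; a test verifies the identity against literally sampled
waveforms.  Ties are broken by smallest |δ_vor|+|δ_okr|, then
lexicographically, making the search deterministic.  The waveform-MSE
criterion was chosen because it penalizes gain and phase mismatch in one
scalar; observed responses enter as their sinusoid reconstructions (the
fitted gain/phase), and sessions at different weeks are kept separate.
Note an identifiability caveat: when the unimodal phases of all control
animals are similar, the loss surface has a shallow valley along which the
two delays trade off; the optimum is still unique on the grid but
individual delays should be interpreted with care.

*Application.*  The control-fitted shifts are applied unchanged to every
animal; an animal/frequency with a QC-flagged unimodal phase gets no
prediction there.

## Sweep statistics

Computed on per-cycle slow-phase *position* trajectories (not velocity).

* `Rep` = mean of the above-diagonal entries of the N×N pairwise Pearson
  correlation matrix.  Pairs use their overlapping valid bins
  (pairwise-complete); entries with under 50% overlap or a constant sweep
  are missing and the averaging denominator shrinks accordingly.
* `Amp` = sqrt(mean over sweeps of σ²), where σ is the population standard
  deviation of a sweep's valid bins about its mean — σ² enters a plain
  mean, hence the population convention.  A full-cycle sinusoidal sweep of
  amplitude A gives σ = A/√2.

Rep is invariant to per-sweep affine rescaling and to sweep order; Amp
scales linearly with position.  Per-trial values are reported per
frequency plus an across-frequency mean.

## Cohort metrics and clustering

Vestibular weight `w = g_aVOR/(g_aVOR + g_OKR)` is computed per frequency
at the baseline week and reported in percent; it is scale-invariant in the
two gains.  The integration metric Δ = mean CGR − mean OKR averages gains
across the three common frequencies (0.2, 0.5, 1 Hz); negative Δ means the
animal stabilizes gaze worse with vestibular input than with vision alone.

Phenotype clustering is agglomerative UPGMA (unweighted average Euclidean
linkage, scipy) on the per-animal (mean aVOR, Δ) plane, with no feature
scaling by default (a `standardize` flag exists).  The aVOR feature is the
cross-frequency mean (selectable).  The 2-cluster cut labels the
lower-mean-Δ cluster Δ−; the two children of the Δ+ node are compared on
mean aVOR and the lower one labelled the low-VOR subgroup.  Linkage
heights are verified against a brute-force UPGMA implementation.

Structure-function regressions are ordinary least squares of hair-cell
marker counts on the matching reflex gain (canal ↔ 1 Hz aVOR, utricule ↔
OCR slope), with r² and the two-sided p-value; p-values are reported raw
(single planned regressions, no multiplicity family).

## Synthetic cohort

The generator emulates the statistical structure the analyses rely on:

* **Protocol**: weeks 0–12 in steps of 2; aVOR at 0.2–2 Hz, 30 °/s peak;
  OKR at 0.1–1 Hz, 10 °/s; CGR at 0.2/0.5/1 Hz, 30 °/s; OCR tilt steps of
  10° up to ±40° held ≥10 s; OVAR at 50 °/s in both directions.
* **Lesion trajectory** (treated group): aVOR gain multiplier falls to 1/3
  at week 6 (two thirds of the reflex lost) and recovers to ~0.55 by week
  12; OCR and MOR bias dip and recover on similar schedules; a phase lead
  proportional to the gain loss (15° at the trough) develops.  OKR gains
  at frequencies above 0.2 Hz rise after week 6 (peak ×1.3 at week 8,
  ×1.2 at week 12) — the frequency-specific visual substitution.
* **Baselines**: aVOR gain grows with frequency (0.35 → 0.85), OKR falls
  (0.75 → 0.25), so the vestibular weight crosses 50% between 0.2 and
  0.5 Hz; OCR slope 0.55; MOR bias 6 °/s with 2.5 °/s modulation.
  Per-animal baselines are drawn with 8% fractional spread.
* **Integration subtypes** among treated animals (47% / 16% / 37%,
  matching the observed 12/7 split with a low-VOR minority inside Δ+):
  Δ+ combines optimally (CGR = shifted phasor sum of its unimodal truths
  at δ_vor = 10 ms, δ_okr = −5 ms); Δ+ low-VOR has its VOR additionally
  halved; Δ− has the same attenuation *and* high cycle-to-cycle gain
  jitter (SD 0.5 vs 0.05) with its base gain deflated by 1/√(1+jitter²)
  so its expected raw sweep amplitude matches the low-VOR subtype, and its
  combined gain is only 0.4 of the model prediction.  This reproduces the
  dissociation: reproducibility separates Δ− from low-VOR Δ+, amplitude
  does not, and Δ correlates positively with Rep.
* **Trial rendering**: slow-phase velocity = per-cycle-jittered gain ×
  phase-shifted reference + white velocity noise (SD 3 °/s); position is
  the trapezoidal integral, punctuated by Poisson quick phases (1.2 /s,
  amplitude |N(8°, 2°)| toward the centering set-point, 100 ms
  refractory) whose ground-truth mask is stored with the trace.  The eye
  is sampled at 120 Hz, the stimulus at 1 kHz on its own grid and linearly
  interpolated onto the eye timebase, exercising the dual-rate path.  The
  quick-phase parameters are plausible defaults, not fitted values — no
  saccade statistics were available to calibrate them.  A single noise
  model is shared by all sinusoidal modalities.

What the generator does **not** emulate: tracker dropouts and blinks,
pupil-size artifacts, torsional kinematics, habituation across sessions,
non-sinusoidal slow-phase waveforms, and any correlation between an
animal's noise level and its lesion severity beyond the subtype structure.
Passing tests therefore demonstrate correctness of the estimators and the
pipeline's contracts under the stated generative model, not robustness to
every artifact of real recordings.

## Numerical choices and problem sizes

Quadrature fits use `numpy.linalg.lstsq`; VAF uses population variances;
phases wrap to (−180°, 180°] with +180° preferred at the branch point.
The generator integrates velocity trapezoidally so that the analysis-side
central differences are phase-consistent (a left Riemann sum would bias
the recovered lag by half a sample, 4.2 ms at 120 Hz).  Monte-Carlo tests
use 100–200 seeded draws; the demo pipeline used in tests and in the
acceptance script is 4 SHAM + 6 IDPN animals, 3 weeks × 3 frequencies ×
3 sinusoidal modalities plus OCR and OVAR (~360 trials), chosen to keep a
full run around ten seconds while leaving every stage statistically
meaningful; the phenotype analyses use 19–20 treated animals as in the
study design they mirror.

## Known limitations

* The shift optimization's two delays are weakly identified when control
  phases cluster tightly (see above); only their combined effect on the
  predicted phasor is strongly constrained.
* Slow-phase displacement inside excised quick-phase gaps is discarded,
  slightly deflating `EHp` amplitude for saccade-dense trials.
* The velocity offset Cte is estimated and reported but not used
  downstream.
* Repeated-measures ANOVA and post-hoc families are out of scope; the
  tables are written as CSV for export to any statistics package.
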
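# Methods

`iksvar` models the path from a heterozygous *KCNQ1* variant to its
electrocardiographic phenotype in four stages: (1) synthetic two-electrode
voltage-clamp (TEVC) datasets emulating *Xenopus laevis* oocyte recordings
of KCNQ1 and IKs (KCNQ1 + KCNE1) currents; (2) the measurement, per-day
normalization, Boltzmann activation fitting, Student's t statistics and
functional classification applied to such datasets; (3) injection of the
measured effect — relative current amplitude `r` and activation shift
`ΔV1/2` — into a human ventricular myocyte model paced to its limit cycle;
(4) a one-dimensional transmural cable whose far-field pseudo-ECG yields QT
intervals for percent-change comparisons, with Bazett QTc classification
for the clinical fixture table.

## Synthetic clamp data

Each oocyte's current is a sum of three ohmic components:

    I(t, V) = g_leak·(V − E_leak)  +  xIKs(t, V)  +  channel(t, V)  +  ε

The exogenous channel and the endogenous xIKs (KCNE1 co-assembling with
native xKCNQ1, present whenever KCNE1 cRNA is injected) share the same
phenomenological gating: a Boltzmann steady state `g∞(V) =
1/(1 + exp((V1/2 − V)/k))`, mono-exponential activation
`a(t) = 1 − exp(−t/τ)` during the depolarizing step, and mono-exponential
deactivation in the tail with the gating level carried continuously across
the step→tail transition (the recorded current jumps there, because the
driving force jumps — that ohmic jump *is* the tail current signal).

Defaults (all config knobs, units in field names):

| parameter | default | rationale |
| --- | --- | --- |
| KCNQ1-alone gating | V1/2 −20 mV, k 12 mV, τ 150 ms | fast homotetramer activation |
| IKs gating | V1/2 +20 mV, k 14 mV, τ_act 2.5 s, τ_deact 400 ms | KCNE1 slows activation into the seconds range |
| WT total amplitude | 2.5 µA (no KCNE1), 6.0 µA (+KCNE1) at +40 mV | "several µA" IKs expression at the high cRNA dose |
| leak level | 0.15 µA at +40 mV, reversal −40 mV | non-injected oocytes pass ≈150 nA at +40 mV |
| xIKs level | 12% of the WT IKs amplitude | small but clearly nonzero KCNE1-alone currents |
| expression CV | 25% (lognormal, mean 1) | typical oocyte batch scatter |
| day effect | 15% lognormal multiplier shared within a day | batch/batch variation |
| leak CV | 30% | leak varies more than expression |
| recording noise | 0.02 µA additive Gaussian per sample | instrument floor |
| K⁺ reversal | −90 mV | low-K⁺ ND96-like bath |

The per-condition truth `r_total` is defined on the same scale the analysis
estimates: the ratio of mean total end-of-step current to the wild-type
reference at the reference voltage (+40 mV).  The generator solves for the
exogenous-channel conductance that realizes the requested total given leak
and xIKs; when the target lies below the endogenous level (a variant
dominant-negative on xKCNQ1), the channel component is zero and the xIKs
component itself is reduced.  This choice makes the generator truth the
exact twin of the analysis output and keeps the round trip unbiased — had
`r_total` scaled only the exogenous term, the common background would bias
recovered reductions by ~3 percentage points.

The generator emulates: per-day batches, lognormal expression scatter,
endogenous backgrounds, slow sigmoidal activation and deactivating tails.
It does not emulate: capacitance transients beyond a blanking placeholder,
leak trends or run-down within a recording, voltage-dependent time
constants, subunit-assembly stoichiometry (heterozygous amplitudes come
from the fixture, not from combinatorics), or temperature effects.  Passing
recovery tests therefore show the analysis pipeline is correct and unbiased
under realistic variance — not that it would be robust to artifacts absent
from the generator.

## Clamp analysis

End-of-step amplitude is the mean over the last 50 ms of the step; the tail
peak is the signed extremum after a 10 ms blanking window.  Amplitudes are
divided by the day's mean wild-type reference amplitude at the reference
voltage; a final global rescale pins the pooled normalized reference mean to
exactly 1 (with unequal per-day n, plain day division alone leaves it within
O(CV²/n) of 1).  Comparisons use the two-tailed equal-variance Student's
t-test with flags at p < 0.05 and no multiple-testing correction, matching
lab practice for this kind of dataset.  Classification: loss/gain of
function vs the full-dose wild-type; dominant negative (het, no KCNE1) vs
the half-dose wild-type; below-endogenous (homomeric, +KCNE1) vs the
KCNE1-alone control.

Activation curves: tails normalized per oocyte to that oocyte's maximum,
fitted with the two-parameter Boltzmann (slope bounded in [1, 40] mV;
boundary-pinned or degenerate fits excluded from averaging), V1/2 averaged
across oocytes.  A known limitation follows from the voltage range: IKs
reaches only ~80% activation at +40 mV, so the max-normalized fit
underestimates the underlying gating midpoint by ~7 mV and compresses
between-condition shifts (a true +8 mV shift fits as ≈+4.7 mV).  This is a
property of the wet-lab method itself over −40…+40 mV, not of the
implementation; tests therefore assert estimator consistency against the
noise-free estimand rather than recovery of the generative midpoint, and
the cardiac stages take ΔV1/2 from the fixture table rather than from
re-fitted synthetic data.

## Ventricular myocyte model

The cell stage implements the 2006 ten Tusscher–Panfilov human ventricular
myocyte model (19 states; ENDO/M/EPI variants differing in Ito and IKs
conductance) at 37 °C.  The variant perturbation acts only on IKs: the
activation-gate steady state `xs_inf` is shifted by +ΔV1/2 (time constants
untouched — the model's single squared activation gate is the natural
carrier of the shift) and, in the SHIFT_AND_SCALE series, `G_Ks` is
multiplied by `r` from the heterozygous +KCNE1 context, the
patient-relevant state.  Both series are available; SHIFT_AND_SCALE is the
headline default.  No Q10 correction maps the 21–22 °C oocyte measurements
onto the 37 °C model; `r` and ΔV1/2 are taken as dimensionless/additive.

Numerics: fixed-step Rush–Larsen integration (exponential gate updates,
forward-Euler concentrations), dt = 0.02 ms, chosen so the single-cell and
tissue stages share identical reaction numerics; halving to dt = 0.005 ms
changes APD90 by < 0.1 ms.  An independently written re-encoding of the
model (plain-numpy right-hand side, adaptive LSODA, rtol 1e-6/atol 1e-8)
lives in the test suite as a cross-check; the two routes agree to < 0.2 mV
RMS over a beat and < 0.15 ms in APD90.

Pacing: 2 Hz, 1 ms / 52 pA/pF stimulus, up to 500 beats.  Limit-cycle
detection requires the consecutive-beat APD90 difference to stay below
0.01 ms for five beat pairs in a row: a single sub-tolerance difference
occurs spuriously around beat ~18, where the early rate-adaptation
transient turns around and the beat-to-beat difference passes through zero
before regrowing.  With the five-pair rule the epicardial cell converges
around beat ~460; a slow residual drift of ≲0.01 ms/beat (intracellular
Na⁺/K⁺ equilibration) remains, which is why the tolerance is defined on
consecutive beats rather than on an absolute steady state.  APD90 is
measured from the end of the steepest upstroke interval to the first
downward crossing of rest + 0.1·amplitude, with linear interpolation.

## Cable pseudo-ECG

The tissue surrogate is a 16 mm monodomain cable, dx = 0.1 mm, 25% ENDO /
35% M / 40% EPI from the stimulated endocardial end, diffusion coefficient
0.154 mm²/ms (conduction velocity ≈ 0.7 m/s), no-flux boundaries,
forward-Euler diffusion at dt = 0.02 ms with a hard stability guard
(dt ≤ dx²/2D).  The stimulated segment is a fixed 0.5 mm of tissue so that
grid refinement does not shrink the excited region below the liminal
length.  Nodes start from their cell type's single-cell 2 Hz limit cycle
(with the same IKs perturbation) and the cable runs 20 conditioning beats
before the readout beat.  The far-field electrode sits 20 mm beyond the
epicardial end on the cable axis:

    φ(t) ∝ −∫ (∂Vm/∂x) · 1/(x_e − x)² dx ,

baseline-subtracted.  QT is the interval between the first and last time
|φ| exceeds 0.001 mV.  Measured on this surrogate, QT is stable to < 5%
for thresholds in 0.001–0.005 mV but not below: the last-repolarizing
mid-myocardial segment leaves a slow signal tail at a few 1e-4 of the R
amplitude, and a threshold inside that tail slides along it.  QT from the
cable is therefore used only for variant-vs-wild-type percent change at a
fixed threshold, never for absolute-duration claims; grid refinement
(dx/2, dt/4) changes QT by < 2%.  The apico-basal and transventricular
gKs gradients, His–Purkinje activation optimization and torso forward
problem of a full-heart simulation are deliberately out of scope.

Bazett correction: QTc = QT/√RR with normality limits 450 ms (men) and
460 ms (women).

## Fixture provenance

`variant_effects_paper.json` distinguishes `"text"` entries — the four
numerically stated effect sizes (G119R het+KCNE1 r = 0.74, K421E het
r = 0.84 and homo r = 0.34, R591C het r = 0.72) — from
`"figure_placeholder"` entries read approximately off bar graphs and
activation fits so that every variant/context combination is runnable.
Placeholders are stand-ins and are excluded from all quantitative
acceptance checks.  L273V is analyzed at +20 mV (its effect is
voltage-dependent); all other variants at +40 mV.

## Problem sizes

Recovery runs use the default conditions of 3 recording days × 10 oocytes per
condition; the non-injected calibration uses 200 oocytes spread over 8 days
with a day-clustered standard error (oocytes within a day share the batch
multiplier, so a per-oocyte s.e. would understate the uncertainty several-
fold).  Monte-Carlo oracles in the test suite use up to 400 oocytes; cable
property tests use 3 conditioning beats where only propagation structure is
probed, and the fully conditioned cable where baseline flatness matters.
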
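# Methods

## The kinetic model

The model follows the upper part of *E. coli* glycolysis with four state
metabolites — glucose-6-phosphate (G6P), fructose-1,6-bisphosphate (FBP),
phosphoenolpyruvate (PEP) and pyruvate (PYR), all in mmol l⁻¹ — connected by
six reactions: glucose uptake by the phosphotransferase system (PTS),
phosphofructokinase (PFK), fructose-1,6-bisphosphatase (FBPase), a lumped
FBP→PEP conversion (labelled FBA), pyruvate kinase (PYK), and pyruvate
dehydrogenase (PDH).  Mass balancing gives

    dG6P/dt = PTS + FBPase − PFK
    dFBP/dt = PFK − FBPase − FBA
    dPEP/dt = 2·FBA − PYK − PTS
    dPYR/dt = PTS + PYK − PDH

(the factor 2 on FBA reflects the cleavage of one hexose-bisphosphate into
two triose units).  Growth dilution is neglected; the glycolytic flux
dwarfs it.

Rate laws combine Michaelis–Menten/Hill saturation with power-law factors
encoding three allosteric interactions:

    PTS    = Vmax1 / (k1·(PYR/PEP) + k2 + k3·(PYR/PEP) + 1)
    PFK    = Vmax2 / (1 + Km1/G6P)^n1 · PEP^(−a1)
    FBPase = Vmax3 · FBP/(FBP + Km2) · PEP^(a2)
    FBA    = Vmax4 · FBP/(FBP + Km3)
    PYK    = Vmax5 / (1 + Km4/PEP)^n2 · FBP^(a3)
    PDH    = Vmax6 / (1 + Km5/PYR)^n3

`a1` is the PEP inhibition of PFK, `a2` the PEP activation of FBPase and
`a3` the FBP feed-forward activation of PYK.  A feedback is "switched off"
by pinning its exponent to 0, giving 8 model structures.  The PTS
denominator carries both `k1` and `k3` on the same PYR/PEP term; the two
are algebraically redundant but are kept as written.

### Steady-state calibration

All metabolites are set to 1 mmol l⁻¹ and all maximal rates are solved so
that this unit state is a steady state carrying the measured glucose
uptake flux

    F_glc = 8 mmol g⁻¹ h⁻¹ / 0.002 l g⁻¹ / 60 = 66.66 mmol l⁻¹ min⁻¹.

The balances pin PTS = FBA = PYK = F_glc and PDH = 2·F_glc.  The
PFK/FBPase cycle is underdetermined; its split is set by a sampled flux
ratio ρ = F_FBPase/F_PFK with F_PFK − F_FBPase = F_glc, i.e.
F_FBPase = ρ/(1−ρ)·F_glc.  ρ is sampled on [0.01, 0.99]; the upper end is
clipped below 1 because the cycle fluxes diverge as ρ → 1.  Each Vmax is
then the target flux divided by the remainder of its rate law at the unit
state, where every power-law factor equals 1 — so the calibration is
independent of the exponents, and the unit-state fluxes are identical
across all 8 structures sharing the same draws.

### Parameter sampling and stability screening

Binding constants (`k1..k3`, `Km1..Km5`) are drawn log-uniformly on
[0.1, 10], Hill coefficients and active exponents log-uniformly on [1, 4],
and ρ log-uniformly on [0.01, 0.99].  All quantities are drawn for every
candidate regardless of structure (inactive exponents are zeroed
afterwards), so structure comparisons at the same seed share common random
numbers.  A candidate is kept only if every eigenvalue of the analytic
4×4 Jacobian at the unit state has real part below −10⁻⁵ min⁻¹ (strict;
marginal modes count as unstable).  Rejection sampling continues until the
requested ensemble size is reached (a cap of 10⁷ rejections guards against
degenerate configurations).  For the full structure roughly 40–50% of
draws are rejected.

### Perturbation protocol and oscillation classification

Each accepted model starts at the unit steady state; at t = 50 min the PTS
Vmax is multiplied by 0.95 (a permanent 5% uptake downshift) and the ODE
is integrated to t = 250 min with LSODA at rtol 10⁻⁸ / atol 10⁻¹⁰.  An
upshift protocol (start from a steady state calibrated at reduced uptake,
then scale Vmax1 up) uses the same machinery via the calibration's
`uptake_flux` argument and `simulate_perturbation`'s factor.

The pyruvate series on a uniform 1-min observation grid, restricted to
[60, 250] min (10 min after the shift, skipping the relaxation transient),
is detrended by removing its least-squares straight line and Fourier
transformed.  The single-sided amplitude spectrum 2|X_q|/N is used, so a
sinusoid of amplitude A reads A at its bin; a trajectory counts as
oscillating when the maximal non-DC amplitude exceeds 0.001, and its
period is the inverse of the peak frequency (ties resolve to the lower
frequency).

**Observation grid.**  The classification grid is 1 min, not the 0.1-min
grid used for trajectory export.  At the calibrated flux the model's
limit cycles are fast (intrinsic periods of roughly 3–40 s, median ~9 s
when measured on a 0.01-min grid): metabolite turnover at 66.66 mmol l⁻¹
min⁻¹ over pool sizes of ~1 mmol l⁻¹ sets second-scale relaxation times.
On a 1-min grid these cycles register at aliased, minute-scale apparent
periods, which is the scale at which such simulations are conventionally
reported and compared with minute-scale single-cell measurements; the
oscillating/non-oscillating call itself is insensitive to the grid
(identical counts at 0.1, 0.5 and 1.0 min in our checks) because aliasing
preserves amplitude.  Users who care about the intrinsic timescale should
pass a finer `dt_out` to `simulate_perturbation` and classify with an
explicit `analysis_start`.

### Ensemble statistics

The oscillating fraction P is reported with Clopper–Pearson binomial
intervals.  Parameter importance uses Welch's two-sided two-sample t-test
between each parameter's values in the oscillating subset and in the full
ensemble (the subset is deliberately not removed from the ensemble);
p < 10⁻¹⁰ is classed "strong", 10⁻¹⁰–10⁻⁵ "moderate".  Zero-variance
parameters (exponents pinned to 0) get p = 1 and a degenerate flag.
With ensembles of ~1000 sets (~60 oscillating) only the largest effects
reach these extreme significance classes; directional statements (e.g.
elevated `a3` among oscillating sets) are stable at this size.

## Single-cell FRET trace analysis

Input is a long-format table of per-cell two-channel intensities sampled
at 1 Hz.  The pipeline applies, in order:

1. **Dark count**: subtract the camera offset (106 counts) from both
   channels; values at or below zero are clipped to 10⁻⁶ counts and
   flagged (the downstream corrections divide by the channels).
2. **Bleach correction**: fit the stimulated segment of each channel with
   a·exp(−bt)+c, or a−bt for low bleaching, and divide the whole series by
   the fit.  When no model is forced, the exponential is fitted first and
   replaced by the line if its decay rate is within 2 standard errors of
   zero; a non-convergent exponential falls back to linear with a warning.
3. **Ratio**: corrected CFP over corrected YFP (the numerator is
   configurable; sensors differ in sign convention).
4. **Responsiveness filter**: per-cell response = mean over a post-stimulus
   plateau (frames 120–180 after the stimulus) minus the mean over the
   last 60 pre-stimulus frames.  Cells below 10% of the population
   response (boundary inclusive) are discarded; a warning fires if more
   than 15% of cells drop out.  The plateau windows are package choices —
   they bracket the settled response while avoiding the step transient.
5. **Window**: an 800-frame segment starting 50 s after stimulation.
6. **PSD**: per cell, |DFT|² of the raw window divided by the squared time
   mean and scaled by dt/N, reported for q = 1..N/2 at frequencies
   q/(N·dt); DC is excluded from the report.  The cell average carries the
   SEM over cells.  With this normalisation white noise of mean μ and
   standard deviation σ gives a flat spectrum at σ²·dt/μ², and the
   spectrum satisfies Parseval's identity against the window's relative
   variance.
7. **Autocorrelation**: per cell, the unbiased estimator
   C(m) = Σₖ δr_{k+m}δr_k / ((N−m)·var(δr)) of the mean-subtracted window,
   then averaged over cells; C(0) = 1 identically.
8. **Dose–response**: nonlinear least squares of Y = A·L^H/(L^H + K^H),
   with A pinned to 1 for normalized curves; K is the EC50 in input units.
   The EC50 is seeded at the geometric mean of the doses.

Single-channel traces (NAD(P)H autofluorescence) skip steps 3–4 and reuse
the same windowing/PSD/autocorrelation.

## Synthetic trace generator

Each cell has a latent ratio: baseline 1.0, a +10% step at the stimulus
(suppressed for a configurable non-responder fraction, default 5%), and an
optional oscillation — amplitude·cos(2πf₀(t−t_stim)+φ), damped by
exp(−(t−t_stim)/τ) or sustained, with φ either common or uniform per cell.
Defaults: f₀ = 0.006 Hz, relative amplitude 2%, τ = 120 s, 1000 s
duration, 100 cells.  The two channels realise the ratio symmetrically and
with opposite signs (CFP ∝ √ratio, YFP ∝ 1/√ratio), are bleached
exponentially per channel (2×10⁻⁴ and 3×10⁻⁴ s⁻¹), and receive the camera
dark count plus independent Gaussian noise (10 counts/frame on ~2000-count
baselines; a Poisson mode exists but Gaussian is the default, justified by
the high counts).  The generator returns per-cell ground truth for oracle
tests.

What it emulates: the step-plus-fluctuation phenomenology of
metabolite-sensor imaging, including population-level cancellation of
randomly-phased single-cell oscillations and a flat noise floor in the
no-oscillation control.  What it does not: photophysics (channel noise is
additive and independent, not anti-correlated shot noise), cell-to-cell
expression variability, segmentation/tracking artifacts, or any coupling
to the kinetic model.  Tests passing on these traces validate the
analysis chain's algebra and statistics, not the biology of real traces.

## Numerical choices and degenerate inputs

* ODE integration: LSODA (stiffness-switching), rtol 10⁻⁸, atol 10⁻¹⁰;
  states are checked positive on the output grid and integration failures
  carry the failure time.  Trajectories that fail mid-ensemble are counted
  as non-oscillating with a warning (rare: ≲1 per 3000 stable sets).
* Jacobians are analytic (products of log-derivatives); tests pin them to
  central finite differences at 10⁻⁴ relative.
* FFT conventions: rfft; the Nyquist bin is excluded from the ensemble
  amplitude spectrum (it is not a 2/N-scaled pair) and included in the
  FRET PSD (q = N/2).
* The responsiveness cutoff is applied with a 10⁻⁹ relative tolerance so
  the 10%-of-population boundary is inclusive under float rounding.
* Degenerate inputs raise: non-positive concentrations, flux ratio ≥ 1,
  zero-mean or zero-variance windows, fewer than 3 detrend points or
  distinct doses.

## Problem sizes

Default analysis sizes are chosen so the full pipeline runs on a laptop
core: ensembles of 1000 sets for the downshift experiment (the acceptance
script uses 2000), 500 per structure for the 8-structure screen, 800-frame
windows with 60–100 synthetic cells.  Fractions at these sizes carry
binomial noise of roughly ±0.7 (n = 1000) percentage points; the shipped
tables report exact counts and confidence intervals.

## Known limitations

* The oscillating fraction of the downshift ensemble is ~6% under this
  implementation's stated sampling and classification conventions; the
  exact value is sensitive to unstated protocol details (FFT segment,
  sustainedness criterion, per-class sampling distributions) that the
  analysis text leaves open, so cross-implementation comparisons should
  use binomial tolerances, not exact counts.
* Linear stability is assessed only at the pre-shift steady state; the
  classification is purely simulation + FFT, with no bifurcation
  continuation.
* The model omits cofactors, energy/redox state and genome-scale context;
  it is a minimal oscillator scaffold, not a quantitative flux model.
* The FRET branch starts from extracted per-cell traces; segmentation and
  tracking are upstream of this package.
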
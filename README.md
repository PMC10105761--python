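# pyrosc

Ensemble kinetic modelling of pyruvate oscillations in *E. coli*
glycolysis, and the single-cell FRET fluctuation analysis used to look
for them in live cells.

Intracellular metabolite levels in single bacteria are not static:
glycolytic intermediates can oscillate on the scale of minutes.  This
package implements the two computational halves of that story for
systems biologists:

1. **Ensemble modelling of a minimal glycolysis oscillator.**  A
   4-metabolite (G6P, FBP, PEP, PYR), 6-reaction (PTS, PFK, FBPase,
   FBA, PYK, PDH) ODE model with three allosteric interactions encoded
   as power-law factors: PEP ⊣ PFK (exponent a1), PEP → FBPase (a2)
   and FBP → PYK (a3).  Kinetic parameters are sampled log-uniformly,
   every maximal rate is calibrated so the all-ones metabolite state is
   a steady state carrying the glucose uptake flux
   F_glc = 8 mmol g⁻¹ h⁻¹ / 0.002 l g⁻¹ / 60 = 66.66 mmol l⁻¹ min⁻¹,
   and only linearly stable sets (all Jacobian eigenvalues with
   Re λ < −10⁻⁵) are kept.  Each model is perturbed by a 5% drop of the
   uptake Vmax at t = 50 min and its pyruvate trajectory is classified
   as oscillating or not by first-order detrending plus FFT with a
   0.001 amplitude threshold — over many sampled models this yields the
   fraction of parameter space that supports sustained oscillations,
   per feedback structure, and t-tests on which parameters favour them.

2. **Single-cell FRET ratio fluctuation analysis.**  From per-cell
   CFP/YFP time series (1 Hz): camera dark-count subtraction (106
   counts), photobleaching correction by dividing out a fitted
   a·e^(−bt)+c (or linear) decay, the FRET ratio R = CFP/YFP, a
   responsiveness filter (cells under 10% of the population response are
   discarded), an N = 800-frame window starting 50 s after stimulation,
   the mean-normalised power spectral density
   s_R(ω = 2πq/N) = ⟨|r̃_q|²/r̄²⟩_cells · dt/N,
   the unbiased autocorrelation
   C(m) = ⟨Σₖ δr_{k+m}δr_k / ((N−|m|)·mean δr²)⟩_cells,
   and Hill dose-response fits Y = A·L^H/(L^H + K^H).

A seeded synthetic-trace generator (`pyrosc.synthetic`) produces
dual-channel traces with dark offset, bleaching, shot noise, step
responses and damped/sustained per-cell oscillations — with ground
truth — so the whole FRET branch is testable without microscopy data.

## Worked example

Run a 100-model downshift ensemble of the full three-feedback model and
fit a noise-free dose-response table:

```
$ pyrosc ensemble run --n 100 --seed 5 --out ens.csv
6/100 oscillating (P = 0.060); median period 6.62 min

$ pyrosc fret dose-response --table doses.csv
A = 1, H = 1, EC50 = 5.5 (residual norm 2.38e-16)
```

The first command reports that 6 of 100 randomly sampled stable models
kept oscillating after the 5% uptake downshift, with a median apparent
period of 6.6 min on the 1-min observation grid; `ens.csv` holds one
row per parameter set (all 21 kinetic constants, the oscillation call,
dominant frequency, period, FFT amplitude).  The second recovers the
EC50 (here 5.5 µM, the half-saturating glucose concentration) from a
Hill curve to machine precision.

The numbered scripts under `analysis/` run the full study: the
downshift ensemble (`01`), the 8-structure feedback screen (`02`),
parameter-importance t-tests (`03`), the synthetic FRET benchmark with
PSD/autocorrelation recovery and desynchronization averaging (`04`),
and dose-response fitting (`05`).  Each writes its tables under
`results/` and prints a one-paragraph summary.

## Layout

```
src/pyrosc/        kinetics.py   ODE model, calibration, sampling, stability
                   ensemble.py   detrend+FFT classification, screens, t-tests
                   fret.py       trace corrections, PSD, autocorrelation, Hill
                   synthetic.py  seeded trace & dose-response generators
                   io.py, cli.py tables, config, manifests, CLI
analysis/          numbered study drivers (01–05)
tests/             pytest suite (unit, property, acceptance)
docs/methods.md    model, conventions, numerical choices, limitations
```
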
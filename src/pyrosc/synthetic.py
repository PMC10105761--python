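"""Synthetic single-cell fluorescence traces.

Generates dual-channel (CFP/YFP) 1 Hz traces with the statistical
structure the FRET pipeline assumes: camera dark offset, per-channel
exponential photobleaching, additive white camera noise, a step
response at the stimulus, an optional oscillatory component per cell
(damped or sustained, with a common or per-cell random phase), and a
configurable fraction of non-responding cells.  The two channels move
in opposite directions on stimulation, as a FRET pair does.  Ground
truth (phases, responder flags, latent parameters) is returned with
the traces so analyses can be checked against it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .fret import FluorescenceTrace, DARK_COUNT

__all__ = ["OscillationBlock", "TraceGeneratorConfig", "generate_traces",
           "generate_dose_response"]


@dataclass(frozen=True)
class OscillationBlock:
    """Oscillatory component of the latent ratio.

    The default frequency of 0.006 Hz (~170 s period) sits in the
    low-frequency band where single-cell metabolite fluctuations are
    observed; the relative amplitude is chosen so the induced spectral
    power stands clearly above the white-noise floor below 0.02 Hz.
    """

    mode: str = "none"                 # none | damped | sustained
    frequency: float = 0.006           # Hz
    relative_amplitude: float = 0.02   # fraction of the baseline ratio
    damping_tau: float = 120.0         # s, damped mode only
    phase: str = "per-cell-random"     # common | per-cell-random

    def __post_init__(self):
        if self.mode not in ("none", "damped", "sustained"):
            raise ValueError(f"unknown oscillation mode {self.mode!r}")
        if self.phase not in ("common", "per-cell-random"):
            raise ValueError(f"unknown phase convention {self.phase!r}")


@dataclass(frozen=True)
class TraceGeneratorConfig:
    """Study conditions for one synthetic experiment.

    Baseline intensities and noise levels emulate EM-CCD counts of
    well-expressing cells at 1 s exposure; the 10% ratio step mimics a
    saturating stimulus response and the 5% non-responder fraction the
    (sub-15%) unresponsive subpopulation seen in live imaging.
    """

    n_cells: int = 100
    dt: float = 1.0                    # s
    duration: float = 1000.0           # s
    dark_count: float = DARK_COUNT
    cfp_baseline: float = 2000.0       # counts above dark
    yfp_baseline: float = 2000.0
    cfp_bleach_rate: float = 2e-4      # s^-1
    yfp_bleach_rate: float = 3e-4
    stimulus_time: float = 100.0       # s
    response_amplitude: float = 0.10   # relative ratio step on stimulation
    oscillation: OscillationBlock = field(default_factory=OscillationBlock)
    noise_sd: float = 10.0             # counts per frame per channel
    noise_model: str = "gaussian"      # gaussian | poisson
    non_responder_fraction: float = 0.05
    baseline_ratio: float = 1.0

    def __post_init__(self):
        if self.noise_model not in ("gaussian", "poisson"):
            raise ValueError(f"unknown noise model {self.noise_model!r}")
        for ch in ("cfp", "yfp"):
            if getattr(self, f"{ch}_baseline") <= 0:
                raise ValueError("expected channel intensity must stay above the "
                                 "dark count")


def _latent_ratio(config: TraceGeneratorConfig, t: np.ndarray,
                  responder: bool, phase: float) -> np.ndarray:
    osc = config.oscillation
    r = np.full_like(t, config.baseline_ratio)
    after = t >= config.stimulus_time
    if responder:
        r = r + config.baseline_ratio * config.response_amplitude * after
    if osc.mode != "none" and osc.relative_amplitude > 0:
        tau = t - config.stimulus_time
        wave = np.cos(2 * np.pi * osc.frequency * tau + phase)
        if osc.mode == "damped":
            wave = wave * np.exp(-np.maximum(tau, 0.0) / osc.damping_tau)
        r = r + config.baseline_ratio * osc.relative_amplitude * wave * after
    return r


def generate_traces(
    config: TraceGeneratorConfig,
    rng: np.random.Generator | int = 0,
) -> tuple[list[FluorescenceTrace], pd.DataFrame]:
    """Generate one synthetic experiment.

    Each cell's latent FRET ratio is baseline + step (responders only)
    + oscillation; the two channels realise it with opposite-signed
    responses (CFP up, YFP down for a positive ratio excursion, split
    symmetrically as sqrt factors), are bleached exponentially, and
    receive independent per-frame noise plus the camera dark count.

    Returns the traces and a ground-truth table (one row per cell:
    responder flag, oscillation phase, latent parameters).
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    t = np.arange(0.0, config.duration, config.dt)
    n_non = int(round(config.non_responder_fraction * config.n_cells))
    responder_flags = np.ones(config.n_cells, dtype=bool)
    if n_non:
        responder_flags[rng.choice(config.n_cells, size=n_non, replace=False)] = False

    osc = config.oscillation
    if osc.phase == "common":
        phases = np.zeros(config.n_cells)
    else:
        phases = rng.uniform(0.0, 2 * np.pi, config.n_cells)

    traces, truth_rows = [], []
    for j in range(config.n_cells):
        ratio = _latent_ratio(config, t, bool(responder_flags[j]), float(phases[j]))
        if np.any(ratio <= 0):
            raise ValueError(
                "configuration produces a non-positive latent ratio "
                "(oscillation amplitude or response too large)"
            )
        # symmetric opposite-signed split: cfp ~ sqrt(ratio), yfp ~ 1/sqrt(ratio)
        rel = np.sqrt(ratio / config.baseline_ratio)
        cfp_clean = config.cfp_baseline * rel * np.exp(-config.cfp_bleach_rate * t)
        yfp_clean = config.yfp_baseline / rel * np.exp(-config.yfp_bleach_rate * t)
        if np.any(cfp_clean <= 0) or np.any(yfp_clean <= 0):
            raise ValueError("configuration produces non-positive expected intensity")
        if config.noise_model == "poisson":
            cfp = rng.poisson(cfp_clean).astype(float)
            yfp = rng.poisson(yfp_clean).astype(float)
        else:
            cfp = cfp_clean + rng.normal(0.0, config.noise_sd, t.size)
            yfp = yfp_clean + rng.normal(0.0, config.noise_sd, t.size)
        cell_id = f"cell{j:04d}"
        traces.append(FluorescenceTrace(
            cell_id=cell_id, times=t,
            cfp=cfp + config.dark_count, yfp=yfp + config.dark_count,
        ))
        truth_rows.append({
            "cell_id": cell_id,
            "responder": bool(responder_flags[j]),
            "phase": float(phases[j]),
            "oscillation_mode": osc.mode,
            "frequency": osc.frequency,
            "relative_amplitude": osc.relative_amplitude if osc.mode != "none" else 0.0,
            "response_amplitude": config.response_amplitude,
            "baseline_ratio": config.baseline_ratio,
        })
    return traces, pd.DataFrame(truth_rows)


def generate_dose_response(
    K: float,
    H: float,
    A: float,
    doses,
    noise_sd: float = 0.0,
    rng: np.random.Generator | int = 0,
) -> pd.DataFrame:
    """Hill-model dose-response table Y = A L^H/(L^H + K^H) + noise."""
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    L = np.asarray(doses, dtype=float)
    if np.any(L <= 0):
        raise ValueError("doses must be positive")
    Y = A * L**H / (L**H + K**H)
    if noise_sd:
        Y = Y + rng.normal(0.0, noise_sd, L.size)
    return pd.DataFrame({"concentration": L, "response": Y})
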
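#!/usr/bin/env python
"""FRET pipeline benchmark on synthetic single-cell traces.

Generates three conditions — sustained 0.006 Hz oscillations with
per-cell random phases, a white-noise control, and common-phase damped
oscillations — pushes them through the full analysis (dark count,
bleach correction, ratio, responsiveness filter, 800-frame window,
PSD, autocorrelation) and reports what the spectra recover.

Writes results/fret_psd.csv, results/fret_acf.csv and
results/fret_population_psd.csv.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from pyrosc import fret as F
from pyrosc import synthetic as S

parser = argparse.ArgumentParser(description=__doc__)
parser.add_argument("--n-cells", type=int, default=100)
parser.add_argument("--seed", type=int, default=0)
parser.add_argument("--out-dir", type=Path, default=Path("results"))
args = parser.parse_args()

STIM = 100.0


def pipeline(traces):
    ratios = []
    for tr in traces:
        tr = F.subtract_dark_count(tr)
        i0 = int(np.searchsorted(tr.times, STIM))
        stim = (i0, tr.times.size)
        cfp = F.correct_bleaching(tr.cfp, tr.times, stim)
        yfp = F.correct_bleaching(tr.yfp, tr.times, stim)
        ratios.append(F.compute_ratio(
            F.FluorescenceTrace(tr.cell_id, tr.times, cfp, yfp), "cfp"))
    kept, unresponsive, _ = F.filter_responsive(ratios, STIM)
    windows = np.vstack([F.select_window(r, STIM, 50.0, 800) for r in kept])
    return windows, unresponsive


conditions = {
    "sustained": S.OscillationBlock(mode="sustained", frequency=0.006,
                                    phase="per-cell-random"),
    "white_noise": S.OscillationBlock(mode="none"),
    "damped_common": S.OscillationBlock(mode="damped", frequency=0.006,
                                        damping_tau=120.0, phase="common"),
}

psd_tables, acf_tables, pop_tables = [], [], []
for name, osc in conditions.items():
    config = S.TraceGeneratorConfig(
        n_cells=args.n_cells, duration=1000.0, oscillation=osc,
    )
    traces, _ = S.generate_traces(config, rng=args.seed)
    windows, unresponsive = pipeline(traces)
    psd = F.compute_psd(windows, dt=1.0)
    acf = F.compute_autocorrelation(windows, dt=1.0, max_lag=400)
    pop = F.compute_psd(windows.mean(axis=0)[None, :], dt=1.0)
    psd_tables.append(pd.DataFrame({
        "condition": name, "frequency_hz": psd.frequencies,
        "psd_mean": psd.mean, "psd_sem": psd.sem,
    }))
    acf_tables.append(pd.DataFrame({
        "condition": name, "lag_s": acf.lags, "C": acf.mean,
    }))
    pop_tables.append(pd.DataFrame({
        "condition": name, "frequency_hz": pop.frequencies,
        "psd_population": pop.mean,
    }))
    peak = psd.frequencies[np.argmax(psd.mean)]
    print(f"{name:14s} unresponsive {unresponsive:5.1%}  "
          f"single-cell PSD peak at {peak:.4f} Hz  "
          f"(population-mean peak "
          f"{pop.mean[np.argmin(np.abs(pop.frequencies - 0.006))]:.2e} vs "
          f"single-cell {psd.mean[np.argmin(np.abs(psd.frequencies - 0.006))]:.2e})")

args.out_dir.mkdir(parents=True, exist_ok=True)
pd.concat(psd_tables).to_csv(args.out_dir / "fret_psd.csv", index=False)
pd.concat(acf_tables).to_csv(args.out_dir / "fret_acf.csv", index=False)
pd.concat(pop_tables).to_csv(args.out_dir / "fret_population_psd.csv", index=False)
print(f"Wrote PSD/ACF tables to {args.out_dir}/")
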
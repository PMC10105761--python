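"""Single-cell FRET ratio fluctuation analysis.

Processes per-cell dual-channel (CFP/YFP) fluorescence time series
recorded at 1 Hz: camera dark-count subtraction, photobleaching
correction by fitting and dividing out an exponential (or linear)
decay, FRET ratio computation, a responsiveness filter against the
population response, windowing, a mean-normalised power spectral
density, an unbiased autocorrelation estimator, and Hill dose-response
fitting.  Single-channel traces (e.g. NAD(P)H autofluorescence) go
through the same windowing/PSD/autocorrelation path.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy import optimize

__all__ = [
    "DARK_COUNT",
    "FluorescenceTrace",
    "RatioTrace",
    "SpectralResult",
    "AutocorrResult",
    "DoseResponseFit",
    "subtract_dark_count",
    "correct_bleaching",
    "compute_ratio",
    "filter_responsive",
    "select_window",
    "compute_psd",
    "compute_autocorrelation",
    "fit_dose_response",
]

#: EM-CCD camera offset, counts.
DARK_COUNT = 106.0
#: Floor applied to channel values that fall to or below zero after
#: dark-count subtraction.
POSITIVE_FLOOR = 1e-6
#: Default analysis window: 800 frames starting 50 s after stimulation.
WINDOW_FRAMES = 800
WINDOW_OFFSET = 50.0


@dataclass(frozen=True)
class FluorescenceTrace:
    """Per-cell fluorescence time series, one or two channels.

    ``yfp`` is ``None`` in single-channel mode (autofluorescence).
    """

    cell_id: str
    times: np.ndarray   # s, uniform grid k*dt
    cfp: np.ndarray     # camera counts
    yfp: np.ndarray | None = None

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        if t.size < 2:
            raise ValueError("trace needs at least 2 frames")
        steps = np.diff(t)
        if not np.allclose(steps, steps[0], rtol=1e-6, atol=1e-9):
            raise ValueError(f"cell {self.cell_id}: non-uniform sampling interval")
        if len(self.cfp) != t.size or (self.yfp is not None and len(self.yfp) != t.size):
            raise ValueError(f"cell {self.cell_id}: channel/timestamp length mismatch")

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0])

    @property
    def single_channel(self) -> bool:
        return self.yfp is None


@dataclass(frozen=True)
class RatioTrace:
    """Dimensionless FRET ratio per frame for one cell."""

    cell_id: str
    times: np.ndarray
    ratio: np.ndarray
    numerator: str = "cfp"
    denominator: str = "yfp"

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0])


@dataclass(frozen=True)
class SpectralResult:
    """Mean-normalised PSD per cell and averaged over cells.

    Frequencies are q/(N dt) Hz for q = 1..N/2 (DC excluded).  The PSD
    of cell j at bin q is |r~_qj|^2 / rbar_j^2 * dt/N where r~ is the
    DFT of the raw (not mean-subtracted) window and rbar its time mean.
    """

    frequencies: np.ndarray      # Hz
    per_cell: np.ndarray         # shape (n_cells, N/2)
    mean: np.ndarray
    sem: np.ndarray
    n_frames: int
    dt: float


@dataclass(frozen=True)
class AutocorrResult:
    """Cell-averaged unbiased autocorrelation of the ratio fluctuations."""

    lags: np.ndarray             # s
    per_cell: np.ndarray         # shape (n_cells, n_lags)
    mean: np.ndarray


@dataclass(frozen=True)
class DoseResponseFit:
    """Hill-model fit Y = A L^H / (L^H + K^H)."""

    amplitude: float   # A
    hill: float        # H
    ec50: float        # K, in the units of the supplied concentrations
    residual_norm: float

    def predict(self, concentrations) -> np.ndarray:
        L = np.asarray(concentrations, dtype=float)
        return self.amplitude * L**self.hill / (L**self.hill + self.ec50**self.hill)


def subtract_dark_count(
    trace: FluorescenceTrace, dark: float = DARK_COUNT
) -> FluorescenceTrace:
    """Remove the camera offset from every channel.

    Values that end up at or below zero are clipped to a small positive
    floor (a warning is raised); downstream corrections divide by the
    channels.
    """

    def shift(channel):
        if channel is None:
            return None
        out = np.asarray(channel, dtype=float) - dark
        low = out < POSITIVE_FLOOR
        if np.any(low):
            warnings.warn(
                f"cell {trace.cell_id}: {int(low.sum())} frames at or below the "
                "dark count; clipped to the positive floor"
            )
            out = np.where(low, POSITIVE_FLOOR, out)
        return out

    return replace(trace, cfp=shift(trace.cfp), yfp=shift(trace.yfp))


def _fit_exponential(t, y):
    """Least-squares fit of a*exp(-b t) + c; returns (params, stderr of b)."""
    # linear-regression-seeded start: slope sign sets the initial decay
    a0 = max(y[0] - y[-1], 1e-3 * abs(y.mean()) + 1e-12)
    b0 = 1.0 / max(t[-1] - t[0], 1.0)
    c0 = y[-1]
    popt, pcov = optimize.curve_fit(
        lambda tt, a, b, c: a * np.exp(-b * tt) + c,
        t, y, p0=(a0, b0, c0), maxfev=10000,
    )
    berr = float(np.sqrt(pcov[1, 1])) if np.all(np.isfinite(pcov)) else np.inf
    return popt, berr


def correct_bleaching(
    channel: np.ndarray,
    times: np.ndarray,
    stim_window: tuple[int, int],
    model: str | None = None,
) -> np.ndarray:
    """Divide out the photobleaching trend fitted on the stimulated segment.

    ``model`` is ``"exponential"`` (f = a exp(-b t) + c), ``"linear"``
    (f = a - b t), or ``None`` for automatic choice: exponential unless
    the fitted decay rate is statistically indistinguishable from zero
    (|b| < 2 standard errors), in which case the bleaching is low and a
    straight line is used.  A non-convergent exponential fit falls back
    to linear with a warning.
    """
    channel = np.asarray(channel, dtype=float)
    times = np.asarray(times, dtype=float)
    i0, i1 = stim_window
    if i1 - i0 < 10:
        raise ValueError("stimulated segment must span at least 10 frames")
    if np.any(channel <= 0):
        raise ValueError("channel must be strictly positive (subtract dark count first)")
    t_fit, y_fit = times[i0:i1], channel[i0:i1]

    if model not in (None, "exponential", "linear"):
        raise ValueError(f"unknown bleach model {model!r}")

    fitted = None
    if model in (None, "exponential"):
        try:
            (a, b, c), berr = _fit_exponential(t_fit, y_fit)
            if model is None and abs(b) < 2.0 * berr:
                fitted = None  # low bleaching: fall through to linear
            else:
                fitted = a * np.exp(-b * times) + c
        except RuntimeError:
            if model == "exponential":
                warnings.warn("exponential bleach fit did not converge; using linear")
            fitted = None
    if fitted is None:
        slope, intercept = np.polyfit(t_fit, y_fit, 1)
        fitted = intercept + slope * times
    if np.any(fitted <= 0):
        raise ValueError("fitted bleach curve crosses zero inside the trace")
    return channel / fitted


def compute_ratio(trace: FluorescenceTrace, numerator: str = "cfp") -> RatioTrace:
    """FRET ratio per frame; ``numerator`` selects which channel is on top.

    The pyruvate sensor reports as corrected CFP over corrected YFP;
    sensors with the opposite sign convention (e.g. the PTS interaction
    pair) use ``numerator="yfp"``.
    """
    if trace.single_channel:
        raise ValueError("ratio undefined for single-channel traces")
    if numerator not in ("cfp", "yfp"):
        raise ValueError("numerator must be 'cfp' or 'yfp'")
    num = trace.cfp if numerator == "cfp" else trace.yfp
    den = trace.yfp if numerator == "cfp" else trace.cfp
    if np.any(den == 0):
        raise ZeroDivisionError(f"cell {trace.cell_id}: zero denominator channel")
    return RatioTrace(
        cell_id=trace.cell_id,
        times=trace.times,
        ratio=np.asarray(num, float) / np.asarray(den, float),
        numerator=numerator,
        denominator="yfp" if numerator == "cfp" else "cfp",
    )


# plateau windows (frames relative to the stimulus) used to measure the
# per-cell step response
PRE_PLATEAU_FRAMES = 60
POST_PLATEAU_RANGE = (120, 180)


def _step_response(ratio: RatioTrace, stimulus_time: float) -> float:
    k_stim = int(np.searchsorted(ratio.times, stimulus_time))
    pre = ratio.ratio[max(k_stim - PRE_PLATEAU_FRAMES, 0):k_stim]
    post = ratio.ratio[k_stim + POST_PLATEAU_RANGE[0]: k_stim + POST_PLATEAU_RANGE[1]]
    if pre.size == 0 or post.size == 0:
        raise ValueError(f"cell {ratio.cell_id}: trace too short around the stimulus")
    return float(post.mean() - pre.mean())


def filter_responsive(
    cells: list[RatioTrace],
    stimulus_time: float,
    threshold_fraction: float = 0.10,
    population_response: float | None = None,
) -> tuple[list[RatioTrace], float, dict[str, float]]:
    """Drop cells whose FRET step is below 10% of the population response.

    The per-cell response is the difference between post- and
    pre-stimulus plateau means; the population response defaults to the
    mean per-cell response.  A cell is kept iff |response| >=
    threshold_fraction * |population response| (boundary inclusive).
    Returns (kept cells, unresponsive fraction, per-cell responses); a
    warning is raised when more than 15% of cells are unresponsive.
    """
    responses = {c.cell_id: _step_response(c, stimulus_time) for c in cells}
    if population_response is None:
        population_response = float(np.mean(list(responses.values())))
    if population_response == 0:
        raise ValueError("population response is zero; cannot filter")
    # boundary inclusive, robust to float rounding of the plateau means
    cutoff = threshold_fraction * abs(population_response) * (1.0 - 1e-9)
    kept = [c for c in cells if abs(responses[c.cell_id]) >= cutoff]
    if not kept:
        raise ValueError("no responsive cells left after filtering")
    unresponsive = 1.0 - len(kept) / len(cells)
    if unresponsive > 0.15:
        warnings.warn(
            f"{unresponsive:.0%} of cells unresponsive (> 15%); "
            "check stimulus delivery or sensor expression"
        )
    return kept, unresponsive, responses


def select_window(
    ratio: RatioTrace,
    stimulus_time: float,
    offset: float = WINDOW_OFFSET,
    n_frames: int = WINDOW_FRAMES,
) -> np.ndarray:
    """Contiguous ``n_frames``-long segment starting ``offset`` s after the stimulus."""
    start = int(np.searchsorted(ratio.times, stimulus_time + offset))
    available = ratio.ratio.size - start
    if available < n_frames:
        raise ValueError(
            f"cell {ratio.cell_id}: window needs {n_frames} frames, "
            f"only {max(available, 0)} available ({n_frames - available} short)"
        )
    return ratio.ratio[start: start + n_frames]


def compute_psd(windows: np.ndarray, dt: float = 1.0) -> SpectralResult:
    """Mean-normalised power spectral density, averaged over cells.

    ``windows`` has one row per cell (equal even length N).  Per cell,
    the periodogram |DFT|^2 of the raw window is divided by the squared
    time mean and scaled by dt/N; bins q = 1..N/2 are reported at
    frequencies q/(N dt).  The cell average carries the standard error
    of the mean over cells.
    """
    windows = np.atleast_2d(np.asarray(windows, dtype=float))
    n = windows.shape[1]
    if n % 2 != 0:
        raise ValueError("window length must be even")
    means = windows.mean(axis=1)
    if np.any(means == 0):
        raise ValueError("zero-mean window; PSD normalisation undefined")
    spectra = np.fft.rfft(windows, axis=1)       # q = 0..N/2
    power = np.abs(spectra[:, 1:]) ** 2           # drop DC
    per_cell = power / means[:, None] ** 2 * dt / n
    mean = per_cell.mean(axis=0)
    n_cells = per_cell.shape[0]
    sem = (per_cell.std(axis=0, ddof=1) / np.sqrt(n_cells)
           if n_cells > 1 else np.zeros_like(mean))
    freqs = np.arange(1, n // 2 + 1) / (n * dt)
    return SpectralResult(
        frequencies=freqs, per_cell=per_cell, mean=mean, sem=sem,
        n_frames=n, dt=dt,
    )


def compute_autocorrelation(
    windows: np.ndarray, dt: float = 1.0, max_lag: int | None = None
) -> AutocorrResult:
    """Unbiased autocorrelation of the mean-subtracted ratio, cell-averaged.

    Per cell, C_j(m) = sum_k dr_{k+m} dr_k / ((N - m) * var(dr)) where
    dr is the window minus its time mean and var its population
    variance, so C_j(0) = 1 exactly; the result is averaged over cells.
    """
    windows = np.atleast_2d(np.asarray(windows, dtype=float))
    n = windows.shape[1]
    if n < 2:
        raise ValueError("window must have at least 2 frames")
    if max_lag is None:
        max_lag = n - 1
    delta = windows - windows.mean(axis=1, keepdims=True)
    variances = np.mean(delta**2, axis=1)
    if np.any(variances == 0):
        raise ValueError("zero-variance window; autocorrelation undefined")
    # full linear autocorrelation via FFT, one row per cell
    nfft = 2 ** int(np.ceil(np.log2(2 * n - 1)))
    fts = np.fft.rfft(delta, nfft, axis=1)
    acov = np.fft.irfft(fts * np.conj(fts), nfft, axis=1)[:, : max_lag + 1]
    lags = np.arange(max_lag + 1)
    per_cell = acov / ((n - lags)[None, :] * variances[:, None])
    return AutocorrResult(
        lags=lags * dt, per_cell=per_cell, mean=per_cell.mean(axis=0)
    )


def fit_dose_response(
    concentrations,
    responses,
    normalized: bool = False,
) -> DoseResponseFit:
    """Nonlinear least-squares fit of the Hill model Y = A L^H/(L^H + K^H).

    With ``normalized=True`` the amplitude is pinned to A = 1 and only
    (H, K) are fitted.  K (the EC50) is returned in the units of the
    supplied concentrations.
    """
    L = np.asarray(concentrations, dtype=float)
    Y = np.asarray(responses, dtype=float)
    if np.unique(L).size < 3:
        raise ValueError("need at least 3 distinct concentrations")
    if np.any(L <= 0):
        raise ValueError("concentrations must be positive")
    k0 = float(np.exp(np.mean(np.log(L))))  # geometric-mean start for the EC50

    def hill(LL, A, H, K):
        return A * LL**H / (LL**H + K**H)

    try:
        if normalized:
            popt, _ = optimize.curve_fit(
                lambda LL, H, K: hill(LL, 1.0, H, K), L, Y,
                p0=(1.0, k0), bounds=([1e-6, 1e-12], [50.0, np.inf]),
                maxfev=20000,
            )
            A, (H, K) = 1.0, popt
        else:
            popt, _ = optimize.curve_fit(
                hill, L, Y,
                p0=(float(Y.max()) or 1.0, 1.0, k0),
                bounds=([-np.inf, 1e-6, 1e-12], [np.inf, 50.0, np.inf]),
                maxfev=20000,
            )
            A, H, K = popt
    except RuntimeError as exc:
        raise RuntimeError(f"Hill fit did not converge: {exc}") from exc
    residual = float(np.linalg.norm(Y - hill(L, A, H, K)))
    return DoseResponseFit(
        amplitude=float(A), hill=float(H), ec50=float(K), residual_norm=residual
    )
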
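"""Heart-rate and respiratory sinus arrhythmia (RSA) analysis.

Input is a series of heartbeat times. Inter-beat intervals (IBIs) outside
the physiological range [250, 1500] ms (heart rate outside [40, 240] BPM)
are treated as artifacts; the surviving instantaneous heart rate is
interpolated to a 1 ms grid with a modified Akima cubic Hermite
interpolant. RSA strength is estimated from multitaper spectra of the
instantaneous heart rate in sliding 60 s windows: each window's spectrum
is normalized to unit area over the respiratory band 0.25–0.5 Hz
(15–30 breaths/min), the power around the dominant respiratory peak is
averaged, and the per-window values are normalized across windows as
(P − μ)/μ with μ the median window power.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats
from scipy.interpolate import Akima1DInterpolator
from scipy.signal import find_peaks, peak_widths
from scipy.signal.windows import dpss

from .synthgen import SessionRecord, StimEvent, block_extents, AIRFLOW, TOUCH

__all__ = [
    "HeartbeatSeries",
    "RSAResult",
    "clean_heartbeats",
    "rsa_strength",
    "block_hr_means",
    "block_rsa_means",
    "compare_blocks",
]

IBI_MIN_MS = 250.0
IBI_MAX_MS = 1500.0
HR_GRID_STEP = 0.001  # 1 ms


@dataclass
class HeartbeatSeries:
    """Cleaned heartbeat series with interpolated instantaneous heart rate."""

    beat_times: np.ndarray  # kept beats (s)
    ibi_ms: np.ndarray  # successive differences of beat_times (ms)
    hr_times: np.ndarray  # 1 ms grid (s)
    hr_instant: np.ndarray  # BPM on the grid

    @property
    def duration(self) -> float:
        return float(self.hr_times[-1] - self.hr_times[0])


def clean_heartbeats(beat_times: np.ndarray) -> HeartbeatSeries:
    """Remove artifactual beats and interpolate heart rate to a 1 ms grid.

    Beats terminating an IBI shorter than 250 ms are dropped (scanned
    greedily so cascaded artifacts are handled); IBIs longer than 1500 ms
    are treated as gaps — the beats are kept but the corresponding HR
    samples are excluded from the interpolation support. Boundary values
    (exactly 250 or 1500 ms, i.e. 240 or 40 BPM) are retained.
    """
    beats = np.asarray(beat_times, dtype=float)
    if beats.ndim != 1 or beats.size < 3:
        raise ValueError("need at least 3 heartbeat times")
    if np.any(np.diff(beats) < 0):
        raise ValueError("beat times must be sorted")

    kept = [beats[0]]
    for t in beats[1:]:
        if (t - kept[-1]) * 1000.0 >= IBI_MIN_MS:
            kept.append(t)
    kept = np.asarray(kept)
    ibi_ms = np.diff(kept) * 1000.0

    valid = ibi_ms <= IBI_MAX_MS  # short ones already removed; inclusive bounds
    t_samp = kept[1:][valid]
    hr_samp = 60000.0 / ibi_ms[valid]
    if t_samp.size < 3:
        raise ValueError("fewer than 3 valid beats after cleaning; series unusable")

    n_grid = int(np.floor((t_samp[-1] - t_samp[0]) / HR_GRID_STEP)) + 1
    grid = t_samp[0] + HR_GRID_STEP * np.arange(n_grid)
    interp = Akima1DInterpolator(t_samp, hr_samp, method="makima")
    hr = interp(np.clip(grid, t_samp[0], t_samp[-1]))
    return HeartbeatSeries(beat_times=kept, ibi_ms=ibi_ms, hr_times=grid, hr_instant=hr)


@dataclass
class RSAResult:
    """Sliding-window RSA strength for one session."""

    window_centers: np.ndarray  # s
    strength: np.ndarray  # normalized (P - mu) / mu, unitless
    raw: np.ndarray  # band power before cross-window normalization
    mu: float
    window: float
    hop: float
    n_tapers: int


def _window_psd_band(
    x: np.ndarray, fs: float, tapers: np.ndarray, band: tuple[float, float]
) -> tuple[np.ndarray, np.ndarray]:
    """Multitaper PSD restricted to `band`, normalized to unit area there."""
    x = x - x.mean()
    spec = np.fft.rfft(tapers * x[None, :], axis=1)
    psd = (np.abs(spec) ** 2).mean(axis=0)
    f = np.fft.rfftfreq(x.size, 1.0 / fs)
    m = (f >= band[0]) & (f <= band[1])
    fb, pb = f[m], psd[m]
    area = np.trapezoid(pb, fb)
    if area > 0:
        pb = pb / area
    return fb, pb


def _peak_band_power(fb: np.ndarray, pb: np.ndarray) -> float:
    """Average power around the dominant respiratory peak (± half-width).

    Falls back to the band average when the window's spectrum has no
    interior peak.
    """
    peaks, _ = find_peaks(pb)
    if peaks.size == 0:
        return float(pb.mean())
    widths, _, _, _ = peak_widths(pb, peaks, rel_height=0.5)
    best = int(np.argmax(pb[peaks]))
    df = fb[1] - fb[0]
    f_peak = fb[peaks[best]]
    half = widths[best] * df / 2.0
    m = (fb >= f_peak - half) & (fb <= f_peak + half)
    return float(pb[m].mean())


def rsa_strength(
    hbs: HeartbeatSeries,
    window: float = 60.0,
    hop: float = 3.0,
    n_tapers: int = 7,
    nw: float = 4.0,
    band: tuple[float, float] = (0.25, 0.5),
    mu_mode: str = "median",
) -> RSAResult:
    """Sliding-window multitaper RSA strength of instantaneous heart rate.

    ``hop`` is the window step: consecutive 60 s windows share 57 s by
    default. ``mu_mode`` selects the cross-window normalization constant:
    the median window power (default) or their sum.
    """
    fs = 1.0 / HR_GRID_STEP
    n_win = int(round(window * fs))
    x = hbs.hr_instant
    if x.size < n_win:
        raise ValueError("series shorter than one analysis window")
    if mu_mode not in ("median", "sum"):
        raise ValueError("mu_mode must be 'median' or 'sum'")
    tapers = dpss(n_win, nw, Kmax=n_tapers)
    step = int(round(hop * fs))
    starts = np.arange(0, x.size - n_win + 1, step)
    raw = np.empty(starts.size)
    centers = np.empty(starts.size)
    for i, s in enumerate(starts):
        fb, pb = _window_psd_band(x[s : s + n_win], fs, tapers, band)
        raw[i] = _peak_band_power(fb, pb)
        centers[i] = hbs.hr_times[s] + window / 2.0
    mu = float(np.median(raw)) if mu_mode == "median" else float(raw.sum())
    # degenerate series (e.g. perfectly flat heart rate) have zero power
    strength = (raw - mu) / mu if mu != 0 else np.zeros_like(raw)
    return RSAResult(
        window_centers=centers, strength=strength, raw=raw, mu=mu,
        window=window, hop=hop, n_tapers=n_tapers,
    )


def _means_by_block_type(
    times: np.ndarray, values: np.ndarray, stim_events: Sequence[StimEvent]
) -> dict[str, float]:
    out: dict[str, list[np.ndarray]] = {AIRFLOW: [], TOUCH: []}
    for t0, t1, _, btype in block_extents(stim_events):
        m = (times >= t0) & (times < t1)
        if m.any():
            out[btype].append(values[m])
    return {k: float(np.concatenate(v).mean()) for k, v in out.items() if v}


def block_hr_means(hbs: HeartbeatSeries, stim_events: Sequence[StimEvent]) -> dict[str, float]:
    """Mean instantaneous heart rate (BPM) per block type."""
    return _means_by_block_type(hbs.hr_times, hbs.hr_instant, stim_events)


def block_rsa_means(rsa: RSAResult, stim_events: Sequence[StimEvent]) -> dict[str, float]:
    """Mean normalized RSA strength per block type (windows by center time)."""
    return _means_by_block_type(rsa.window_centers, rsa.strength, stim_events)


def compare_blocks(
    touch_values: Sequence[float],
    airflow_values: Sequence[float],
    alternative: str = "greater",
) -> dict:
    """One-sided paired t-test across sessions (touch vs. airflow).

    ``alternative='greater'`` tests touch > airflow (the RSA contrast);
    use ``'less'`` for the heart-rate contrast (grooming lowers heart
    rate). Identical pairs give t = 0 and p = 0.5 by convention.
    """
    a = np.asarray(touch_values, float)
    b = np.asarray(airflow_values, float)
    if a.shape != b.shape:
        raise ValueError("mismatched per-session value lists")
    if a.size < 2:
        raise ValueError("paired t-test needs at least 2 sessions")
    diffs = a - b
    if np.allclose(diffs, 0.0):
        return {"t": 0.0, "p": 0.5, "n": int(a.size), "mean_diff": 0.0}
    res = stats.ttest_rel(a, b, alternative=alternative)
    return {
        "t": float(res.statistic),
        "p": float(res.pvalue),
        "n": int(a.size),
        "mean_diff": float(diffs.mean()),
    }


def session_autonomic_summary(session: SessionRecord, **rsa_kw) -> dict:
    """Clean heartbeats and report per-block-type HR and RSA means."""
    hbs = clean_heartbeats(session.heartbeats)
    rsa = rsa_strength(hbs, **rsa_kw)
    return {
        "hr": block_hr_means(hbs, session.stim_events),
        "rsa": block_rsa_means(rsa, session.stim_events),
    }
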
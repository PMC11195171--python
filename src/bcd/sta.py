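"""Spike-triggered averages of baseline LFP and their power spectra.

For each unit, LFP snippets of ±80 ms are cut around every spike that
falls inside an extracted baseline window (with full context inside the
session) and averaged per block label. The STA spectrum is the average of
per-snippet Welch periodograms (Hann window) — the conditional expectation
of LFP power given that a spike occurred during baseline. Per-nucleus mean
STAs (mSTA) are pointwise means over the units recorded in that nucleus.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import signal as sps

from .baselines import BaselineWindow
from .synthgen import SessionRecord

__all__ = [
    "STAResult",
    "collect_snippets",
    "spike_triggered_average",
    "sta_spectrum",
    "mean_sta",
]

PAD = 0.080  # s of LFP context on each side of a spike


@dataclass
class STAResult:
    """Spike-triggered average and spectrum for one unit (one label)."""

    lags: np.ndarray  # s, symmetric about 0
    sta: np.ndarray  # µV
    n_spikes: int
    spectrum_freqs: np.ndarray
    spectrum: np.ndarray
    unit: int = -1
    channel: int = -1
    nucleus: str = ""
    label: str = ""


def collect_snippets(
    session: SessionRecord,
    windows: Sequence[BaselineWindow],
    unit: int,
    pad: float = PAD,
) -> dict[str, np.ndarray]:
    """±pad LFP snippets around baseline spikes of one unit, per label.

    A spike qualifies when it lies inside a baseline window extracted on
    the unit's own channel and the full ±pad context fits in the session.
    """
    train = session.spikes[unit]
    fs = session.fs
    half = int(round(pad * fs))
    n = session.lfp.shape[1]
    spans = [
        (w.t_start, w.t_end, w.label)
        for w in windows
        if w.channel == train.channel
    ]
    out: dict[str, list[np.ndarray]] = {}
    for t in train.times:
        i = int(round(t * fs))
        if i - half < 0 or i + half + 1 > n:
            continue
        for t0, t1, lab in spans:
            if t0 <= t <= t1:
                out.setdefault(lab, []).append(session.lfp[train.channel, i - half : i + half + 1])
                break
    return {k: np.asarray(v, float) for k, v in out.items()}


def sta_spectrum(
    snippets: np.ndarray,
    fs: float,
    nperseg: int | None = None,
    noverlap: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Average of per-snippet Welch periodograms (Hann window, 50% overlap).

    ``nperseg`` defaults to the snippet length (a single Hann-windowed
    segment per snippet), the only choice that resolves the 1–50 Hz band
    on ±80 ms snippets.
    """
    snippets = np.atleast_2d(np.asarray(snippets, float))
    if snippets.shape[0] < 1:
        raise ValueError("need at least one snippet")
    n = snippets.shape[1]
    if nperseg is None:
        nperseg = n
    if nperseg > n:
        raise ValueError(f"segment length {nperseg} exceeds snippet length {n}")
    if noverlap is None:
        noverlap = nperseg // 2
    f, psd = sps.welch(snippets, fs=fs, window="hann", nperseg=nperseg, noverlap=noverlap, axis=1)
    return f, psd.mean(axis=0)


def spike_triggered_average(
    session: SessionRecord,
    windows: Sequence[BaselineWindow],
    unit: int,
    pad: float = PAD,
) -> dict[str, STAResult]:
    """Per-label STA (and STA spectrum) of one unit's baseline spikes.

    Labels with no qualifying spikes are absent from the result; an empty
    dict means the unit never fired inside a baseline window.
    """
    fs = session.fs
    half = int(round(pad * fs))
    lags = np.arange(-half, half + 1) / fs
    snips = collect_snippets(session, windows, unit, pad)
    out: dict[str, STAResult] = {}
    for lab, arr in snips.items():
        f, psd = sta_spectrum(arr, fs)
        out[lab] = STAResult(
            lags=lags,
            sta=arr.mean(axis=0),
            n_spikes=arr.shape[0],
            spectrum_freqs=f,
            spectrum=psd,
            unit=unit,
            channel=session.spikes[unit].channel,
            nucleus=session.channel_nuclei[session.spikes[unit].channel],
            label=lab,
        )
    return out


def mean_sta(results: Sequence[STAResult]) -> STAResult:
    """Pointwise mean STA/spectrum over units (mSTA), e.g. within a nucleus."""
    if not results:
        raise ValueError("mean_sta needs at least one STAResult")
    r0 = results[0]
    for r in results[1:]:
        if r.lags.size != r0.lags.size or r.spectrum_freqs.size != r0.spectrum_freqs.size:
            raise ValueError("STA results have incompatible grids")
    return STAResult(
        lags=r0.lags.copy(),
        sta=np.mean([r.sta for r in results], axis=0),
        n_spikes=int(sum(r.n_spikes for r in results)),
        spectrum_freqs=r0.spectrum_freqs.copy(),
        spectrum=np.mean([r.spectrum for r in results], axis=0),
        nucleus=r0.nucleus if len({r.nucleus for r in results}) == 1 else "",
        label=r0.label if len({r.label for r in results}) == 1 else "",
    )
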
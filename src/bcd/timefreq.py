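"""Wavelet spectrograms of baseline windows.

Each baseline LFP segment is turned into a time × frequency power image
with a continuous wavelet transform using a complex Morlet mother wavelet
of central frequency ω0 = 5 (a standard balance of temporal and spectral
resolution), evaluated on a 1–50 Hz grid. Power is the squared modulus of
the transform, amplitude-normalized so that equal-amplitude tones at
different frequencies produce equal power. A dataset-level min–max scaler
(fit on the training set only, to avoid leaking test statistics into the
classifier) maps each spectrogram pixel to [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pywt
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.exceptions import NotFittedError

from .baselines import BaselineWindow

__all__ = [
    "WaveletConfig",
    "Spectrogram",
    "cwt_spectrogram",
    "spectrogram_stack",
    "restrict_band",
    "restrict_rows",
    "SpectrogramScaler",
]


@dataclass(frozen=True)
class WaveletConfig:
    """Complex-Morlet CWT parameters.

    ``f0`` is the wavelet's central (angular) frequency parameter ω0; the
    scale for an analysis frequency f is a = (ω0/2π)·fs/f, so the wavelet
    at scale a oscillates at f. The default grid spans 1–50 Hz at 1 Hz
    spacing.
    """

    f0: float = 5.0
    freqs: np.ndarray = field(default_factory=lambda: np.arange(1.0, 51.0))
    fs: float = 1000.0

    def __post_init__(self) -> None:
        f = np.asarray(self.freqs, float)
        if f.ndim != 1 or f.size == 0 or np.any(np.diff(f) <= 0) or f[0] <= 0:
            raise ValueError("freqs must be strictly increasing and positive")
        object.__setattr__(self, "freqs", f)

    @property
    def wavelet(self) -> str:
        # cmorB-C: bandwidth 2.0 and center C = f0/2π reproduce the
        # standard Morlet exp(-t²/2)·exp(i·f0·t)
        return f"cmor2.0-{self.f0 / (2 * np.pi):.8f}"

    @property
    def scales(self) -> np.ndarray:
        return (self.f0 / (2 * np.pi)) * self.fs / self.freqs


@dataclass
class Spectrogram:
    """Time × frequency power image of one baseline window."""

    power: np.ndarray  # (n_freqs, n_times), >= 0
    freqs: np.ndarray  # Hz
    times: np.ndarray  # s, relative to window start
    label: str
    channel: int = -1
    nucleus: str = ""
    block_id: int = -1


def cwt_spectrogram(
    window: BaselineWindow,
    cfg: WaveletConfig,
    time_decimation: int = 1,
) -> Spectrogram:
    """CWT power spectrogram of one baseline window.

    ``time_decimation`` block-averages the power image along time (by that
    factor) to reduce classifier input size; the physics is unchanged, only
    the temporal resolution of the image.
    """
    x = np.asarray(window.signal, float)
    coef, _ = pywt.cwt(x, cfg.scales, cfg.wavelet, sampling_period=1.0 / cfg.fs, method="fft")
    power = (np.abs(coef) ** 2) / cfg.scales[:, None]
    times = np.arange(x.size) / cfg.fs
    if time_decimation > 1:
        d = time_decimation
        n = (power.shape[1] // d) * d
        power = power[:, :n].reshape(power.shape[0], -1, d).mean(axis=2)
        times = times[:n].reshape(-1, d).mean(axis=1)
    return Spectrogram(
        power=power.astype(np.float32),
        freqs=cfg.freqs.copy(),
        times=times,
        label=window.label,
        channel=window.channel,
        nucleus=window.nucleus,
        block_id=window.block_id,
    )


def spectrogram_stack(
    windows: Sequence[BaselineWindow],
    cfg: WaveletConfig,
    time_decimation: int = 1,
) -> list[Spectrogram]:
    """Spectrograms for a batch of baseline windows (one vectorized CWT)."""
    if not windows:
        return []
    data = np.stack([np.asarray(w.signal, float) for w in windows])
    coef, _ = pywt.cwt(data, cfg.scales, cfg.wavelet, sampling_period=1.0 / cfg.fs,
                       method="fft", axis=-1)
    power = (np.abs(coef) ** 2) / cfg.scales[:, None, None]  # (F, n, T)
    power = np.transpose(power, (1, 0, 2)).astype(np.float32)
    times = np.arange(data.shape[1]) / cfg.fs
    if time_decimation > 1:
        d = time_decimation
        n = (power.shape[2] // d) * d
        power = power[:, :, :n].reshape(power.shape[0], power.shape[1], -1, d).mean(axis=3)
        times = times[:n].reshape(-1, d).mean(axis=1)
    return [
        Spectrogram(
            power=power[i],
            freqs=cfg.freqs.copy(),
            times=times,
            label=w.label,
            channel=w.channel,
            nucleus=w.nucleus,
            block_id=w.block_id,
        )
        for i, w in enumerate(windows)
    ]


def restrict_rows(
    power: np.ndarray, freqs: np.ndarray, lo: float, hi: float
) -> tuple[np.ndarray, np.ndarray]:
    """Select spectrogram rows with lo <= f <= hi (inclusive bounds)."""
    m = (freqs >= lo) & (freqs <= hi)
    if not m.any():
        raise ValueError(f"band [{lo}, {hi}] Hz does not intersect the frequency grid")
    return power[..., m, :], freqs[m]


def restrict_band(spec: Spectrogram, lo: float, hi: float) -> Spectrogram:
    """Spectrogram restricted to the [lo, hi] Hz band; provenance preserved."""
    power, freqs = restrict_rows(spec.power, spec.freqs, lo, hi)
    return Spectrogram(
        power=power,
        freqs=freqs,
        times=spec.times,
        label=spec.label,
        channel=spec.channel,
        nucleus=spec.nucleus,
        block_id=spec.block_id,
    )


class SpectrogramScaler(TransformerMixin, BaseEstimator):
    """Per-pixel min–max scaling of spectrogram stacks to [0, 1].

    Extrema are estimated from the training set only (``fit``); ``transform``
    clips values outside the training range to [0, 1]. Pixels that are
    constant across the training set map to 0. With ``per_pixel=False``
    each image is scaled by its own global min/max instead.

    Parameters
    ----------
    per_pixel : bool
        Scale each (frequency, time) pixel with its own training extrema
        (dataset-level scaler, the default) or each image independently.
    clip : bool
        Clip transformed values to [0, 1].
    """

    def __init__(self, per_pixel: bool = True, clip: bool = True):
        self.per_pixel = per_pixel
        self.clip = clip

    def fit(self, X: np.ndarray, y=None) -> "SpectrogramScaler":
        X = np.asarray(X)
        if self.per_pixel:
            self.data_min_ = X.min(axis=0)
            self.data_max_ = X.max(axis=0)
            rng = self.data_max_ - self.data_min_
            self.scale_ = np.where(rng > 0, 1.0 / np.where(rng > 0, rng, 1.0), 0.0)
        else:
            self.data_min_ = self.data_max_ = self.scale_ = None
        self.n_features_in_ = int(np.prod(X.shape[1:]))
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        if not hasattr(self, "n_features_in_"):
            raise NotFittedError("SpectrogramScaler must be fit before transform")
        X = np.asarray(X, dtype=np.float32)
        if self.per_pixel:
            out = (X - self.data_min_) * self.scale_
        else:
            mins = X.min(axis=tuple(range(1, X.ndim)), keepdims=True)
            maxs = X.max(axis=tuple(range(1, X.ndim)), keepdims=True)
            rng = np.where(maxs - mins > 0, maxs - mins, 1.0)
            out = np.where(maxs - mins > 0, (X - mins) / rng, 0.0)
        if self.clip:
            out = np.clip(out, 0.0, 1.0)
        return out.astype(np.float32)
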
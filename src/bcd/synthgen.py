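"""Synthetic recording sessions with the statistical structure of the experiment.

The experiment alternates blocks of non-social stimuli (computer-controlled
airflow to the face) with blocks of social grooming touch delivered by a
trusted human partner. Each block is a train of 1 s stimuli separated by
~4 s gaps; the analysis concerns the *baseline* activity between stimuli,
not the evoked responses. This module generates sessions — multichannel
LFP, heartbeat times, and spike trains — in which the only systematic
difference between block types is the injected context effect:

* elevated 10–17 Hz LFP power during touch blocks and elevated 17–25 Hz
  power during airflow blocks,
* lower heart rate and deeper respiratory sinus arrhythmia (RSA, a
  0.25–0.5 Hz parasympathetic modulation of heart rate) during touch.

Setting both band-power gains to 1 and equalizing the heart parameters
yields a null world with no context signal, which downstream decoders must
not be able to classify above chance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import signal

__all__ = [
    "BlockDesign",
    "EffectSpec",
    "StimEvent",
    "SpikeTrain",
    "SessionRecord",
    "make_schedule",
    "block_extents",
    "simulate_lfp",
    "simulate_heartbeats",
    "simulate_spikes",
    "simulate_session",
    "default_channel_map",
]

AIRFLOW = "airflow"
TOUCH = "touch"

#: anatomical labels for amygdala nuclei: lateral, basal, accessory basal,
#: central, paralaminar
NUCLEI = ("L", "B", "AB", "C", "Pl")


@dataclass(frozen=True)
class BlockDesign:
    """Stimulus schedule for one block type.

    Defaults reproduce the experimental paradigm: airflow blocks present an
    11-stimulus sequence repeated 10 times (110 presentations); touch
    blocks present 20 stimuli repeated 5 times (100 presentations); every
    stimulus lasts 1 s and successive stimuli are separated by ~4 s.
    """

    block_type: str
    n_per_sequence: int
    n_repeats: int
    stim_duration: float = 1.0
    inter_stim_gap: float = 4.0

    def __post_init__(self) -> None:
        if self.block_type not in (AIRFLOW, TOUCH):
            raise ValueError(f"unknown block_type {self.block_type!r}")
        if self.n_per_sequence < 1 or self.n_repeats < 1:
            raise ValueError("presentation counts must be positive")
        if self.stim_duration <= 0 or self.inter_stim_gap <= 0:
            raise ValueError("stimulus duration and gap must be positive")

    @property
    def n_presentations(self) -> int:
        return self.n_per_sequence * self.n_repeats

    @classmethod
    def airflow(cls, **kw) -> "BlockDesign":
        return cls(AIRFLOW, n_per_sequence=11, n_repeats=10, **kw)

    @classmethod
    def touch(cls, **kw) -> "BlockDesign":
        return cls(TOUCH, n_per_sequence=20, n_repeats=5, **kw)


@dataclass(frozen=True)
class EffectSpec:
    """Injected context effects and autonomic parameters.

    Band gains are power ratios (touch vs. airflow blocks) applied to the
    band-limited LFP component; ``gain = 1`` means no effect. Heart
    parameters are in BPM; RSA depths are the fractional amplitude of the
    respiratory modulation of instantaneous heart rate.
    """

    touch_band: tuple[float, float] = (10.0, 17.0)
    airflow_band: tuple[float, float] = (17.0, 25.0)
    touch_gain: float = 2.0
    airflow_gain: float = 2.0
    extra_bands: tuple[tuple[float, float, float, str], ...] = ()
    """Optional additional effects: (lo_hz, hi_hz, gain, block_type)."""
    burst_rate: float = 0.2
    burst_duration: float = 0.15
    background_exponent: float = 1.0
    hr_airflow: float = 130.0
    hr_touch: float = 110.0
    rsa_depth_airflow: float = 0.05
    rsa_depth_touch: float = 0.15
    resp_freq: float = 0.3
    hrv_noise: float = 0.02
    """Fractional SD of broadband (<1 Hz) heart-rate variability, the noise
    floor against which the respiratory peak is measured; 0 gives the
    deterministic constant-rate / pure-sinusoid limit."""

    def __post_init__(self) -> None:
        for g, name in ((self.touch_gain, "touch_gain"), (self.airflow_gain, "airflow_gain")):
            if g < 1.0:
                raise ValueError(f"{name} must be >= 1 (power gain factor)")
        for hr, name in ((self.hr_airflow, "hr_airflow"), (self.hr_touch, "hr_touch")):
            if not (40.0 < hr < 240.0):
                raise ValueError(f"{name}={hr} outside the physiological (40, 240) BPM range")
        if not (0.25 <= self.resp_freq <= 0.5):
            raise ValueError("resp_freq must lie in the respiratory band [0.25, 0.5] Hz")
        if self.burst_rate < 0 or self.burst_duration <= 0:
            raise ValueError("burst parameters must be non-negative / positive")
        if self.hrv_noise < 0:
            raise ValueError("hrv_noise must be non-negative")

    @classmethod
    def null(cls, **kw) -> "EffectSpec":
        """A context-free world: no band effects, identical autonomics."""
        kw.setdefault("touch_gain", 1.0)
        kw.setdefault("airflow_gain", 1.0)
        kw.setdefault("hr_airflow", 120.0)
        kw.setdefault("hr_touch", 120.0)
        kw.setdefault("rsa_depth_airflow", 0.1)
        kw.setdefault("rsa_depth_touch", 0.1)
        return cls(**kw)


@dataclass(frozen=True)
class StimEvent:
    onset: float
    offset: float
    block_id: int
    block_type: str


@dataclass(frozen=True)
class SpikeTrain:
    times: np.ndarray
    channel: int


@dataclass
class SessionRecord:
    """One simulated session: LFP, channel map, schedule, spikes, heartbeats."""

    lfp: np.ndarray  # (n_channels, n_samples), µV, float32
    fs: float
    channel_nuclei: list[str]
    stim_events: list[StimEvent]
    spikes: list[SpikeTrain] = field(default_factory=list)
    heartbeats: np.ndarray = field(default_factory=lambda: np.empty(0))
    seed: int | None = None

    @property
    def n_channels(self) -> int:
        return self.lfp.shape[0]

    @property
    def duration(self) -> float:
        return self.lfp.shape[1] / self.fs

    def validate(self) -> None:
        if not np.all(np.isfinite(self.lfp)):
            raise ValueError("LFP contains non-finite values")
        if self.fs < 200.0:
            raise ValueError("fs must be >= 200 Hz for a 1-50 Hz analysis band")
        onsets = [e.onset for e in self.stim_events]
        if any(b <= a for a, b in zip(onsets, onsets[1:])):
            raise ValueError("stim_events must be strictly increasing")
        for a, b in zip(self.stim_events, self.stim_events[1:]):
            if b.onset < a.offset:
                raise ValueError("stim_events overlap")
        dur = self.duration
        for st in self.spikes:
            if st.times.size and (st.times.min() < 0 or st.times.max() > dur):
                raise ValueError("spike times outside session")
        if self.heartbeats.size and (self.heartbeats.min() < 0 or self.heartbeats.max() > dur):
            raise ValueError("heartbeat times outside session")


def default_channel_map(n_channels: int = 32) -> list[str]:
    """Assign channels to nuclei along a linear V-probe.

    The 32-contact probe spans the dorso-ventral extent of the amygdala;
    contacts are split into four contiguous groups mimicking passage
    through the central, lateral, basal and accessory basal nuclei.
    """
    groups = ("C", "L", "B", "AB")
    per = max(1, n_channels // len(groups))
    labels = []
    for g in groups:
        labels.extend([g] * per)
    # remainder goes to the deepest group
    labels.extend(["AB"] * (n_channels - len(labels)))
    return labels[:n_channels]


def make_schedule(
    designs: Sequence[BlockDesign],
    inter_block_gap: float = 120.0,
    t_start: float = 5.0,
) -> list[StimEvent]:
    """Lay out alternating blocks of stimuli as absolute-time events.

    Each block contributes exactly ``n_per_sequence * n_repeats`` events;
    blocks are separated by ``inter_block_gap`` seconds (a few minutes
    elapse between blocks in the experiment).
    """
    if not designs:
        raise ValueError("designs must be non-empty")
    if inter_block_gap <= 0 or t_start < 0:
        raise ValueError("gaps must be positive")
    events: list[StimEvent] = []
    t = t_start
    for block_id, d in enumerate(designs):
        for _ in range(d.n_presentations):
            events.append(StimEvent(t, t + d.stim_duration, block_id, d.block_type))
            t += d.stim_duration + d.inter_stim_gap
        t += inter_block_gap - d.inter_stim_gap
    return events


def block_extents(stim_events: Sequence[StimEvent], margin: float = 2.0) -> list[tuple[float, float, int, str]]:
    """(t0, t1, block_id, block_type) spans covering each block ± margin."""
    out = []
    for bid in sorted({e.block_id for e in stim_events}):
        ev = [e for e in stim_events if e.block_id == bid]
        out.append((ev[0].onset - margin, ev[-1].offset + margin, bid, ev[0].block_type))
    return out


def _fast_len(n: int) -> int:
    """Smallest 5-smooth integer >= n (keeps the FFTs fast)."""
    m = n
    while True:
        k = m
        for p in (2, 3, 5):
            while k % p == 0:
                k //= p
        if k == 1:
            return m
        m += 1


def _spectral_noise(
    rng: np.random.Generator, n: int, fs: float, shaping
) -> tuple[np.ndarray, np.ndarray]:
    """Gaussian noise synthesized in the frequency domain.

    ``shaping(f)`` gives the amplitude-spectrum weight per rfft bin.
    Returns the time-domain signal (length n, unit variance where the
    shaping is non-degenerate) and the squared shaping (∝ per-bin power),
    from which band-power fractions can be read off without further FFTs.
    """
    n_fft = _fast_len(n)
    f = np.fft.rfftfreq(n_fft, 1.0 / fs)
    amp = np.asarray(shaping(f), float)
    amp[0] = 0.0
    spec = amp * (rng.standard_normal(f.size) + 1j * rng.standard_normal(f.size))
    x = np.fft.irfft(spec, n_fft)[:n]
    s = x.std()
    if s > 0:
        x = x / s
    return x, amp**2


def _band_fraction(power: np.ndarray, n_fft_freqs: np.ndarray, lo: float, hi: float) -> float:
    """Fraction of total variance lying in [lo, hi] Hz, from per-bin power."""
    total = power.sum()
    if total == 0:
        return 0.0
    m = (n_fft_freqs >= lo) & (n_fft_freqs <= hi)
    return float(power[m].sum() / total)


def simulate_lfp(
    schedule: Sequence[StimEvent],
    channel_nuclei: Sequence[str],
    effect: EffectSpec,
    fs: float = 1000.0,
    seed: int | np.random.SeedSequence = 0,
    background_std: float = 50.0,
    stim_transient_std: float = 25.0,
    highpass: float = 0.5,
    tail: float = 5.0,
) -> SessionRecord:
    """Simulate multichannel LFP for a stimulus schedule.

    The signal is 1/f background noise plus (i) band-limited context
    modulation applied throughout each block (the latent state persists
    across the whole block, not just the baselines), (ii) Poisson-timed
    oscillatory bursts independent of context, and (iii) brief broadband
    transients during each stimulus, identical for both stimulus types so
    that evoked activity carries no context information.

    ``highpass`` truncates the 1/f background below the given frequency,
    emulating the AC coupling of extracellular recording hardware. Without
    it, 1/f components with periods comparable to the block length would
    make the two block types distinguishable even with no injected effect
    (the noise, not the brain state, would carry block identity).
    """
    if not schedule:
        raise ValueError("schedule must be non-empty")
    if fs < 200.0:
        raise ValueError("fs must be >= 200 Hz")
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    n_channels = len(channel_nuclei)
    duration = schedule[-1].offset + tail
    n = int(round(duration * fs))
    t = np.arange(n) / fs

    extents = block_extents(schedule)
    masks = {AIRFLOW: np.zeros(n, bool), TOUCH: np.zeros(n, bool)}
    for t0, t1, _, btype in extents:
        i0, i1 = max(0, int(t0 * fs)), min(n, int(t1 * fs))
        masks[btype][i0:i1] = True

    band_effects: list[tuple[float, float, float, str]] = [
        (*effect.touch_band, effect.touch_gain, TOUCH),
        (*effect.airflow_band, effect.airflow_gain, AIRFLOW),
        *effect.extra_bands,
    ]

    lfp = np.empty((n_channels, n), dtype=np.float32)
    child_seeds = ss.spawn(n_channels)
    freqs_fft = np.fft.rfftfreq(_fast_len(n), 1.0 / fs)
    alpha = effect.background_exponent
    for ch in range(n_channels):
        rng = np.random.default_rng(child_seeds[ch])

        def pink_shape(f, alpha=alpha):
            a = np.zeros_like(f)
            m = f >= max(highpass, f[1] if f.size > 1 else 0.0)
            a[m] = f[m] ** (-alpha / 2.0)
            return a

        bg, bin_power = _spectral_noise(rng, n, fs, pink_shape)
        bg = bg * background_std
        x = bg.copy()
        for lo, hi, gain, btype in band_effects:
            if gain == 1.0:
                continue
            base_var = _band_fraction(bin_power, freqs_fft, lo, hi) * background_std**2
            extra, _ = _spectral_noise(rng, n, fs, lambda f: (f >= lo) & (f <= hi))
            extra = extra * math.sqrt((gain - 1.0) * base_var)
            x[masks[btype]] += extra[masks[btype]]
        # context-independent oscillatory bursts
        n_bursts = rng.poisson(effect.burst_rate * duration)
        half = effect.burst_duration / 2.0
        for _ in range(n_bursts):
            tc = rng.uniform(0, duration)
            fb = rng.uniform(5.0, 45.0)
            i0, i1 = max(0, int((tc - 3 * half) * fs)), min(n, int((tc + 3 * half) * fs))
            if i1 <= i0:
                continue
            tt = t[i0:i1] - tc
            x[i0:i1] += (2.0 * background_std) * np.exp(-(tt**2) / (2 * half**2)) * np.cos(
                2 * np.pi * fb * tt + rng.uniform(0, 2 * np.pi)
            )
        # stimulus-evoked broadband transients (same for both types)
        if stim_transient_std > 0:
            stim_mask = np.zeros(n, bool)
            for e in schedule:
                stim_mask[int(e.onset * fs) : min(n, int(e.offset * fs))] = True
            x[stim_mask] += rng.standard_normal(int(stim_mask.sum())) * stim_transient_std
        lfp[ch] = x.astype(np.float32)

    rec = SessionRecord(
        lfp=lfp,
        fs=fs,
        channel_nuclei=list(channel_nuclei),
        stim_events=list(schedule),
        seed=None,
    )
    rec.validate()
    return rec


def simulate_heartbeats(
    schedule: Sequence[StimEvent],
    effect: EffectSpec,
    seed: int | np.random.SeedSequence = 0,
    duration: float | None = None,
    artifact_rate: float = 0.0,
    dt: float = 0.01,
) -> np.ndarray:
    """Generate heartbeat times with block-dependent rate and RSA.

    An integrate-and-fire generator: the instantaneous rate is the block's
    base heart rate modulated sinusoidally at the respiratory frequency
    with the block's RSA depth, on top of broadband (<1 Hz) heart-rate
    variability of fractional SD ``effect.hrv_noise`` — the noise floor
    against which the respiratory peak stands out. A beat fires whenever
    the integrated rate crosses an integer. With ``artifact_rate > 0``
    spurious extra beats are inserted (short inter-beat intervals) to
    exercise the cleaning filter.
    """
    if not schedule:
        raise ValueError("schedule must be non-empty")
    if duration is None:
        duration = schedule[-1].offset + 5.0
    rng = np.random.default_rng(
        seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    )
    base = 0.5 * (effect.hr_airflow + effect.hr_touch)
    grid = np.arange(0.0, duration, dt)
    hr = np.full(grid.size, base)
    depth = np.full(grid.size, 0.5 * (effect.rsa_depth_airflow + effect.rsa_depth_touch))
    for t0, t1, _, btype in block_extents(schedule):
        m = (grid >= t0) & (grid < t1)
        hr[m] = effect.hr_touch if btype == TOUCH else effect.hr_airflow
        depth[m] = effect.rsa_depth_touch if btype == TOUCH else effect.rsa_depth_airflow
    modulation = depth * np.sin(2 * np.pi * effect.resp_freq * grid)
    if effect.hrv_noise > 0:
        z, _ = _spectral_noise(rng, grid.size, 1.0 / dt, lambda f: (f > 0) & (f <= 1.0))
        modulation = modulation + effect.hrv_noise * z
    rate = np.clip(hr / 60.0 * (1.0 + modulation), 0.0, None)
    cum = np.concatenate([[0.0], np.cumsum(rate) * dt])
    tg = np.concatenate([grid, [duration]])
    n_beats = int(cum[-1])
    beats = np.interp(np.arange(1, n_beats + 1), cum, tg)
    if artifact_rate > 0:
        n_art = rng.poisson(artifact_rate * duration)
        if n_art:
            hosts = rng.choice(beats[:-1], size=n_art)
            extra = hosts + rng.uniform(0.08, 0.18, size=n_art)
            beats = np.sort(np.concatenate([beats, extra]))
    return beats


def simulate_spikes(
    session: SessionRecord,
    unit_channels: Sequence[int],
    rate: float = 5.0,
    lfp_coupling: float = 0.0,
    coupling_band: tuple[float, float] = (10.0, 17.0),
    seed: int | np.random.SeedSequence = 0,
) -> list[SpikeTrain]:
    """Inhomogeneous-Poisson spike trains, optionally locked to the LFP.

    With ``lfp_coupling > 0`` the firing probability is modulated by the
    unit channel's band-passed LFP, so the spike-triggered average of the
    LFP is oscillatory in the coupling band; with coupling 0 the trains
    are homogeneous Poisson and the STA is flat.
    """
    if rate <= 0:
        raise ValueError("rate must be positive")
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    fs = session.fs
    n = session.lfp.shape[1]
    sos = signal.butter(4, coupling_band, btype="bandpass", fs=fs, output="sos")
    trains: list[SpikeTrain] = []
    for child, ch in zip(ss.spawn(len(unit_channels)), unit_channels):
        rng = np.random.default_rng(child)
        if lfp_coupling != 0.0:
            z = signal.sosfiltfilt(sos, session.lfp[ch].astype(np.float64))
            z /= z.std() or 1.0
            lam = rate * np.clip(1.0 + lfp_coupling * z, 0.0, None)
        else:
            lam = np.full(n, rate)
        hits = rng.random(n) < lam / fs
        times = (np.nonzero(hits)[0] + 0.5) / fs
        trains.append(SpikeTrain(times=times, channel=int(ch)))
    return trains


def simulate_session(
    designs: Sequence[BlockDesign] | None = None,
    effect: EffectSpec | None = None,
    channel_nuclei: Sequence[str] | None = None,
    fs: float = 1000.0,
    seed: int = 0,
    inter_block_gap: float = 120.0,
    n_units: int = 4,
    spike_rate: float = 5.0,
    lfp_coupling: float = 0.5,
) -> SessionRecord:
    """Simulate a full session: schedule, LFP, spikes and heartbeats.

    The default design is three airflow and three touch blocks in
    alternation, 32 channels across four nuclei. One master seed fans out
    to independent substreams for LFP, spikes and heartbeats.
    """
    if designs is None:
        designs = [
            BlockDesign.airflow(), BlockDesign.touch(),
            BlockDesign.airflow(), BlockDesign.touch(),
            BlockDesign.airflow(), BlockDesign.touch(),
        ]
    effect = effect or EffectSpec()
    channel_nuclei = list(channel_nuclei or default_channel_map())
    schedule = make_schedule(designs, inter_block_gap=inter_block_gap)
    ss_lfp, ss_spk, ss_hb = np.random.SeedSequence(seed).spawn(3)
    rec = simulate_lfp(schedule, channel_nuclei, effect, fs=fs, seed=ss_lfp)
    unit_channels = list(range(0, rec.n_channels, max(1, rec.n_channels // max(1, n_units))))[:n_units]
    rec.spikes = simulate_spikes(
        rec, unit_channels, rate=spike_rate, lfp_coupling=lfp_coupling, seed=ss_spk
    )
    rec.heartbeats = simulate_heartbeats(schedule, effect, seed=ss_hb, duration=rec.duration)
    rec.seed = seed
    rec.validate()
    return rec
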
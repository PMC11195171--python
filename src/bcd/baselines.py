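"""Extraction of labelled baseline LFP windows from inter-stimulus intervals.

Baseline activity is taken from the interval between two consecutive
stimuli *of the same type within the same block*, trimmed by 200 ms guards
after the first stimulus' offset and before the next one's onset; nothing
preceding the first stimulus of a block is used. Within the trimmed
intervals, one per-session window offset is chosen by minimizing trial-wise
variability: the ISI-aligned signals are trial-averaged, the per-timepoint
standard deviation across trials is computed, and the contiguous stretch of
the requested window length with the lowest mean SD is selected (earliest
offset on ties). The same offset is applied to every trial so that all
windows in a session share a time base.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .synthgen import SessionRecord

__all__ = [
    "Candidate",
    "BaselineWindow",
    "isi_segments",
    "select_stable_window",
    "extract_baselines",
]

GUARD = 0.2  # s after offset / before onset excluded from the ISI


@dataclass(frozen=True)
class Candidate:
    """One guard-trimmed inter-stimulus interval."""

    t0: float
    t1: float
    block_id: int
    label: str

    @property
    def duration(self) -> float:
        return self.t1 - self.t0


@dataclass
class BaselineWindow:
    """A labelled baseline LFP segment on one channel."""

    channel: int
    nucleus: str
    t_start: float
    t_end: float
    label: str
    block_id: int
    signal: np.ndarray


def isi_segments(
    session: SessionRecord, guard: float = GUARD, min_length: float = 0.0
) -> list[Candidate]:
    """Candidate baseline intervals between consecutive same-block stimuli.

    A block with ``n`` presentations yields at most ``n - 1`` candidates;
    pairs whose trimmed gap is shorter than ``min_length`` are skipped.
    """
    out: list[Candidate] = []
    ev = session.stim_events
    for a, b in zip(ev, ev[1:]):
        if a.block_id != b.block_id:
            continue
        t0, t1 = a.offset + guard, b.onset - guard
        if t1 - t0 >= max(min_length, 0.0) and t1 > t0:
            out.append(Candidate(t0, t1, a.block_id, a.block_type))
    return out


def _aligned_stack(session: SessionRecord, candidates: Sequence[Candidate]) -> np.ndarray:
    """Stack ISI segments aligned at interval start: (trials, channels, time)."""
    fs = session.fs
    n_common = min(int(round(c.duration * fs)) for c in candidates)
    segs = []
    for c in candidates:
        i0 = int(round(c.t0 * fs))
        segs.append(session.lfp[:, i0 : i0 + n_common])
    return np.stack(segs)


def select_stable_window(
    session: SessionRecord,
    candidates: Sequence[Candidate] | None = None,
    window_length: float = 0.5,
) -> float:
    """Choose the per-session window offset with lowest trial-wise variability.

    Returns the offset (s) of the window start relative to each candidate
    interval's start. The stability statistic is the across-trial SD per
    timepoint, computed per channel and averaged over channels, then
    averaged over the sliding window; ties break toward the earliest
    offset.
    """
    if candidates is None:
        candidates = isi_segments(session)
    if len(candidates) < 2:
        raise ValueError("need at least 2 candidate intervals to assess stability")
    fs = session.fs
    stack = _aligned_stack(session, candidates)  # (trials, ch, time)
    n_win = int(round(window_length * fs))
    n_time = stack.shape[2]
    if n_win > n_time:
        raise ValueError(
            f"window of {window_length}s ({n_win} samples) does not fit the "
            f"shortest candidate interval ({n_time} samples at fs={fs})"
        )
    sd_profile = stack.std(axis=0).mean(axis=0)  # (time,)
    # sliding mean of the SD profile over window-length stretches
    c = np.concatenate([[0.0], np.cumsum(sd_profile)])
    window_means = (c[n_win:] - c[:-n_win]) / n_win
    best = int(np.argmin(window_means))  # argmin takes the first minimum
    return best / fs


def extract_baselines(
    session: SessionRecord,
    candidates: Sequence[Candidate] | None = None,
    offset: float | None = None,
    window_length: float = 0.5,
) -> list[BaselineWindow]:
    """Cut one labelled baseline window per channel per candidate interval."""
    if candidates is None:
        candidates = isi_segments(session, min_length=window_length)
    if not candidates:
        return []
    if offset is None:
        offset = select_stable_window(session, candidates, window_length)
    fs = session.fs
    n_win = int(round(window_length * fs))
    out: list[BaselineWindow] = []
    for c in candidates:
        i0 = int(round((c.t0 + offset) * fs))
        if (c.t0 + offset) + window_length > c.t1 + 1e-9:
            continue  # window would cross the pre-onset guard
        for ch in range(session.n_channels):
            out.append(
                BaselineWindow(
                    channel=ch,
                    nucleus=session.channel_nuclei[ch],
                    t_start=c.t0 + offset,
                    t_end=c.t0 + offset + window_length,
                    label=c.label,
                    block_id=c.block_id,
                    signal=session.lfp[ch, i0 : i0 + n_win],
                )
            )
    return out
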
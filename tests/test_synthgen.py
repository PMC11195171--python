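"""Generator contracts: schedules, band effects, heartbeats, spikes."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.signal import welch
from scipy.stats import mannwhitneyu

from bcd.baselines import extract_baselines, isi_segments
from bcd.synthgen import (
    AIRFLOW,
    TOUCH,
    BlockDesign,
    EffectSpec,
    make_schedule,
    simulate_heartbeats,
    simulate_lfp,
    simulate_spikes,
)


class TestSchedule:
    def test_default_block_presentation_counts(self):
        ev = make_schedule([BlockDesign.airflow(), BlockDesign.touch()])
        n_by_block = {b: sum(e.block_id == b for e in ev) for b in (0, 1)}
        assert n_by_block == {0: 110, 1: 100}

    def test_degenerate_single_event(self):
        ev = make_schedule([BlockDesign(AIRFLOW, n_per_sequence=1, n_repeats=1)])
        assert len(ev) == 1
        assert ev[0].offset - ev[0].onset == pytest.approx(1.0)

    def test_events_strictly_increasing_nonoverlapping(self, two_block_schedule):
        ev = two_block_schedule
        assert all(b.onset > a.offset for a, b in zip(ev, ev[1:]))

    def test_invalid_design_rejected(self):
        with pytest.raises(ValueError):
            BlockDesign(AIRFLOW, n_per_sequence=11, n_repeats=10, stim_duration=-1.0)
        with pytest.raises(ValueError):
            make_schedule([])

    @settings(max_examples=25, deadline=None)
    @given(
        n_seq=st.integers(1, 30),
        n_rep=st.integers(1, 12),
        gap=st.floats(0.5, 10.0),
    )
    def test_event_count_conservation(self, n_seq, n_rep, gap):
        d = BlockDesign(TOUCH, n_per_sequence=n_seq, n_repeats=n_rep, inter_stim_gap=gap)
        ev = make_schedule([d], inter_block_gap=30.0)
        assert len(ev) == n_seq * n_rep


def _baseline_band_power(session, lo, hi):
    wins = extract_baselines(session, isi_segments(session, min_length=0.5), window_length=0.5)
    out = {AIRFLOW: [], TOUCH: []}
    for w in wins:
        f, p = welch(w.signal.astype(float), fs=session.fs, nperseg=len(w.signal))
        m = (f >= lo) & (f <= hi)
        out[w.label].append(p[m].mean())
    return {k: np.asarray(v) for k, v in out.items()}


class TestLFP:
    def test_same_seed_bit_identical(self, two_block_schedule):
        a = simulate_lfp(two_block_schedule, ["L"] * 2, EffectSpec(), seed=3)
        b = simulate_lfp(two_block_schedule, ["L"] * 2, EffectSpec(), seed=3)
        assert np.array_equal(a.lfp, b.lfp)

    def test_touch_band_gain_raises_touch_baseline_power(self, signal_session):
        """Welch-periodogram oracle on the generator's own output: the 10-17 Hz
        gain of 2.0 must make touch baseline band power exceed airflow."""
        bp = _baseline_band_power(signal_session, 10, 17)
        stat = mannwhitneyu(bp[TOUCH], bp[AIRFLOW], alternative="greater")
        assert stat.pvalue < 0.01
        assert bp[TOUCH].mean() > bp[AIRFLOW].mean()

    def test_null_world_band_power_indistinct(self, null_session):
        bp = _baseline_band_power(null_session, 10, 17)
        pooled_se = np.hypot(
            bp[TOUCH].std() / np.sqrt(bp[TOUCH].size),
            bp[AIRFLOW].std() / np.sqrt(bp[AIRFLOW].size),
        )
        assert abs(bp[TOUCH].mean() - bp[AIRFLOW].mean()) < 3 * pooled_se

    def test_empty_schedule_rejected(self):
        with pytest.raises(ValueError):
            simulate_lfp([], ["L"], EffectSpec(), seed=0)

    def test_lfp_finite_and_validated(self, signal_session):
        signal_session.validate()
        assert np.all(np.isfinite(signal_session.lfp))


class TestHeartbeats:
    def test_constant_rate_unit_ibis(self):
        ev = make_schedule([BlockDesign(TOUCH, 5, 1)])
        eff = EffectSpec(
            hr_airflow=60.0, hr_touch=60.0, rsa_depth_airflow=0.0, rsa_depth_touch=0.0,
            hrv_noise=0.0,
        )
        beats = simulate_heartbeats(ev, eff, seed=0, duration=60.0)
        assert np.allclose(np.diff(beats), 1.0, atol=1e-6)

    def test_block_mean_hr_recovered(self, two_block_schedule):
        eff = EffectSpec(hr_airflow=130.0, hr_touch=110.0)
        beats = simulate_heartbeats(two_block_schedule, eff, seed=0)
        from bcd.synthgen import block_extents

        for t0, t1, _, btype in block_extents(two_block_schedule):
            n = np.sum((beats >= t0) & (beats < t1))
            hr = 60.0 * n / (t1 - t0)
            target = 110.0 if btype == TOUCH else 130.0
            assert abs(hr - target) < 3.0

    def test_resp_freq_validated(self, two_block_schedule):
        with pytest.raises(ValueError):
            EffectSpec(resp_freq=0.7)

    def test_artifact_beats_injected(self, two_block_schedule):
        from bcd.physio import clean_heartbeats

        beats = simulate_heartbeats(
            two_block_schedule, EffectSpec(), seed=5, artifact_rate=0.02
        )
        cleaned = clean_heartbeats(beats)
        # artifacts create sub-250 ms IBIs, which cleaning must remove
        assert np.any(np.diff(beats) < 0.25)
        assert cleaned.beat_times.size < beats.size
        assert np.all(np.diff(cleaned.beat_times) >= 0.25 - 1e-9)


class TestSpikes:
    def test_poisson_count_at_rate(self, null_session):
        trains = simulate_spikes(null_session, [0], rate=5.0, lfp_coupling=0.0, seed=9)
        expected = 5.0 * null_session.duration
        assert abs(trains[0].times.size - expected) < 3 * np.sqrt(expected)

    def test_rate_must_be_positive(self, null_session):
        with pytest.raises(ValueError):
            simulate_spikes(null_session, [0], rate=0.0)
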
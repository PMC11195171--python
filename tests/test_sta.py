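"""Spike-triggered averages and their Welch spectra."""

import numpy as np
import pytest

from bcd.baselines import BaselineWindow, extract_baselines, isi_segments
from bcd.sta import mean_sta, spike_triggered_average, sta_spectrum, STAResult
from bcd.synthgen import (
    AIRFLOW,
    BlockDesign,
    SessionRecord,
    SpikeTrain,
    make_schedule,
)


def session_with_oscillation(freq=12.5, fs=1000.0, n_events=30, lock_spikes=True, seed=0):
    """Session whose channel-0 LFP is a pure oscillation; spikes either
    phase-locked to its peaks or Poisson."""
    ev = make_schedule([BlockDesign(AIRFLOW, n_events, 1)])
    dur = ev[-1].offset + 5.0
    n = int(dur * fs)
    t = np.arange(n) / fs
    lfp = np.sin(2 * np.pi * freq * t)[None, :].astype(np.float32)
    if lock_spikes:
        # spikes at oscillation peaks: phase 90 degrees
        peak_times = (np.arange(int(dur * freq)) + 0.25) / freq
        times = peak_times
    else:
        rng = np.random.default_rng(seed)
        times = np.sort(rng.uniform(0, dur, int(5 * dur)))
    s = SessionRecord(
        lfp=lfp, fs=fs, channel_nuclei=["B"], stim_events=ev,
        spikes=[SpikeTrain(times=times, channel=0)],
    )
    return s


class TestSTA:
    def test_phase_locked_spikes_recover_oscillation(self):
        """Spikes locked to 12.5 Hz peaks: the STA is the generating
        oscillation, period 80 ms, maximal at lag 0."""
        s = session_with_oscillation()
        wins = extract_baselines(s, window_length=0.5)
        res = spike_triggered_average(s, wins, unit=0)
        sta = res[AIRFLOW].sta
        lags = res[AIRFLOW].lags
        assert sta[lags == 0.0] == pytest.approx(1.0, abs=1e-3)
        # period 80 ms: troughs at +-40 ms, peak again at +-80 ms
        assert sta[np.isclose(lags, 0.040)] == pytest.approx(-1.0, abs=1e-2)
        assert sta[np.isclose(lags, 0.080)] == pytest.approx(1.0, abs=1e-2)

    def test_uncoupled_spikes_flat_sta(self):
        rng = np.random.default_rng(3)
        s = session_with_oscillation(lock_spikes=False)
        s.lfp = rng.normal(0, 1, s.lfp.shape).astype(np.float32)  # uncorrelated noise
        wins = extract_baselines(s, window_length=0.5)
        res = spike_triggered_average(s, wins, unit=0)
        r = res[AIRFLOW]
        bound = 3.0 / np.sqrt(r.n_spikes)
        assert np.all(np.abs(r.sta) < bound + 3 * bound)  # |mean| < 3 SE-ish per lag

    def test_single_spike_sta_is_snippet(self):
        s = session_with_oscillation(lock_spikes=False)
        wins = extract_baselines(s, window_length=0.5)
        w = wins[0]
        t_spike = (w.t_start + w.t_end) / 2
        s.spikes = [SpikeTrain(times=np.array([t_spike]), channel=0)]
        res = spike_triggered_average(s, wins, unit=0)
        r = res[AIRFLOW]
        i = int(round(t_spike * s.fs))
        assert np.allclose(r.sta, s.lfp[0, i - 80 : i + 81])
        assert r.n_spikes == 1

    def test_no_qualifying_spikes_empty_marker(self):
        s = session_with_oscillation(lock_spikes=False)
        wins = extract_baselines(s, window_length=0.5)
        s.spikes = [SpikeTrain(times=np.array([0.01]), channel=0)]  # before any baseline
        assert spike_triggered_average(s, wins, unit=0) == {}

    def test_time_reversal_flips_lag_axis(self):
        rng = np.random.default_rng(1)
        snips = rng.normal(0, 1, (40, 161))
        sta_fwd = snips.mean(axis=0)
        sta_rev = snips[:, ::-1].mean(axis=0)
        assert np.array_equal(sta_rev, sta_fwd[::-1])


class TestSTASpectrum:
    def test_tone_snippets_peak_at_tone(self):
        t = np.arange(161) / 1000.0
        snips = np.tile(np.sin(2 * np.pi * 14.0 * t), (10, 1))
        f, psd = sta_spectrum(snips, fs=1000.0)
        assert abs(f[np.argmax(psd)] - 14.0) <= f[1] - f[0]

    def test_tone_power_parseval(self):
        """Hann-windowed Welch power of a unit tone is amp^2/2 within 10%."""
        t = np.arange(800) / 1000.0
        snips = np.sin(2 * np.pi * 25.0 * t)[None, :]
        f, psd = sta_spectrum(snips, fs=1000.0)
        df = f[1] - f[0]
        assert psd.sum() * df == pytest.approx(0.5, rel=0.1)

    def test_white_noise_spectrum_flat(self):
        rng = np.random.default_rng(0)
        snips = rng.normal(0, 1, (4000, 161))
        f, psd = sta_spectrum(snips, fs=1000.0)
        band = psd[(f >= 1) & (f <= 50)]
        se = band.std() / np.sqrt(band.size)
        assert abs(band.mean() - psd[(f > 50) & (f < 400)].mean()) < 5 * se

    def test_segment_longer_than_snippet_errors(self):
        with pytest.raises(ValueError):
            sta_spectrum(np.zeros((3, 100)), fs=1000.0, nperseg=200)

    def test_band_effect_visible_in_sta_spectra(self, signal_session):
        """With the touch 10-17 Hz and airflow 17-25 Hz gains, mean STA
        spectra differ in opposite directions in the two bands."""
        wins = extract_baselines(
            signal_session, isi_segments(signal_session, min_length=0.5), window_length=0.5
        )
        per_label: dict[str, list] = {"airflow": [], "touch": []}
        for u in range(len(signal_session.spikes)):
            for lab, r in spike_triggered_average(signal_session, wins, u).items():
                per_label[lab].append(r)
        m_air = mean_sta(per_label["airflow"])
        m_touch = mean_sta(per_label["touch"])
        f = m_air.spectrum_freqs
        low = (f >= 10) & (f <= 17)
        high = (f > 17) & (f <= 25)
        assert m_touch.spectrum[low].mean() > m_air.spectrum[low].mean()
        assert m_air.spectrum[high].mean() > m_touch.spectrum[high].mean()


class TestMeanSTA:
    def _mk(self, sta, spec=None):
        n = sta.size
        return STAResult(
            lags=np.linspace(-0.08, 0.08, n), sta=sta, n_spikes=10,
            spectrum_freqs=np.arange(5.0), spectrum=spec if spec is not None else np.ones(5),
            nucleus="B", label="airflow",
        )

    def test_identical_units_mean_is_either(self):
        a = self._mk(np.sin(np.linspace(0, 3, 161)))
        m = mean_sta([a, a])
        assert np.allclose(m.sta, a.sta)

    def test_opposite_signs_cancel(self):
        a = self._mk(np.sin(np.linspace(0, 3, 161)))
        b = self._mk(-a.sta)
        assert np.allclose(mean_sta([a, b]).sta, 0.0)

    def test_empty_list_errors(self):
        with pytest.raises(ValueError):
            mean_sta([])
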
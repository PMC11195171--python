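"""End-to-end pipeline driver.

Chains the stages: simulate sessions → autonomic physiology → baseline
extraction → wavelet spectrograms → classifier training (real and
shuffled-label null) → optional band ablation → spike-triggered averages
→ report. Results are written as tidy CSV tables plus a JSON summary;
every output carries the config hash and master seed, so any artifact is
reproducible from (config, seed) alone.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import baselines, decode, physio, sta, synthgen, timefreq
from .bundle import save_session
from .config import PipelineConfig

log = logging.getLogger("bcd")

__all__ = ["run_pipeline"]


def _stage(name: str):
    class _Timer:
        def __enter__(self):
            self.t0 = time.perf_counter()
            log.info("stage %s: start", name)
            return self

        def __exit__(self, *exc):
            log.info("stage %s: %.1fs", name, time.perf_counter() - self.t0)

    return _Timer()


def _make_classifier(name: str, cfg) -> decode.BaseEstimator:
    if name == "svm":
        return decode.SVMClassifier(C=cfg.svm_C)
    if name == "cnn":
        return decode.CNNClassifier(
            n_epochs=cfg.cnn_epochs,
            batch_size=cfg.cnn_batch_size,
            lr=cfg.cnn_lr,
            dropout=cfg.cnn_dropout,
            pool_stride=cfg.pool_stride,
        )
    raise ValueError(f"unknown classifier {name!r}")


def run_pipeline(config: PipelineConfig, seed: int, outdir: str | Path) -> dict:
    """Run every stage and write the report bundle into ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sim, ana = config.simulation, config.analysis
    summary: dict = {"config_hash": config.hash(), "seed": seed}

    try:
        with _stage("simulate"):
            sessions = [
                synthgen.simulate_session(
                    designs=sim.designs(),
                    effect=sim.effect,
                    channel_nuclei=synthgen.default_channel_map(sim.n_channels),
                    fs=sim.fs,
                    seed=int(np.random.SeedSequence([seed, i]).generate_state(1)[0] % (2**31)),
                    inter_block_gap=sim.inter_block_gap,
                    n_units=sim.n_units,
                    spike_rate=sim.spike_rate,
                    lfp_coupling=sim.lfp_coupling,
                )
                for i in range(sim.n_sessions)
            ]
            save_session(outdir / "session000.h5", sessions[0])
    except Exception as e:
        raise RuntimeError(f"stage 'simulate' failed (designs={sim.designs()!r}): {e}") from e

    try:
        with _stage("physio"):
            phys = [
                physio.session_autonomic_summary(
                    s, window=ana.rsa_window, hop=ana.rsa_hop,
                    n_tapers=ana.rsa_tapers, nw=ana.rsa_nw, mu_mode=ana.rsa_mu_mode,
                )
                for s in sessions
            ]
            summary["physio"] = {"per_session": phys}
            if len(phys) >= 2:
                summary["physio"]["rsa_test"] = physio.compare_blocks(
                    [p["rsa"]["touch"] for p in phys],
                    [p["rsa"]["airflow"] for p in phys],
                    alternative="greater",
                )
                summary["physio"]["hr_test"] = physio.compare_blocks(
                    [p["hr"]["touch"] for p in phys],
                    [p["hr"]["airflow"] for p in phys],
                    alternative="less",
                )
    except Exception as e:
        raise RuntimeError(f"stage 'physio' failed: {e}") from e

    rng = np.random.default_rng(np.random.SeedSequence([seed, 10_001]))
    rows = []
    detect: dict[str, dict] = {}
    per_nucleus_acc: dict[str, np.ndarray] = {}
    wcfg = timefreq.WaveletConfig(
        f0=ana.wavelet_f0,
        freqs=np.arange(ana.freq_min, ana.freq_max + ana.freq_step / 2, ana.freq_step),
        fs=sim.fs,
    )
    protocol = decode.TrainingProtocol(n_repeats=ana.n_repeats)

    try:
        with _stage("extract+spectro+train"):
            for si, session in enumerate(sessions):
                cands = baselines.isi_segments(session, guard=ana.guard, min_length=ana.window_length)
                wins = baselines.extract_baselines(session, cands, window_length=ana.window_length)
                log.info("session %d: %d baseline windows", si, len(wins))
                specs = timefreq.spectrogram_stack(wins, wcfg, time_decimation=ana.time_decimation)
                nuclei = sorted(set(session.channel_nuclei))
                for nuc in nuclei:
                    try:
                        ds = decode.build_dataset(
                            specs, session=si, nucleus=nuc,
                            min_per_class=ana.min_per_class, max_per_class=ana.max_per_class,
                            rng=rng,
                        )
                    except ValueError as err:
                        log.info("session %d nucleus %s skipped: %s", si, nuc, err)
                        continue
                    for clf_name in ana.classifiers:
                        model = _make_classifier(clf_name, ana)
                        dist = decode.accuracy_distribution(ds, model, protocol, rng)
                        key = f"s{si}/{nuc}/{clf_name}"
                        detect[key] = {
                            "quantiles": dist.quantiles.tolist(),
                            "null_quantiles": dist.null_quantiles.tolist(),
                            "separated_from_null": dist.separated_from_null(),
                        }
                        if clf_name == ana.classifiers[0] and si == 0:
                            per_nucleus_acc[nuc] = dist.accuracies
                        for r, a in enumerate(dist.accuracies):
                            rows.append((si, nuc, clf_name, "full", r, a, False))
                        for r, a in enumerate(dist.null_accuracies):
                            rows.append((si, nuc, clf_name, "full", r, a, True))
                        if ana.run_ablation:
                            abl = decode.band_ablation(
                                ds, model, protocol, bands=ana.bands, rng=rng, include_full=False
                            )
                            for band, d2 in abl.items():
                                for r, a in enumerate(d2.accuracies):
                                    rows.append((si, nuc, clf_name, band, r, a, False))
    except Exception as e:
        raise RuntimeError(f"stage 'decode' failed: {e}") from e

    if len(per_nucleus_acc) >= 2:
        counts = {
            n: sessions[0].channel_nuclei.count(n) for n in per_nucleus_acc
        }
        summary["cross_nucleus"] = decode.cross_nucleus_test(per_nucleus_acc, counts)

    if ana.run_sta:
        try:
            with _stage("sta"):
                session = sessions[0]
                cands = baselines.isi_segments(session, guard=ana.guard, min_length=ana.window_length)
                wins = baselines.extract_baselines(session, cands, window_length=ana.window_length)
                sta_rows = []
                for u in range(len(session.spikes)):
                    for lab, res in sta.spike_triggered_average(session, wins, u).items():
                        for lag, v in zip(res.lags, res.sta):
                            sta_rows.append((u, res.nucleus, lab, lag, v))
                pd.DataFrame(
                    sta_rows, columns=["unit", "nucleus", "label", "lag_s", "sta_uv"]
                ).to_csv(outdir / "sta.csv", index=False)
        except Exception as e:
            raise RuntimeError(f"stage 'sta' failed: {e}") from e

    df = pd.DataFrame(
        rows,
        columns=["session", "nucleus", "classifier", "band", "repeat", "accuracy", "is_null"],
    )
    df.to_csv(outdir / "accuracies.csv", index=False)
    summary["decoding"] = detect
    summary["context_signal_detected"] = (
        all(v["separated_from_null"] for v in detect.values()) if detect else None
    )
    (outdir / "summary.json").write_text(json.dumps(summary, indent=2, default=float))
    return summary
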
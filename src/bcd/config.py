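"""Declarative pipeline configuration.

Every tunable the pipeline uses — including the choices that go beyond
what the experimental protocol pins down (sampling rate, blocks per
session, window length, wavelet grid, dropout rate, learning rate, SVM
hyperparameters) — appears explicitly here, so a run is reproducible from
(config, seed) alone. Configs round-trip losslessly through dict / YAML.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .synthgen import BlockDesign, EffectSpec

SCHEMA_VERSION = 1

__all__ = ["SimulationConfig", "AnalysisConfig", "PipelineConfig"]


@dataclass(frozen=True)
class SimulationConfig:
    n_airflow_blocks: int = 3
    n_touch_blocks: int = 3
    airflow_n_per_sequence: int = 11
    airflow_n_repeats: int = 10
    touch_n_per_sequence: int = 20
    touch_n_repeats: int = 5
    stim_duration: float = 1.0
    inter_stim_gap: float = 4.0
    inter_block_gap: float = 120.0
    n_channels: int = 32
    fs: float = 1000.0
    n_units: int = 4
    spike_rate: float = 5.0
    lfp_coupling: float = 0.5
    n_sessions: int = 1
    effect: EffectSpec = field(default_factory=EffectSpec)

    def designs(self) -> list[BlockDesign]:
        a = BlockDesign(
            "airflow", self.airflow_n_per_sequence, self.airflow_n_repeats,
            self.stim_duration, self.inter_stim_gap,
        )
        t = BlockDesign(
            "touch", self.touch_n_per_sequence, self.touch_n_repeats,
            self.stim_duration, self.inter_stim_gap,
        )
        out: list[BlockDesign] = []
        for i in range(max(self.n_airflow_blocks, self.n_touch_blocks)):
            if i < self.n_airflow_blocks:
                out.append(a)
            if i < self.n_touch_blocks:
                out.append(t)
        return out


@dataclass(frozen=True)
class AnalysisConfig:
    guard: float = 0.2
    window_length: float = 0.5
    wavelet_f0: float = 5.0
    freq_min: float = 1.0
    freq_max: float = 50.0
    freq_step: float = 1.0
    time_decimation: int = 50
    min_per_class: int = 20
    max_per_class: int = 300
    n_repeats: int = 50
    cnn_epochs: int = 40
    cnn_batch_size: int = 20
    cnn_lr: float = 1e-3
    cnn_dropout: float = 0.5
    pool_stride: int = 1
    svm_C: float = 1.0
    bands: tuple[tuple[float, float], ...] = ((10.0, 17.0), (17.0, 25.0), (10.0, 25.0))
    rsa_window: float = 60.0
    rsa_hop: float = 3.0
    rsa_tapers: int = 7
    rsa_nw: float = 4.0
    rsa_mu_mode: str = "median"
    classifiers: tuple[str, ...] = ("svm",)
    run_ablation: bool = False
    run_sta: bool = True


@dataclass(frozen=True)
class PipelineConfig:
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)
    schema_version: int = SCHEMA_VERSION

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return json.loads(json.dumps(d))  # tuples -> lists, plain types only

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if d.get("schema_version", SCHEMA_VERSION) != SCHEMA_VERSION:
            raise ValueError(f"unsupported config schema version {d.get('schema_version')}")
        sim = dict(d.get("simulation", {}))
        eff = sim.pop("effect", None)
        if eff is not None:
            eff = dict(eff)
            for key in ("touch_band", "airflow_band"):
                if key in eff:
                    eff[key] = tuple(eff[key])
            if "extra_bands" in eff:
                eff["extra_bands"] = tuple(tuple(b) for b in eff["extra_bands"])
            sim["effect"] = EffectSpec(**eff)
        ana = dict(d.get("analysis", {}))
        if "bands" in ana:
            ana["bands"] = tuple(tuple(b) for b in ana["bands"])
        if "classifiers" in ana:
            ana["classifiers"] = tuple(ana["classifiers"])
        return cls(
            simulation=SimulationConfig(**sim),
            analysis=AnalysisConfig(**ana),
            schema_version=SCHEMA_VERSION,
        )

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:12]
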
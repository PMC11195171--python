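"""Shared fixtures: small simulated sessions reused across the suite.

Sessions here use one airflow and one touch block (full 110/100
presentation counts) on an 8-channel probe — enough trials for decoding
while keeping the suite fast.
"""

import numpy as np
import pytest

from bcd.baselines import extract_baselines, isi_segments
from bcd.decode import build_dataset
from bcd.synthgen import BlockDesign, EffectSpec, make_schedule, simulate_session
from bcd.timefreq import WaveletConfig, spectrogram_stack

TWO_BLOCKS = [BlockDesign.airflow(), BlockDesign.touch()]


@pytest.fixture(scope="session")
def two_block_schedule():
    return make_schedule(TWO_BLOCKS)


@pytest.fixture(scope="session")
def signal_session():
    """Session with the default injected context effects (band gains 2.0)."""
    return simulate_session(
        designs=TWO_BLOCKS, effect=EffectSpec(), channel_nuclei=["B"] * 8,
        seed=7, n_units=2, lfp_coupling=0.6,
    )


@pytest.fixture(scope="session")
def null_session():
    """Context-free session: no band effects, identical autonomics."""
    return simulate_session(
        designs=TWO_BLOCKS, effect=EffectSpec.null(), channel_nuclei=["B"] * 8,
        seed=11, n_units=2, lfp_coupling=0.0,
    )


def _dataset(session, seed, max_per_class=300):
    wins = extract_baselines(
        session, isi_segments(session, min_length=0.5), window_length=0.5
    )
    # subsample windows per class before the (costly) wavelet transform
    rng = np.random.default_rng(seed)
    keep = []
    for lab in ("airflow", "touch"):
        idx = [i for i, w in enumerate(wins) if w.label == lab]
        keep.extend(rng.choice(idx, size=min(max_per_class, len(idx)), replace=False))
    wins = [wins[i] for i in sorted(keep)]
    specs = spectrogram_stack(wins, WaveletConfig(fs=session.fs), time_decimation=50)
    return build_dataset(specs, nucleus="B", max_per_class=max_per_class, rng=rng)


@pytest.fixture(scope="session")
def signal_dataset(signal_session):
    return _dataset(signal_session, seed=1)


@pytest.fixture(scope="session")
def null_dataset(null_session):
    return _dataset(null_session, seed=2)
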
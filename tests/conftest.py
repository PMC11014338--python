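"""Shared fixtures: session-scoped synthetic recordings and datasets."""

from dataclasses import replace

import numpy as np
import pytest

from cardiovib import bands as bd
from cardiovib import segment as sg
from cardiovib import simulate as sim


@pytest.fixture(scope="session")
def default_recording():
    """Default-config recording, seed 7, 60 cycles (noise and jitter on)."""
    return sim.synthesize_recording(sim.SimulationConfig(seed=7, n_cycles=60))


@pytest.fixture(scope="session")
def noise_free_recording():
    """Same geometry with every stochastic nuisance term off."""
    cfg = sim.with_noise_free(sim.SimulationConfig(seed=7, n_cycles=20))
    return sim.synthesize_recording(cfg)


@pytest.fixture(scope="session")
def default_bands(default_recording):
    rec = default_recording
    return bd.decompose_bands(rec.vibration, rec.ecg, rec.sampling_rate)


@pytest.fixture(scope="session")
def noise_free_bands(noise_free_recording):
    rec = noise_free_recording
    return bd.decompose_bands(rec.vibration, rec.ecg, rec.sampling_rate)


@pytest.fixture(scope="session")
def template_schedule():
    return sim.make_event_schedule(0.8, jitter=0.0)


def build_corpus(n_cycles, seed=0, noise_sd=0.05, use_true_onsets=True):
    """Labeled dataset helper used by learnability tests."""
    cfg = sim.SimulationConfig(
        seed=seed,
        n_cycles=n_cycles,
        noise_sd=noise_sd,
        baseline_amplitude=0.2 if noise_sd > 0 else 0.0,
        ecg_noise_sd=0.01 if noise_sd > 0 else 0.0,
    )
    if noise_sd == 0.0:
        cfg = replace(cfg, noise_sd=0.0)
    rec = sim.synthesize_recording(cfg)
    band_traces = bd.decompose_bands(rec.vibration, rec.ecg, rec.sampling_rate)
    vib = {k: v for k, v in band_traces.items() if k != "ECG"}
    return sg.segment_recording(rec, vib, use_true_onsets=use_true_onsets)


@pytest.fixture(scope="session")
def corpus_builder():
    return build_corpus


@pytest.fixture(scope="session")
def small_labeled_dataset():
    """120-cycle labeled dataset with default-level noise (fast fixture)."""
    return build_corpus(120, seed=3)
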
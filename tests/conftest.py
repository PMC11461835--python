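"""Shared fixtures: small synthetic cohorts and preprocessed bands."""

from __future__ import annotations

import numpy as np
import pytest

from somnaug.meta import EEGSignal, RecordingMeta
from somnaug.preprocessing import bandpass_filter, decompose_bands, segment
from somnaug.synthetic import CohortSpec, generate_cohort

FS = 512.0


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_spec():
    """Two subjects per class, one minute each: enough for two 30 s epochs."""
    return CohortSpec(n_insomnia=2, n_healthy=2, duration_s=60.0, seed=7)


@pytest.fixture(scope="session")
def small_cohort(small_spec):
    return generate_cohort(small_spec)


@pytest.fixture(scope="session")
def segmented_cohort(small_cohort):
    """(SegmentedBands, filtered raw) pairs for the small cohort."""
    pairs = []
    for sig in small_cohort:
        filt = bandpass_filter(sig)
        pairs.append((segment(decompose_bands(filt), epoch_s=30.0), filt))
    return pairs


@pytest.fixture()
def sine_signal():
    """10 s unit 10 Hz sinusoid at 512 Hz with metadata."""
    t = np.arange(int(10 * FS)) / FS
    meta = RecordingMeta("sine", "healthy")
    return EEGSignal(np.sin(2 * np.pi * 10.0 * t), FS, meta)
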
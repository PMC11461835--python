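"""Synthetic band-structured two-class EEG cohorts.

Each subject's trace is a sum of five independent band-limited Gaussian
noise processes — white noise passed through the same Butterworth design
the preprocessing stage uses, one filter per clinical band — scaled so the
realized mean-square power of each band equals the class's target exactly.
Optional powerline and baseline-drift artifacts can be mixed in for
denoising tests.

Class contrast defaults plant an elevated alpha-band power in the
insomnia class.  The default elevation is calibrated so that, after the
full analysis chain (bandpass, DWT band decomposition, MCSA
augmentation), the two classes' measured alpha band power separates by
about two pooled within-class standard deviations of the augmented
feature-table rows — a planted effect of Cohen's d ≈ 2 at the level the
classifiers actually see.  Recording metadata is drawn so insomnia
subjects have sleep latency above 20 minutes and healthy subjects below.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as sps

from .meta import EEGSignal, Group, RecordingMeta

#: generator band edges in Hz (clinical Table-style edges; gamma capped at
#: the 45 Hz analysis bandwidth)
BAND_EDGES = {
    "delta": (0.5, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 12.0),
    "beta": (12.0, 30.0),
    "gamma": (30.0, 45.0),
}

#: baseline band powers in µV² shared by both classes (delta-dominant
#: overnight sleep spectrum)
_BASE_POWERS = {"delta": 40.0, "theta": 12.0, "alpha": 4.0, "beta": 6.0, "gamma": 1.5}


#: planted insomnia alpha power in µV².  Calibrated once so the augmented
#: feature table's measured alpha band power separates the classes by
#: ~2 pooled within-class row SDs (see docs/methods.md).
INSOMNIA_ALPHA_POWER = 6.4


def default_band_power_map() -> dict[str, dict[str, float]]:
    """Per-class band-power targets with the planted alpha contrast."""
    healthy = dict(_BASE_POWERS)
    insomnia = dict(_BASE_POWERS)
    insomnia["alpha"] = INSOMNIA_ALPHA_POWER
    return {"healthy": healthy, "insomnia": insomnia}


@dataclass
class ArtifactConfig:
    """Powerline and baseline-drift contamination (off by default)."""

    powerline_amp_uv: float = 0.0
    powerline_hz: float = 50.0
    baseline_amp_uv: float = 0.0
    baseline_hz: float = 0.2


@dataclass
class CohortSpec:
    """Study-condition parameters for one synthetic cohort."""

    n_insomnia: int = 6
    n_healthy: int = 6
    duration_s: float = 90.0
    fs: float = 512.0
    band_power_map: dict[str, dict[str, float]] = field(
        default_factory=default_band_power_map
    )
    artifact_config: ArtifactConfig = field(default_factory=ArtifactConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_insomnia < 0 or self.n_healthy < 0:
            raise ValueError("subject counts must be non-negative")
        if self.duration_s <= 0:
            raise ValueError(f"duration_s must be positive, got {self.duration_s}")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        for cls, powers in self.band_power_map.items():
            for band, p in powers.items():
                if p < 0:
                    raise ValueError(f"negative band power {cls}/{band}: {p}")


def _band_noise(rng: np.random.Generator, n: int, fs: float, lo: float, hi: float,
                power: float) -> np.ndarray:
    """Band-limited Gaussian noise rescaled to exact mean-square ``power``."""
    if power == 0.0:
        return np.zeros(n)
    w = rng.standard_normal(n)
    sos = sps.butter(4, [lo, hi], btype="bandpass", fs=fs, output="sos")
    y = sps.sosfiltfilt(sos, w, padtype="even")
    ms = np.mean(y**2)
    if ms == 0.0:
        return np.zeros(n)
    return y * np.sqrt(power / ms)


def _subject_rng(spec: CohortSpec, group: Group, subject_index: int) -> np.random.Generator:
    gcode = 0 if group is Group.HEALTHY else 1
    return np.random.default_rng(
        np.random.SeedSequence([int(spec.seed) % 2**31, gcode, int(subject_index)])
    )


def generate_subject(
    spec: CohortSpec, group: Group | str, subject_index: int
) -> EEGSignal:
    """One subject's EEG trace; deterministic for fixed spec seed + index."""
    group = Group(group)
    rng = _subject_rng(spec, group, subject_index)
    n = int(round(spec.duration_s * spec.fs))
    if n < 2**7:
        raise ValueError("duration too short for a DWT-decomposable window")
    targets = spec.band_power_map[group.value]
    x = np.zeros(n)
    for band, (lo, hi) in BAND_EDGES.items():
        x += _band_noise(rng, n, spec.fs, lo, hi, targets.get(band, 0.0))
    art = spec.artifact_config
    t = np.arange(n) / spec.fs
    if art.powerline_amp_uv > 0:
        x += art.powerline_amp_uv * np.sin(2 * np.pi * art.powerline_hz * t)
    if art.baseline_amp_uv > 0:
        x += art.baseline_amp_uv * np.sin(2 * np.pi * art.baseline_hz * t)
    prefix = "INS" if group is Group.INSOMNIA else "n"
    meta = RecordingMeta(
        subject_id=f"{prefix}{subject_index + 1}",
        group=group,
        fs=spec.fs,
    )
    return EEGSignal(x, spec.fs, meta)


def _fmt_clock(seconds: float) -> str:
    s = int(round(seconds)) % 86400
    return f"{s // 3600:02d}:{s % 3600 // 60:02d}:{s % 60:02d}"


def _draw_meta(rng: np.random.Generator, meta: RecordingMeta) -> RecordingMeta:
    """Clock times: insomnia SL in (25, 120] min, healthy SL in [1, 15] min."""
    start_s = rng.uniform(21.5 * 3600, 23.5 * 3600)
    tib_min = rng.uniform(6.0 * 60, 9.0 * 60)
    if meta.group is Group.INSOMNIA:
        sl_min = rng.uniform(25.0, 120.0)
        waso = rng.uniform(60.0, 400.0)
    else:
        sl_min = rng.uniform(1.0, 15.0)
        waso = rng.uniform(2.0, 60.0)
    onset_s = start_s + sl_min * 60.0
    end_s = start_s + tib_min * 60.0
    return replace(
        meta,
        sleep_start=_fmt_clock(start_s),
        sleep_onset=_fmt_clock(onset_s),
        sleep_end=_fmt_clock(end_s),
        waso_min=round(waso, 1),
    )


def generate_cohort(spec: CohortSpec) -> list[EEGSignal]:
    """Generate the full two-class cohort with metadata.

    Returns ``n_insomnia + n_healthy`` signals; each signal's ``meta``
    carries the drawn clock times and class label.
    """
    signals: list[EEGSignal] = []
    for group, count in ((Group.INSOMNIA, spec.n_insomnia),
                         (Group.HEALTHY, spec.n_healthy)):
        for i in range(count):
            sig = generate_subject(spec, group, i)
            mrng = np.random.default_rng(
                np.random.SeedSequence(
                    [int(spec.seed) % 2**31, 7919, 0 if group is Group.HEALTHY else 1, i]
                )
            )
            sig.meta = _draw_meta(mrng, sig.meta)
            signals.append(sig)
    return signals
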
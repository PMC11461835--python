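"""Layer-1 (signal-level) augmentation: MCSA.

Modified conventional signal augmentation generates new EEG traces from a
segmented band decomposition.  For every (band, segment) pair:

* MCSA-1 multiplies that one band-segment by an amplification factor
  (scaled synthetic signals, SSS);
* MCSA-2 adds white Gaussian noise at a configured SNR to that one
  band-segment (noise-injected synthetic signals, NISS).

In both cycles the perturbed band-segment is recombined with the raw
versions of the other segments and the four untouched bands (the "1 SFB +
4 RFB" addition set), and each addition-set signal is additionally
convolved with the filtered raw trace, power-renormalized, to form the
convolution set.  One full sweep therefore emits exactly
``4 * n_subjects * 5 bands * n_segments`` signals.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .meta import EEGSignal, Group
from .preprocessing import BANDS, SegmentedBands

#: SNR cap treated as "no noise"
SNR_CAP_DB = 120.0


@dataclass
class Provenance:
    cycle: str          # "MCSA1" | "MCSA2"
    op: str             # "addition" | "convolution"
    band: str
    segment_idx: int
    param: float        # scale factor (MCSA1) or SNR dB (MCSA2)
    seed: int
    source_subject: str


@dataclass
class AugmentedSignal:
    """A synthetic EEG trace with full generation provenance."""

    samples: np.ndarray
    fs: float
    label: Group
    provenance: Provenance = field(repr=False)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        self.label = Group(self.label)

    def __len__(self) -> int:
        return self.samples.size


@dataclass
class McsaConfig:
    """Layer-1 parameters: amplification factor and injected-noise SNR."""

    scale_factor: float = 1.5
    snr_db: float = 10.0
    convolution_mode: str = "same-normalized"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.scale_factor <= 0:
            raise ValueError(f"scale_factor must be > 0, got {self.scale_factor}")
        if not np.isfinite(self.snr_db):
            raise ValueError("snr_db must be finite")
        if self.convolution_mode != "same-normalized":
            raise ValueError(f"unknown convolution mode {self.convolution_mode!r}")


def _check_index(seg: SegmentedBands, band: str, segment_idx: int) -> None:
    if band not in seg.epochs:
        raise IndexError(f"unknown band {band!r}; have {sorted(seg.epochs)}")
    if not (0 <= segment_idx < seg.n_segments):
        raise IndexError(
            f"segment {segment_idx} out of range [0, {seg.n_segments})"
        )


def _recombine(seg: SegmentedBands, band: str, new_segment: np.ndarray,
               segment_idx: int) -> np.ndarray:
    """Replace one band-segment, then sum all bands back to a full trace."""
    out = np.zeros(seg.n_segments * seg.epoch_len)
    for b in BANDS:
        e = seg.epochs[b]
        if b == band:
            e = e.copy()
            e[segment_idx] = new_segment
        out += e.reshape(-1)
    return out


def _label_of(seg: SegmentedBands) -> tuple[Group, str]:
    meta = seg.source.source.meta
    if meta is None:
        raise ValueError("segmented bands lack source metadata (label unknown)")
    return meta.group, meta.subject_id


def scale_band_segment(
    seg: SegmentedBands, band: str, segment_idx: int, factor: float
) -> AugmentedSignal:
    """MCSA-1 addition-set signal: one band-segment amplitude-scaled."""
    _check_index(seg, band, segment_idx)
    if factor < 0:
        raise ValueError(f"factor must be >= 0, got {factor}")
    scaled = factor * seg.epochs[band][segment_idx]
    samples = _recombine(seg, band, scaled, segment_idx)
    label, subject = _label_of(seg)
    return AugmentedSignal(
        samples, seg.fs, label,
        Provenance("MCSA1", "addition", band, segment_idx, factor, 0, subject),
    )


def inject_noise_band_segment(
    seg: SegmentedBands, band: str, segment_idx: int, snr_db: float, seed: int
) -> AugmentedSignal:
    """MCSA-2 addition-set signal: white Gaussian noise into one band-segment.

    The noise power is set from the targeted segment's own power:
    ``P_noise = P_segment / 10^(snr_db/10)``.  SNRs at or above
    ``SNR_CAP_DB`` are treated as noiseless.
    """
    _check_index(seg, band, segment_idx)
    target = seg.epochs[band][segment_idx]
    p_sig = float(np.mean(target**2))
    if p_sig <= 0:
        raise ValueError(
            f"band {band!r} segment {segment_idx} has zero power; SNR undefined"
        )
    if snr_db >= SNR_CAP_DB:
        noisy = target.copy()
    else:
        p_noise = p_sig / 10.0 ** (snr_db / 10.0)
        _, subject = _label_of(seg)
        rng = np.random.default_rng(
            np.random.SeedSequence(
                [int(seed) % 2**31, zlib.crc32(subject.encode()),
                 BANDS.index(band), segment_idx]
            )
        )
        noisy = target + rng.normal(0.0, np.sqrt(p_noise), size=target.size)
    samples = _recombine(seg, band, noisy, segment_idx)
    label, subject = _label_of(seg)
    return AugmentedSignal(
        samples, seg.fs, label,
        Provenance("MCSA2", "addition", band, segment_idx, snr_db, seed, subject),
    )


def convolve_with_raw(aug: AugmentedSignal, raw_filtered: EEGSignal) -> AugmentedSignal:
    """Convolution-set signal: convolve with the filtered raw trace.

    "Same"-aligned linear convolution truncated to the augmented signal's
    length, then rescaled so output power equals the input's power (raw
    convolution of two full-length traces explodes in amplitude).
    """
    if aug.fs != raw_filtered.fs:
        raise ValueError(
            f"sampling rate mismatch: {aug.fs} vs {raw_filtered.fs}"
        )
    y = sps.fftconvolve(aug.samples, raw_filtered.samples, mode="same")
    p_in = float(np.mean(aug.samples**2))
    p_out = float(np.mean(y**2))
    if p_out > 0 and p_in > 0:
        y = y * np.sqrt(p_in / p_out)
    prov = Provenance(
        aug.provenance.cycle, "convolution", aug.provenance.band,
        aug.provenance.segment_idx, aug.provenance.param,
        aug.provenance.seed, aug.provenance.source_subject,
    )
    return AugmentedSignal(y, aug.fs, aug.label, prov)


def run_mcsa(
    cohort: list[tuple[SegmentedBands, EEGSignal]], cfg: McsaConfig
) -> list[AugmentedSignal]:
    """Full layer-1 sweep over a cohort.

    ``cohort`` pairs each subject's segmented band decomposition with the
    filtered raw trace used for the convolution set.  Emits, per subject,
    band and segment: MCSA-1 addition, MCSA-1 convolution, MCSA-2 addition
    and MCSA-2 convolution — ``4 * S * 5 * G`` signals in total.
    """
    out: list[AugmentedSignal] = []
    for seg, raw in cohort:
        for band in BANDS:
            for g in range(seg.n_segments):
                sss = scale_band_segment(seg, band, g, cfg.scale_factor)
                niss = inject_noise_band_segment(seg, band, g, cfg.snr_db, cfg.seed)
                out.append(sss)
                out.append(convolve_with_raw(sss, raw))
                out.append(niss)
                out.append(convolve_with_raw(niss, raw))
    return out
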
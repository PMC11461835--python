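"""Layer-1 augmentation: scaling/noise identities, count law, provenance."""

import numpy as np
import pytest

from somnaug.mcsa import (
    McsaConfig,
    convolve_with_raw,
    inject_noise_band_segment,
    run_mcsa,
    scale_band_segment,
)
from somnaug.preprocessing import BANDS


def _seg_power(seg, band, idx):
    return float(np.mean(seg.epochs[band][idx] ** 2))


def _out_band_seg_power(aug, seg, band, idx):
    """Power of one band-segment inside an augmented full trace.

    The untouched bands of the raw decomposition are subtracted, leaving
    the augmented band's contribution in that segment window.
    """
    lo, hi = idx * seg.epoch_len, (idx + 1) * seg.epoch_len
    others = sum(seg.epochs[b].reshape(-1)[lo:hi] for b in BANDS if b != band)
    return float(np.mean((aug.samples[lo:hi] - others) ** 2))


def test_factor_one_is_identity(segmented_cohort):
    seg, _ = segmented_cohort[0]
    aug = scale_band_segment(seg, "alpha", 0, 1.0)
    assert np.max(np.abs(aug.samples - seg.reconstruct())) <= 1e-9


def test_factor_two_quadruples_target_power_only(segmented_cohort):
    seg, _ = segmented_cohort[0]
    aug = scale_band_segment(seg, "alpha", 0, 2.0)
    assert _out_band_seg_power(aug, seg, "alpha", 0) == pytest.approx(
        4.0 * _seg_power(seg, "alpha", 0), rel=0.01
    )
    # untouched: delta in the scaled window, alpha in the other window
    raw = seg.reconstruct()
    lo, hi = seg.epoch_len, 2 * seg.epoch_len
    assert np.allclose(aug.samples[lo:hi], raw[lo:hi], rtol=0, atol=1e-9)


def test_factor_zero_silences_band_segment(segmented_cohort):
    seg, _ = segmented_cohort[0]
    aug = scale_band_segment(seg, "gamma", 1, 0.0)
    assert _out_band_seg_power(aug, seg, "gamma", 1) <= 1e-12


def test_unknown_band_and_bad_index_rejected(segmented_cohort):
    seg, _ = segmented_cohort[0]
    with pytest.raises(IndexError):
        scale_band_segment(seg, "sigma", 0, 1.5)
    with pytest.raises(IndexError):
        scale_band_segment(seg, "alpha", 99, 1.5)


def test_injected_noise_snr_measured(segmented_cohort):
    """Realized SNR of the injected noise is within 0.5 dB of configured."""
    seg, _ = segmented_cohort[0]
    aug = inject_noise_band_segment(seg, "theta", 0, snr_db=10.0, seed=5)
    raw = seg.reconstruct()
    lo, hi = 0, seg.epoch_len
    noise = aug.samples[lo:hi] - raw[lo:hi]
    p_sig = _seg_power(seg, "theta", 0)
    snr = 10 * np.log10(p_sig / np.mean(noise**2))
    assert snr == pytest.approx(10.0, abs=0.5)


def test_snr_cap_is_noiseless(segmented_cohort):
    seg, _ = segmented_cohort[0]
    aug = inject_noise_band_segment(seg, "theta", 0, snr_db=120.0, seed=5)
    raw = seg.reconstruct()
    assert np.max(np.abs(aug.samples - raw)) <= 1e-5 * np.max(np.abs(raw))


def test_noise_injection_deterministic(segmented_cohort):
    seg, _ = segmented_cohort[0]
    a = inject_noise_band_segment(seg, "beta", 1, 10.0, seed=9)
    b = inject_noise_band_segment(seg, "beta", 1, 10.0, seed=9)
    assert np.array_equal(a.samples, b.samples)
    c = inject_noise_band_segment(seg, "beta", 1, 10.0, seed=10)
    assert not np.array_equal(a.samples, c.samples)


def test_convolution_with_impulse_is_identity(segmented_cohort):
    from somnaug.meta import EEGSignal

    seg, _ = segmented_cohort[0]
    aug = scale_band_segment(seg, "alpha", 0, 1.5)
    n = len(aug.samples)
    impulse = np.zeros(n)
    impulse[(n - 1) // 2] = 1.0  # center of "same" alignment
    kernel = EEGSignal(impulse, aug.fs)
    out = convolve_with_raw(aug, kernel)
    assert out.samples == pytest.approx(aug.samples, abs=1e-9)
    assert out.provenance.op == "convolution"


def test_convolution_preserves_length_and_power(segmented_cohort):
    seg, raw = segmented_cohort[0]
    aug = scale_band_segment(seg, "delta", 0, 1.5)
    out = convolve_with_raw(aug, raw)
    assert len(out.samples) == len(aug.samples)
    p_ratio = np.mean(out.samples**2) / np.mean(aug.samples**2)
    assert p_ratio == pytest.approx(1.0, abs=1e-6)


def test_convolution_fs_mismatch_rejected(segmented_cohort):
    from somnaug.meta import EEGSignal

    seg, raw = segmented_cohort[0]
    aug = scale_band_segment(seg, "delta", 0, 1.5)
    other = EEGSignal(raw.samples, 256.0)
    with pytest.raises(ValueError, match="mismatch"):
        convolve_with_raw(aug, other)


def test_count_law_and_label_conservation(segmented_cohort):
    """4 signals per (subject, band, segment); labels inherited exactly."""
    cfg = McsaConfig(seed=1)
    out = run_mcsa(segmented_cohort, cfg)
    S = len(segmented_cohort)
    G = segmented_cohort[0][0].n_segments
    assert len(out) == 4 * S * 5 * G
    by_subject = {}
    for seg, _ in segmented_cohort:
        meta = seg.source.source.meta
        by_subject[meta.subject_id] = meta.group
    for aug in out:
        assert aug.label == by_subject[aug.provenance.source_subject]
    # balanced cohort stays balanced
    labels = [a.label.value for a in out]
    assert labels.count("insomnia") == labels.count("healthy")
    # every (cycle, op) combination present in equal number
    combos = [(a.provenance.cycle, a.provenance.op) for a in out]
    for combo in {("MCSA1", "addition"), ("MCSA1", "convolution"),
                  ("MCSA2", "addition"), ("MCSA2", "convolution")}:
        assert combos.count(combo) == S * 5 * G


def test_empty_cohort_gives_empty_list():
    assert run_mcsa([], McsaConfig()) == []


def test_addition_outputs_preserve_untouched_band_segments(segmented_cohort):
    """All band-segments except the targeted one match raw bit-close."""
    seg, _ = segmented_cohort[0]
    raw = seg.reconstruct()
    scale = np.max(np.abs(raw))
    for band in ("alpha", "gamma"):
        aug = scale_band_segment(seg, band, 0, 1.5)
        for g in range(1, seg.n_segments):
            lo, hi = g * seg.epoch_len, (g + 1) * seg.epoch_len
            assert np.max(np.abs(aug.samples[lo:hi] - raw[lo:hi])) <= 1e-9 * scale


@pytest.mark.parametrize("bad", [{"scale_factor": 0.0}, {"scale_factor": -1.0},
                                 {"snr_db": float("inf")}])
def test_invalid_config_rejected(bad):
    with pytest.raises(ValueError):
        McsaConfig(**bad)
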
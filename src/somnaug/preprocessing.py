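"""Denoising, band-limiting, DWT band decomposition and epoch segmentation.

The analysis chain is: wavelet denoise -> 0.5–45 Hz zero-phase Butterworth
bandpass -> 7-level db8 DWT -> per-band reconstruction -> fixed-length
epochs.

Band/level map at fs = 512 Hz (dyadic DWT sub-band edges; the clinical
12/30 Hz edges cannot fall on dyadic boundaries, the nearest dyadic
assignment is used and the prior bandpass suppresses out-of-band content):

====== =========== ==================
band    DWT levels  nominal range (Hz)
====== =========== ==================
delta   A7 + D7     0–4
theta   D6          4–8
alpha   D5          8–16
beta    D4          16–32
gamma   D3          32–64
(residual D1 + D2   > 64, discarded)
====== =========== ==================
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pywt
from scipy import signal as sps

from .meta import EEGSignal

#: canonical band order, slowest first
BANDS = ("delta", "theta", "alpha", "beta", "gamma")

# wavedec at level 7 returns [A7, D7, D6, D5, D4, D3, D2, D1]
_LEVEL_NAMES = ("A7", "D7", "D6", "D5", "D4", "D3", "D2", "D1")
_BAND_LEVELS_512 = {
    "delta": ("A7", "D7"),
    "theta": ("D6",),
    "alpha": ("D5",),
    "beta": ("D4",),
    "gamma": ("D3",),
}
_RESIDUAL_LEVELS = ("D2", "D1")
_DWT_LEVEL = 7
_WAVELET = "db8"


def denoise_wavelet(
    signal: EEGSignal,
    wavelet: str = "db8",
    level: int = 5,
    rule: str = "universal-soft",
) -> EEGSignal:
    """Wavelet denoising: universal threshold, soft shrinkage of details.

    The noise scale is the MAD of the finest detail level divided by
    0.6745; the threshold sigma*sqrt(2 ln n) is applied to detail
    coefficients only, the approximation is left untouched.
    """
    if rule != "universal-soft":
        raise ValueError(f"unsupported denoising rule: {rule!r}")
    x = signal.samples
    if len(x) < 2**level:
        raise ValueError(
            f"signal too short for level-{level} denoising: {len(x)} samples"
        )
    coeffs = pywt.wavedec(x, wavelet, level=level, mode="symmetric")
    d1 = coeffs[-1]
    sigma = np.median(np.abs(d1 - np.median(d1))) / 0.6745
    thr = sigma * np.sqrt(2.0 * np.log(len(x)))
    if thr == 0.0:  # noiseless input; pywt soft mode divides by |coeff|
        return EEGSignal(x.copy(), signal.fs, signal.meta)
    den = [coeffs[0]] + [pywt.threshold(c, thr, mode="soft") for c in coeffs[1:]]
    y = pywt.waverec(den, wavelet, mode="symmetric")[: len(x)]
    return EEGSignal(y, signal.fs, signal.meta)


def bandpass_filter(
    signal: EEGSignal,
    lo: float = 0.5,
    hi: float = 45.0,
    order: int = 4,
) -> EEGSignal:
    """Zero-phase (forward-backward) Butterworth bandpass."""
    fs = signal.fs
    if not (0.0 < lo < hi):
        raise ValueError(f"need 0 < lo < hi, got lo={lo}, hi={hi}")
    if hi >= fs / 2.0:
        raise ValueError(f"hi={hi} Hz must be below Nyquist ({fs / 2} Hz)")
    sos = sps.butter(order, [lo, hi], btype="bandpass", fs=fs, output="sos")
    y = sps.sosfiltfilt(sos, signal.samples, padtype="even")
    return EEGSignal(y, fs, signal.meta)


@dataclass
class BandDecomposition:
    """Five time-domain band reconstructions plus the discarded residual."""

    bands: dict[str, np.ndarray]
    residual: np.ndarray
    source: EEGSignal = field(repr=False)

    @property
    def fs(self) -> float:
        return self.source.fs

    def reconstruction(self) -> np.ndarray:
        """Sum of the five bands plus the residual (== DWT input)."""
        return sum(self.bands.values()) + self.residual


def decompose_bands(
    signal: EEGSignal,
    wavelet: str = _WAVELET,
    mode: str = "symmetric",
    band_levels: dict[str, tuple[str, ...]] | None = None,
) -> BandDecomposition:
    """7-level db8 DWT decomposition into the five clinical bands.

    Each band is the inverse DWT of its coefficient levels with every other
    level zeroed, so the five bands plus the residual sum back to the input
    exactly (linearity of the inverse transform).

    The built-in level map assumes fs = 512 Hz; other rates require an
    explicit ``band_levels`` map.
    """
    x = signal.samples
    if len(x) < 2**7:
        raise ValueError(f"signal too short for 7-level DWT: {len(x)} samples")
    if band_levels is None:
        if abs(signal.fs - 512.0) > 1e-9:
            raise ValueError(
                f"built-in band/level map assumes fs = 512 Hz, got {signal.fs}; "
                "pass an explicit band_levels map"
            )
        band_levels = _BAND_LEVELS_512
    coeffs = pywt.wavedec(x, wavelet, level=_DWT_LEVEL, mode=mode)
    index = {nm: i for i, nm in enumerate(_LEVEL_NAMES)}

    def _rec(level_names: tuple[str, ...]) -> np.ndarray:
        keep = {index[nm] for nm in level_names}
        cs = [c if i in keep else np.zeros_like(c) for i, c in enumerate(coeffs)]
        return pywt.waverec(cs, wavelet, mode=mode)[: len(x)]

    bands = {b: _rec(levels) for b, levels in band_levels.items()}
    residual = _rec(_RESIDUAL_LEVELS)
    return BandDecomposition(bands=bands, residual=residual, source=signal)


@dataclass
class SegmentedBands:
    """Per-band stacks of aligned, non-overlapping fixed-length epochs.

    ``epochs[band]`` has shape ``(n_segments, epoch_len)``; a trailing
    partial epoch is dropped.
    """

    epochs: dict[str, np.ndarray]
    epoch_s: float
    fs: float
    source: BandDecomposition = field(repr=False)

    @property
    def n_segments(self) -> int:
        return next(iter(self.epochs.values())).shape[0]

    @property
    def epoch_len(self) -> int:
        return next(iter(self.epochs.values())).shape[1]

    def reconstruct(self) -> np.ndarray:
        """Sum the raw band epochs back into one trace of covered length."""
        return sum(e.reshape(-1) for e in self.epochs.values())


def segment(decomp: BandDecomposition, epoch_s: float = 30.0) -> SegmentedBands:
    """Cut every band into identical aligned non-overlapping epochs."""
    fs = decomp.fs
    epoch_len = int(round(epoch_s * fs))
    if epoch_len < 1:
        raise ValueError(f"epoch of {epoch_s} s is shorter than one sample")
    n = len(next(iter(decomp.bands.values())))
    n_seg = n // epoch_len
    if n_seg == 0:
        raise ValueError(
            f"epoch of {epoch_len} samples longer than signal of {n} samples"
        )
    cut = n_seg * epoch_len
    epochs = {
        b: decomp.bands[b][:cut].reshape(n_seg, epoch_len).copy() for b in BANDS
    }
    return SegmentedBands(epochs=epochs, epoch_s=epoch_s, fs=fs, source=decomp)


def preprocess(
    signal: EEGSignal,
    lo: float = 0.5,
    hi: float = 45.0,
    order: int = 4,
    denoise_level: int = 5,
    epoch_s: float = 30.0,
) -> SegmentedBands:
    """Full chain: denoise -> bandpass -> band decomposition -> epochs."""
    den = denoise_wavelet(signal, level=denoise_level)
    filt = bandpass_filter(den, lo=lo, hi=hi, order=order)
    return segment(decompose_bands(filt), epoch_s=epoch_s)
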
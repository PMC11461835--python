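"""Band-wise feature extraction: entropies, band power and moments.

Nine features per band — sample entropy, spectral entropy, Shannon
entropy, log-energy entropy, band power, mean, standard deviation,
skewness and excess kurtosis — over the five clinical bands give the
45-column feature table that both augmentation layer 2 and the
classifiers consume.

Sample entropy is quadratic in the sequence length, so on full-length
band reconstructions it is evaluated on a uniformly strided subsequence
of at most ``SAMPEN_MAX_SAMPLES`` points (all other features use every
sample).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy import stats

from .meta import EEGSignal
from .mcsa import AugmentedSignal
from .preprocessing import BANDS, decompose_bands

#: fixed feature order within each band
FEATURE_NAMES = (
    "sample_entropy",
    "spectral_entropy",
    "shannon_entropy",
    "log_energy_entropy",
    "band_power",
    "mean",
    "std",
    "skewness",
    "kurtosis",
)

#: the 45 numeric columns of the feature table, band-major
FEATURE_COLUMNS = tuple(f"{b}_{f}" for b in BANDS for f in FEATURE_NAMES)

SAMPEN_MAX_SAMPLES = 1024
LEE_EPS = 1e-12


def sample_entropy(x, m: int = 2, r: float = 0.2) -> float:
    """Sample entropy: −ln(A/B) with Chebyshev distance, self-matches excluded.

    ``r`` is a fraction of the sequence's (population) standard deviation.
    Template matching uses N − m − 1 templates of length m and m+1 alike,
    the convention under which SampEn of a constant sequence is 0.  When no
    m+1 matches exist the value is capped at ``ln(B_max·(B_max−1))`` instead
    of returning infinity.
    """
    x = np.asarray(x, dtype=np.float64)
    n = x.size
    if n <= m + 1:
        raise ValueError(f"need length > m+1 = {m + 1}, got {n}")
    tol = r * x.std()
    # pairwise scalar closeness; ANDing diagonal shifts extends matches to
    # any template length in O(n^2) booleans.  A and B share the same
    # nt = n - m template start positions.
    close = np.abs(x[:, None] - x[None, :]) <= tol
    nt = n - m
    match_m = close[:nt, :nt].copy()
    for k in range(1, m):
        match_m &= close[k : k + nt, k : k + nt]
    b_count = int(match_m.sum()) - nt  # minus self-pairs
    match_m1 = match_m & close[m : m + nt, m : m + nt]
    a_count = int(match_m1.sum()) - nt
    cap = np.log(nt * (nt - 1)) if nt > 1 else 0.0
    if a_count <= 0 or b_count <= 0:
        return float(cap)
    return float(-np.log(a_count / b_count))


def spectral_entropy(x, fs: float) -> float:
    """Normalized Shannon entropy of the Welch PSD, in [0, 1]."""
    x = np.asarray(x, dtype=np.float64)
    if x.size < 64:
        raise ValueError(f"need at least 64 samples, got {x.size}")
    if not np.any(x):
        return 0.0
    nperseg = min(1024, x.size)
    _, psd = sps.welch(x, fs=fs, nperseg=nperseg)
    total = psd.sum()
    if total <= 0:
        return 0.0
    p = psd / total
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum() / np.log2(len(psd)))


def shannon_entropy(x, bins: int = 256) -> float:
    """Histogram Shannon entropy in bits over equal-width amplitude bins."""
    x = np.asarray(x, dtype=np.float64)
    if x.size < max(1, bins // 8):
        raise ValueError(f"need at least {bins // 8} samples, got {x.size}")
    if np.ptp(x) == 0:
        return 0.0
    counts, _ = np.histogram(x, bins=bins)
    p = counts[counts > 0] / x.size
    return float(-(p * np.log2(p)).sum())


def log_energy_entropy(x) -> float:
    """Log-energy entropy: sum of log(x_i^2 + eps)."""
    x = np.asarray(x, dtype=np.float64)
    return float(np.log(x**2 + LEE_EPS).sum())


def band_power(band_signal) -> float:
    """Mean squared amplitude (µV²) of a band-limited time series."""
    x = np.asarray(band_signal, dtype=np.float64)
    return float(np.mean(x**2))


def stat_moments(x) -> tuple[float, float, float, float]:
    """(mean, population std, skewness, excess kurtosis); 0s at zero variance."""
    x = np.asarray(x, dtype=np.float64)
    if x.size < 4:
        raise ValueError(f"need at least 4 samples, got {x.size}")
    mu = float(x.mean())
    sd = float(x.std())
    if sd == 0.0:
        return (mu, 0.0, 0.0, 0.0)
    return (
        mu,
        sd,
        float(stats.skew(x)),
        float(stats.kurtosis(x)),  # Fisher: Gaussian -> 0
    )


def _strided(x: np.ndarray, max_n: int) -> np.ndarray:
    if x.size <= max_n:
        return x
    step = int(np.ceil(x.size / max_n))
    return x[::step]


def band_features(band_signal: np.ndarray, fs: float) -> dict[str, float]:
    """All nine features of one band-limited trace."""
    mu, sd, sk, ku = stat_moments(band_signal)
    return {
        "sample_entropy": sample_entropy(_strided(band_signal, SAMPEN_MAX_SAMPLES)),
        "spectral_entropy": spectral_entropy(band_signal, fs),
        "shannon_entropy": shannon_entropy(band_signal),
        "log_energy_entropy": log_energy_entropy(band_signal),
        "band_power": band_power(band_signal),
        "mean": mu,
        "std": sd,
        "skewness": sk,
        "kurtosis": ku,
    }


def extract_table(signals: list[AugmentedSignal | EEGSignal]) -> pd.DataFrame:
    """Assemble the labeled 45-column feature table.

    Each signal is decomposed into its five bands (7-level db8 DWT) and the
    nine features are computed on each full-length band reconstruction.
    Rows carry ``label``, ``subject_id`` and a ``provenance`` tag
    ("real" or "cycle:op:band:segment").
    """
    rows = []
    for sig in signals:
        if isinstance(sig, AugmentedSignal):
            label = sig.label.value
            subject = sig.provenance.source_subject
            p = sig.provenance
            prov = f"{p.cycle}:{p.op}:{p.band}:{p.segment_idx}"
            as_eeg = EEGSignal(sig.samples, sig.fs)
        else:
            if sig.meta is None:
                raise ValueError("EEGSignal without metadata has no label")
            label = sig.meta.group.value
            subject = sig.meta.subject_id
            prov = "real"
            as_eeg = sig
        decomp = decompose_bands(as_eeg)
        row: dict[str, object] = {}
        for b in BANDS:
            feats = band_features(decomp.bands[b], as_eeg.fs)
            for f in FEATURE_NAMES:
                row[f"{b}_{f}"] = feats[f]
        row["label"] = label
        row["subject_id"] = subject
        row["provenance"] = prov
        rows.append(row)
    df = pd.DataFrame(rows, columns=list(FEATURE_COLUMNS) + ["label", "subject_id", "provenance"])
    if df[list(FEATURE_COLUMNS)].isna().any().any():
        raise AssertionError("feature table contains missing values")
    return df
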
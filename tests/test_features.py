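"""Feature extraction: entropy oracles, moment conventions, table contract."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from somnaug.features import (
    FEATURE_COLUMNS,
    band_power,
    extract_table,
    log_energy_entropy,
    sample_entropy,
    shannon_entropy,
    spectral_entropy,
    stat_moments,
)

FS = 512.0


# ------------------------------------------------------------ SampEn oracle

def sampen_bruteforce(x, m=2, r=0.2):
    """Exhaustive O(n^2) template-pair count, written independently."""
    x = np.asarray(x, float)
    n = len(x)
    tol = r * x.std()
    nt = n - m

    def count(length):
        c = 0
        for i in range(nt):
            for j in range(nt):
                if i == j:
                    continue
                if max(abs(x[i + k] - x[j + k]) for k in range(length)) <= tol:
                    c += 1
        return c

    b = count(m)
    a = count(m + 1)
    if a <= 0 or b <= 0:
        return np.log(nt * (nt - 1))
    return -np.log(a / b)


@settings(max_examples=40, deadline=None, derandomize=True)
@given(st.integers(min_value=0, max_value=10_000),
       st.integers(min_value=8, max_value=30))
def test_sample_entropy_matches_bruteforce(seed, n):
    x = np.random.default_rng(seed).standard_normal(n)
    assert sample_entropy(x) == pytest.approx(sampen_bruteforce(x), abs=1e-12)


def test_sample_entropy_repeating_pattern_matches_oracle():
    x = np.tile([1.0, -1.0], 10)
    assert sample_entropy(x) == pytest.approx(sampen_bruteforce(x), abs=1e-12)


def test_sample_entropy_constant_is_zero():
    assert sample_entropy(np.ones(50)) == pytest.approx(0.0, abs=1e-12)


def test_sample_entropy_noise_exceeds_sinusoid():
    rng = np.random.default_rng(3)
    noise = rng.standard_normal(2000)
    t = np.arange(2000)
    sine = np.sqrt(2.0) * np.sin(2 * np.pi * 0.01 * t)  # equal variance
    assert sample_entropy(noise) > sample_entropy(sine)


def test_sample_entropy_too_short_rejected():
    with pytest.raises(ValueError):
        sample_entropy([1.0, 2.0, 3.0])


# --------------------------------------------------------- other entropies

def test_spectral_entropy_sinusoid_low():
    t = np.arange(8192) / FS
    assert spectral_entropy(np.sin(2 * np.pi * 10 * t), FS) <= 0.2


def test_spectral_entropy_white_noise_high(rng):
    assert spectral_entropy(rng.standard_normal(8192), FS) >= 0.9


def test_spectral_entropy_scale_invariant(rng):
    x = rng.standard_normal(4096)
    assert spectral_entropy(3.7 * x, FS) == pytest.approx(
        spectral_entropy(x, FS), abs=1e-12
    )


def test_spectral_entropy_zero_signal():
    assert spectral_entropy(np.zeros(256), FS) == 0.0


def test_shannon_entropy_uniform_8_bins():
    x = (np.arange(8) + 0.5) / 8.0  # one sample per bin
    assert shannon_entropy(x, bins=8) == pytest.approx(3.0, abs=1e-12)


def test_shannon_entropy_constant_zero_and_bounds(rng):
    assert shannon_entropy(np.ones(64)) == 0.0
    x = rng.standard_normal(4096)
    assert 0.0 <= shannon_entropy(x) <= np.log2(256)


def test_shannon_entropy_affine_invariant(rng):
    """Equal-width bins over the observed range ignore affine amplitude maps."""
    x = rng.standard_normal(4096)
    assert shannon_entropy(2.5 * x + 7.0) == pytest.approx(
        shannon_entropy(x), abs=1e-12
    )


def test_log_energy_entropy_identities():
    # the epsilon regularizer contributes ~n*eps = 4e-12
    assert log_energy_entropy([1.0, 1.0, 1.0, 1.0]) == pytest.approx(0.0, abs=1e-11)
    assert log_energy_entropy([np.e, np.e]) == pytest.approx(4.0, abs=1e-9)


def test_log_energy_entropy_doubling_identity(rng):
    x = rng.standard_normal(500) + 1.0  # bounded away from 0 so eps is negligible
    n = len(x)
    assert log_energy_entropy(2 * x) - log_energy_entropy(x) == pytest.approx(
        n * np.log(4.0), rel=1e-9
    )


# ------------------------------------------------------- power and moments

def test_band_power_unit_sinusoid():
    t = np.arange(int(100 * FS)) / FS
    assert band_power(np.sin(2 * np.pi * 10 * t)) == pytest.approx(0.5, rel=0.01)


def test_band_power_zero_and_quadratic_scaling(rng):
    assert band_power(np.zeros(100)) == 0.0
    x = rng.standard_normal(1000)
    assert band_power(3.0 * x) == pytest.approx(9.0 * band_power(x), rel=1e-12)


def test_moments_symmetric_sequence():
    mu, sd, sk, ku = stat_moments([-2.0, -1.0, 1.0, 2.0])
    assert mu == 0.0
    assert sk == 0.0
    assert sd == pytest.approx(np.sqrt(2.5))


def test_moments_gaussian_kurtosis_near_zero():
    g = np.random.default_rng(1).standard_normal(100_000)
    assert stat_moments(g)[3] == pytest.approx(0.0, abs=0.05)


def test_moments_constant_sequence():
    assert stat_moments([3.0] * 10) == (3.0, 0.0, 0.0, 0.0)


# ----------------------------------------------------------- feature table

def test_table_shape_and_no_missing(segmented_cohort):
    from somnaug.mcsa import McsaConfig, run_mcsa

    aug = run_mcsa(segmented_cohort[:1], McsaConfig(seed=0))
    table = extract_table(aug)
    assert len(table) == len(aug)
    assert list(table.columns[:45]) == list(FEATURE_COLUMNS)
    assert not table[list(FEATURE_COLUMNS)].isna().any().any()
    assert set(table["label"]) <= {"insomnia", "healthy"}


def test_identical_signals_identical_rows(small_cohort):
    sig = small_cohort[0]
    table = extract_table([sig, sig])
    a, b = table.iloc[0][list(FEATURE_COLUMNS)], table.iloc[1][list(FEATURE_COLUMNS)]
    assert (a == b).all()


def test_planted_alpha_gap_visible_in_class_means(small_cohort):
    table = extract_table(small_cohort)
    means = table.groupby("label")["alpha_band_power"].mean()
    assert means["insomnia"] > means["healthy"]
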
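"""Feature math: periodogram, relative power, fuzzy entropy, phase lag index.

Fuzzy entropy and PLI are checked against independent brute-force
implementations written directly from their defining sums.
"""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.signal import butter, hilbert, sosfiltfilt

from szeeg import (
    DEFAULT_BANDS,
    DEFAULT_BOUNDS,
    FeatureError,
    FuzEnParams,
    InputError,
    fuzzy_entropy,
    pli,
    pli_matrix,
    power_spectrum,
    relative_power,
)

FS = 128.0
N = 512
ALPHA = DEFAULT_BANDS[2]


def random_window(seed, n=N, band=None):
    x = np.random.default_rng(seed).standard_normal(n)
    if band is not None:
        sos = butter(4, [band.f_lo, band.f_hi], btype="bandpass",
                     fs=FS, output="sos")
        x = sosfiltfilt(sos, x)
    return x


# ---------------------------------------------------------------------------
# Independent oracles


def fuzen_bruteforce(x, m=2, k=0.2):
    """Direct evaluation of the FuzEn defining sums.

    Mean-centered subsequences, Chebyshev distances, Gaussian-like fuzzy
    membership, averaged over all ordered pairs i != j; dimension m uses
    N-m subsequences and dimension m+1 uses N-m-1.
    """
    x = np.asarray(x, float)
    r = k * x.std()

    def mean_membership(mm, count):
        vecs = np.array([x[i:i + mm] - x[i:i + mm].mean()
                         for i in range(count)])
        tot = 0.0
        for i in range(count):
            d = np.abs(vecs - vecs[i]).max(axis=1)
            w = np.exp(-np.log(2.0) * (d / r) ** 2)
            tot += w.sum() - w[i]  # exclude the self pair
        return tot / (count * (count - 1))

    n = x.size
    return (math.log(mean_membership(m, n - m))
            - math.log(mean_membership(m + 1, n - m - 1)))


def fuzen_pure_python(x, m=2, k=0.2):
    """Fully scalar double-loop FuzEn for very short windows."""
    x = [float(v) for v in x]
    n = len(x)
    r = k * float(np.std(x))

    def mean_membership(mm, count):
        vecs = []
        for i in range(count):
            seq = x[i:i + mm]
            mu = sum(seq) / mm
            vecs.append([v - mu for v in seq])
        tot, cnt = 0.0, 0
        for i in range(count):
            for j in range(count):
                if i == j:
                    continue
                d = max(abs(a - b) for a, b in zip(vecs[i], vecs[j]))
                tot += math.exp(-math.log(2.0) * (d / r) ** 2)
                cnt += 1
        return tot / cnt

    return (math.log(mean_membership(m, n - m))
            - math.log(mean_membership(m + 1, n - m - 1)))


def pli_bruteforce(x, y, trim=0.05):
    """Signum-of-phase-difference average, one sample at a time."""
    phx = np.angle(hilbert(x))
    phy = np.angle(hilbert(y))
    k = int(round(trim * len(x)))
    total = 0
    for t in range(k, len(x) - k):
        d = phx[t] - phy[t]
        while d <= -np.pi:
            d += 2 * np.pi
        while d > np.pi:
            d -= 2 * np.pi
        if abs(d - np.pi) < 1e-15:  # wrap convention: pi -> -pi
            d = -np.pi
        total += int(d > 0) - int(d < 0)
    return abs(total / (len(x) - 2 * k))


# ---------------------------------------------------------------------------
# Power spectrum


class TestPowerSpectrum:
    def test_sinusoid_mass_on_its_bin(self):
        t = np.arange(N) / FS
        freqs, pxx = power_spectrum(np.sin(2 * np.pi * 10.0 * t), FS)
        bin_10 = int(np.argmin(np.abs(freqs - 10.0)))
        mass = pxx[bin_10 - 1 : bin_10 + 2].sum()
        assert mass > 0.99 * pxx.sum()

    def test_zero_signal_gives_zero_spectrum(self):
        _, pxx = power_spectrum(np.zeros(N), FS)
        assert np.all(pxx == 0)

    @pytest.mark.parametrize("n", [N, N + 1])  # even and odd lengths
    def test_parseval_identity(self, n):
        x = random_window(7, n=n)
        _, pxx = power_spectrum(x, FS)
        assert pxx.sum() == pytest.approx(np.mean(x**2), rel=1e-9)

    def test_too_short_signal_rejected(self):
        with pytest.raises(InputError):
            power_spectrum(np.array([1.0]), FS)


class TestRelativePower:
    def test_flat_spectrum_scores_one_in_every_band(self):
        freqs = np.fft.rfftfreq(N, 1 / FS)
        pxx = np.ones_like(freqs)
        for band in DEFAULT_BANDS:
            assert relative_power(freqs, pxx, band) == pytest.approx(1.0)

    def test_pure_alpha_sinusoid(self):
        t = np.arange(N) / FS
        freqs, pxx = power_spectrum(np.sin(2 * np.pi * 10.0 * t), FS)
        rp = {b.name: relative_power(freqs, pxx, b) for b in DEFAULT_BANDS}
        assert rp["Alpha"] == pytest.approx(44.5 / 5.0, rel=1e-6)
        for name in ("Delta", "Theta", "Beta", "Gamma"):
            assert rp[name] < 1e-6

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(0, 10**6))
    def test_bandwidth_weighted_sum_is_one(self, seed):
        freqs, pxx = power_spectrum(random_window(seed), FS)
        total = sum(
            relative_power(freqs, pxx, b) * b.width
            / (DEFAULT_BOUNDS.f_m - DEFAULT_BOUNDS.f_n)
            for b in DEFAULT_BANDS
        )
        assert total == pytest.approx(1.0, abs=1e-9)

    def test_zero_power_flagged(self):
        freqs = np.fft.rfftfreq(N, 1 / FS)
        with pytest.raises(FeatureError):
            relative_power(freqs, np.zeros_like(freqs), ALPHA)


# ---------------------------------------------------------------------------
# Fuzzy entropy


class TestFuzzyEntropy:
    def test_scale_invariance_power_of_two_exact(self):
        x = random_window(1)
        assert fuzzy_entropy(4.0 * x) == fuzzy_entropy(x)

    def test_scale_invariance_general_factor(self):
        x = random_window(2)
        assert fuzzy_entropy(5.0 * x) == pytest.approx(
            fuzzy_entropy(x), rel=1e-10
        )

    def test_noise_more_irregular_than_sinusoid(self):
        t = np.arange(N) / FS
        tone = np.sin(2 * np.pi * 10.0 * t)
        assert fuzzy_entropy(random_window(3)) > fuzzy_entropy(tone)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.integers(0, 10**6))
    def test_non_negative_on_noise_windows(self, seed):
        assert fuzzy_entropy(random_window(seed, n=256)) >= 0.0

    def test_constant_signal_flagged(self):
        with pytest.raises(FeatureError):
            fuzzy_entropy(np.ones(64))

    def test_too_short_signal_rejected(self):
        with pytest.raises(InputError):
            fuzzy_entropy(np.array([0.0, 1.0, 0.5]), FuzEnParams(m=2))

    def test_matches_bruteforce_oracle(self):
        for seed in range(10):
            x = random_window(seed, band=ALPHA if seed % 2 else None)
            assert fuzzy_entropy(x) == pytest.approx(
                fuzen_bruteforce(x), abs=1e-10
            )

    def test_matches_pure_python_oracle_short_windows(self):
        for seed in range(5):
            x = random_window(seed, n=64)
            assert fuzzy_entropy(x) == pytest.approx(
                fuzen_pure_python(x), abs=1e-10
            )


# ---------------------------------------------------------------------------
# Phase lag index


class TestPli:
    def test_identical_signals_give_exact_zero(self):
        x = random_window(4, band=ALPHA)
        assert pli(x, x) == 0.0

    @pytest.mark.parametrize("trim", [0.0, 0.05])
    def test_constant_lag_sinusoid_gives_one(self, trim):
        t = np.arange(N) / FS
        x = np.sin(2 * np.pi * 10.0 * t)
        y = np.sin(2 * np.pi * 10.0 * t - np.pi / 4)
        assert pli(x, y, edge_trim=trim) == 1.0

    def test_independent_noise_near_null_level(self):
        values = [
            pli(random_window(2 * s, band=ALPHA),
                random_window(2 * s + 1, band=ALPHA))
            for s in range(20)
        ]
        assert np.mean(values) < 0.2
        assert max(values) < 0.5

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.integers(0, 10**6))
    def test_symmetry_bounds_and_scale_invariance(self, seed):
        x = random_window(seed, band=ALPHA)
        y = random_window(seed + 10**7, band=ALPHA)
        v = pli(x, y)
        assert 0.0 <= v <= 1.0
        assert pli(y, x) == v
        assert pli(3.5 * x, y) == v

    def test_length_mismatch_rejected(self):
        with pytest.raises(InputError):
            pli(np.zeros(10), np.zeros(11))

    def test_matches_bruteforce_oracle(self):
        for s in range(50):
            x = random_window(3 * s, band=ALPHA)
            y = random_window(3 * s + 1, band=ALPHA)
            assert pli(x, y) == pytest.approx(pli_bruteforce(x, y), abs=1e-12)


class TestPliMatrix:
    def test_symmetric_zero_diagonal_bounded(self):
        w = np.vstack([random_window(s, band=ALPHA) for s in range(16)])
        mat = pli_matrix(w)
        assert mat.shape == (16, 16)
        assert np.array_equal(mat, mat.T)
        assert np.all(np.diag(mat) == 0)
        assert np.all((mat >= 0) & (mat <= 1))

    def test_unique_pair_count(self):
        assert len(np.triu_indices(16, 1)[0]) == 120

    def test_independent_channels_stay_near_null(self):
        w = np.vstack([random_window(100 + s, band=ALPHA) for s in range(16)])
        mat = pli_matrix(w)
        iu = np.triu_indices(16, 1)
        assert mat[iu].mean() < 0.2

    def test_matches_pairwise_pli(self):
        w = np.vstack([random_window(s, band=ALPHA) for s in range(4)])
        mat = pli_matrix(w)
        for i in range(4):
            for j in range(i + 1, 4):
                assert mat[i, j] == pytest.approx(pli(w[i], w[j]), abs=1e-12)
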
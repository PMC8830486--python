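"""Entropy measures against exhaustive counting oracles and known limits."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from neoprog.complexity import (
    EntropyConfig,
    entropy_feature_table,
    permutation_entropy,
    sample_entropy,
    spectral_entropy,
)


def sampen_oracle(x, m, r):
    """Exhaustive double-loop template counting."""
    n = len(x)
    b = a = 0
    for i in range(n - m):
        for j in range(n - m):
            if i == j:
                continue
            if max(abs(x[i + k] - x[j + k]) for k in range(m)) <= r:
                b += 1
            if max(abs(x[i + k] - x[j + k]) for k in range(m + 1)) <= r:
                a += 1
    if a == 0 or b == 0:
        return math.log(max((n - m - 1) * (n - m), 2))
    return -math.log(a / b)


def pen_oracle(x, n, delay):
    counts = {}
    for i in range(len(x) - (n - 1) * delay):
        window = [x[i + k * delay] for k in range(n)]
        pattern = tuple(sorted(range(n), key=lambda k: window[k]))
        counts[pattern] = counts.get(pattern, 0) + 1
    total = sum(counts.values())
    h = -sum(c / total * math.log(c / total) for c in counts.values())
    return h / math.log(math.factorial(n))


class TestSampleEntropy:
    def test_constant_series_is_zero(self):
        assert sample_entropy(np.ones(20), m=2, r_abs=0.0) == 0.0

    def test_repeating_pattern_matches_oracle(self):
        x = np.array([1, 2, 1, 2, 1, 2, 1, 2, 1, 2], float)
        assert sample_entropy(x, 2, 0.5) == pytest.approx(
            sampen_oracle(x, 2, 0.5), abs=1e-12
        )

    @pytest.mark.parametrize("m", [1, 2, 3])
    def test_random_series_match_oracle(self, rng, m):
        for _ in range(100):
            n = int(rng.integers(m + 5, 50))
            x = np.round(rng.standard_normal(n), 2)
            r = float(rng.uniform(0.05, 0.5))
            assert sample_entropy(x, m, r) == pytest.approx(
                sampen_oracle(x, m, r), abs=1e-12
            )

    def test_monotone_non_increasing_in_tolerance(self, rng):
        x = rng.standard_normal(120)
        values = [sample_entropy(x, 2, r) for r in (0.1, 0.2, 0.3, 0.5, 1.0)]
        assert all(a >= b - 1e-12 for a, b in zip(values, values[1:]))

    def test_noise_more_irregular_than_sine(self, rng):
        t = np.arange(200) / 50.0
        noise_vals, sine_vals = [], []
        for seed in range(50):
            g = np.random.default_rng(seed)
            noise = g.standard_normal(200)
            sine = np.sin(2 * np.pi * 3 * t + g.uniform(0, 6))
            noise_vals.append(sample_entropy(noise, 2, 0.2 * noise.std()))
            sine_vals.append(sample_entropy(sine, 2, 0.2 * sine.std()))
        assert np.median(noise_vals) > np.median(sine_vals)

    def test_too_short_series_rejected(self):
        with pytest.raises(ValueError, match="too short"):
            sample_entropy(np.arange(4.0), m=3)


class TestPermutationEntropy:
    @pytest.mark.parametrize("x", [np.arange(20.0), -np.arange(20.0)])
    def test_monotone_series_is_zero(self, x):
        assert permutation_entropy(x, 3, 1) == 0.0

    def test_worked_example_matches_oracle(self):
        x = np.array([4, 7, 9, 10, 6, 11, 3], float)
        assert permutation_entropy(x, 3, 1) == pytest.approx(
            pen_oracle(x, 3, 1), abs=1e-12
        )

    @pytest.mark.parametrize("n,delay", [(2, 1), (3, 1), (3, 2), (4, 1)])
    def test_random_series_match_oracle(self, rng, n, delay):
        for _ in range(25):
            x = rng.standard_normal(int(rng.integers((n - 1) * delay + 2, 50)))
            assert permutation_entropy(x, n, delay) == pytest.approx(
                pen_oracle(x, n, delay), abs=1e-12
            )

    @settings(max_examples=30, deadline=None)
    @given(
        st.lists(st.integers(-10**6, 10**6), min_size=10, max_size=40, unique=True)
    )
    def test_invariant_under_monotone_transform(self, values):
        # integer-valued floats keep both transforms exactly order-preserving
        x = np.asarray(values, dtype=float)
        base = permutation_entropy(x, 3, 1)
        assert permutation_entropy(3.0 * x + 7.0, 3, 1) == pytest.approx(base, abs=1e-12)
        assert permutation_entropy(np.arctan(x / 1e3), 3, 1) == pytest.approx(
            base, abs=1e-12
        )

    def test_printed_normalizer_option_rescales_by_constant(self):
        x = np.random.default_rng(0).standard_normal(100)
        ratio = permutation_entropy(x, 3, 1, "as_printed_ln_n") / permutation_entropy(
            x, 3, 1, "factorial_ln_n!"
        )
        assert ratio == pytest.approx(math.log(6) / math.log(3), abs=1e-12)

    def test_too_short_series_rejected(self):
        with pytest.raises(ValueError, match="too short"):
            permutation_entropy(np.arange(3.0), n=3, delay=2)


class TestSpectralEntropy:
    def test_pure_tone_concentrates(self):
        t = np.arange(256) / 64.0
        assert spectral_entropy(np.sin(2 * np.pi * 8 * t), 64.0) < 0.05

    def test_two_equal_tones_give_ln2(self):
        t = np.arange(512) / 64.0
        x = np.sin(2 * np.pi * 4 * t) + np.sin(2 * np.pi * 12 * t)
        assert spectral_entropy(x, 64.0) == pytest.approx(math.log(2), rel=0.05)

    def test_white_noise_approaches_flat_spectrum_limit(self):
        fs, n = 64.0, 256
        vals = [
            spectral_entropy(np.random.default_rng(s).standard_normal(n), fs)
            for s in range(20)
        ]
        n_bins = np.count_nonzero(
            (np.fft.rfftfreq(n, 1 / fs) >= 0.5) & (np.fft.rfftfreq(n, 1 / fs) <= 32.0)
        )
        assert np.mean(vals) == pytest.approx(math.log(n_bins), rel=0.10)

    def test_amplitude_scaling_invariance(self, rng):
        x = rng.standard_normal(256)
        assert spectral_entropy(17.3 * x, 64.0) == pytest.approx(
            spectral_entropy(x, 64.0), abs=1e-12
        )

    def test_band_above_nyquist_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            spectral_entropy(np.ones(64), 16.0, band=(10.0, 20.0))


class TestEntropyFeatureTable:
    def _imfs(self, rng, n_channels=12, n_modes=1, n_rows=4, n_samples=128):
        labels = ["C3", "F3", "F7", "FZ", "O1", "O2", "P3", "P4", "T3", "T4", "T5", "T6"]
        return {
            lab: rng.standard_normal((n_modes, n_rows, n_samples))
            for lab in labels[:n_channels]
        }

    def test_twelve_channels_one_mode_gives_36_features(self, rng):
        table = entropy_feature_table(self._imfs(rng), 64.0)
        assert table.shape == (1, 36)

    def test_identical_epochs_average_to_single_epoch_value(self, rng):
        epoch = rng.standard_normal(128)
        imfs = {"C3": np.tile(epoch, (1, 5, 1)), "O1": np.tile(epoch, (1, 5, 1))}
        table = entropy_feature_table(imfs, 64.0)
        single = entropy_feature_table(
            {"C3": epoch[None, None, :], "O1": epoch[None, None, :]}, 64.0
        )
        assert np.allclose(table.to_numpy(), single.to_numpy())

    def test_epoch_order_irrelevant(self, rng):
        arr = rng.standard_normal((1, 6, 128))
        t1 = entropy_feature_table({"C3": arr, "O1": arr[:, ::-1]}, 64.0)
        t2 = entropy_feature_table({"C3": arr[:, ::-1], "O1": arr}, 64.0)
        assert np.allclose(t1["pen_C3_imf0"], t2["pen_C3_imf0"])
        assert np.allclose(t1["sampen_O1_imf0"], t2["sampen_O1_imf0"])

    def test_subject_rankings_robust_to_embedding_parameters(self, rng):
        """Across the recommended SampEn parameter grid, the ranking of
        subjects should be stable (cross-setting Spearman > 0.8)."""
        from scipy.stats import spearmanr

        # subjects with graded noise-to-signal mixtures, inside the range
        # where SampEn still responds to the mixing weight (it saturates for
        # noise-dominated mixtures)
        t = np.arange(512) / 64.0
        imfs_by_subject = {}
        for s, w in enumerate(np.linspace(0.05, 0.5, 10)):
            g = np.random.default_rng(100 + s)
            rowset = np.stack(
                [
                    (1 - w) * np.sin(2 * np.pi * 4 * t + g.uniform(0, 6))
                    + w * g.standard_normal(512)
                    for _ in range(8)
                ]
            )
            imfs_by_subject[f"s{s}"] = rowset
        rows = np.vstack(list(imfs_by_subject.values()))
        subject_rows = {
            s: list(range(8 * i, 8 * i + 8)) for i, s in enumerate(imfs_by_subject)
        }
        rankings = []
        for m in (2, 3):
            for r_frac in (0.1, 0.2, 0.25):
                cfg = EntropyConfig(sampen_m=m, sampen_r_frac=r_frac)
                table = entropy_feature_table(
                    {"C3": rows[None, :, :]}, 64.0, cfg, subject_rows
                )
                rankings.append(table["sampen_C3_imf0"].to_numpy())
        for i in range(len(rankings)):
            for j in range(i + 1, len(rankings)):
                rho = spearmanr(rankings[i], rankings[j]).statistic
                assert rho > 0.8

    def test_missing_mode_count_mismatch_rejected(self, rng):
        imfs = {"C3": rng.standard_normal((2, 2, 64)), "O1": rng.standard_normal((1, 2, 64))}
        with pytest.raises(ValueError, match="modes"):
            entropy_feature_table(imfs, 64.0)
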
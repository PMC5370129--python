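"""Epoching, amplitude, phase coherence, MI, negentropy, normality screen."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from assrmix.metrics import (
    assr_amplitude,
    epoch_signal,
    estimation_error,
    mutual_information,
    negentropy,
    phase_coherence,
    phase_coherence_from_phases,
    scott_bins,
    source_stats,
)
from assrmix.stimulus import SampledSignal

F_M = 39.06


def sine(freq, fs, duration, amp=1.0, phase=0.0):
    t = np.arange(int(duration * fs)) / fs
    return SampledSignal(amp * np.sin(2 * np.pi * freq * t + phase), fs)


class TestEpoching:
    def test_forty_seconds_gives_78_epochs(self):
        x = sine(F_M, 1000.0, 40.0)
        ep = epoch_signal(x, F_M, 20)
        assert ep.epochs.shape == (78, 512)
        assert ep.epoch_duration_s == pytest.approx(0.512)

    def test_single_cycle_epochs(self):
        x = sine(F_M, 1000.0, 1.0)
        ep = epoch_signal(x, F_M, 1)
        assert ep.epochs.shape[1] == round(1000.0 / F_M)

    def test_concatenation_reconstructs_signal(self):
        x = sine(F_M, 1000.0, 2.0)
        ep = epoch_signal(x, F_M, 20)
        n = ep.epochs.size
        np.testing.assert_array_equal(ep.epochs.ravel(), x.samples[:n])

    def test_too_short_signal_errors(self):
        with pytest.raises(ValueError, match="too short"):
            epoch_signal(sine(F_M, 1000.0, 0.1), F_M, 20)


class TestAmplitude:
    def test_pure_sinusoid_recovers_amplitude(self):
        # 39.0625 Hz puts exactly 20 cycles in each 5120-sample segment at
        # 10 kHz, so the amplitude at the f_m bin is leakage-free
        x = sine(39.0625, 10_000.0, 5.12, amp=2.5, phase=0.7)
        assert assr_amplitude(x, 39.0625, 20) == pytest.approx(2.5, rel=1e-6)

    def test_near_bin_frequency_recovers_amplitude_approximately(self):
        x = sine(F_M, 10_000.0, 5.0, amp=2.5, phase=0.7)
        assert assr_amplitude(x, F_M, 20) == pytest.approx(2.5, rel=1e-2)

    def test_zero_signal(self):
        x = SampledSignal(np.zeros(10_000), 1000.0)
        assert assr_amplitude(x, F_M, 20) == 0.0

    def test_linearity_in_amplitude(self):
        x1 = sine(F_M, 5000.0, 3.0, amp=1.0)
        x3 = sine(F_M, 5000.0, 3.0, amp=3.0)
        assert assr_amplitude(x3, F_M, 20) == pytest.approx(
            3 * assr_amplitude(x1, F_M, 20), rel=1e-9)

    def test_noise_error_shrinks_with_averaging(self, rng):
        # Monte-Carlo oracle: amplitude error scales ~ 1/sqrt(n_segments)
        fs, amp = 2000.0, 1.0
        errs = {n_seg: [] for n_seg in (4, 36)}
        for _ in range(40):
            t = np.arange(int(36 * 20 / F_M * fs)) / fs
            x = SampledSignal(
                amp * np.sin(2 * np.pi * F_M * t) + 2.0 * rng.standard_normal(len(t)), fs)
            for n_seg in errs:
                errs[n_seg].append(abs(assr_amplitude(x, F_M, 20, n_seg) - amp))
        ratio = np.mean(errs[4]) / np.mean(errs[36])
        assert ratio == pytest.approx(3.0, rel=0.5)  # sqrt(36/4) = 3

    def test_unresolvable_frequency_errors(self):
        x = SampledSignal(np.zeros(100), 1000.0)
        with pytest.raises(ValueError):
            assr_amplitude(x, 0.001, 1)


class TestPhaseCoherence:
    def test_identical_phase_epochs_give_one(self):
        # exact-bin modulation frequency: every 1024-sample epoch at 2 kHz
        # holds exactly 20 cycles, so all epoch phases coincide
        f = 39.0625
        x = sine(f, 2000.0, 10.24, phase=1.1)
        ep = epoch_signal(x, f, 20)
        assert phase_coherence(ep) == pytest.approx(1.0, abs=1e-9)

    def test_antiphase_pair_gives_zero(self):
        assert phase_coherence_from_phases(np.array([0.0, np.pi])) == pytest.approx(
            0.0, abs=1e-12)

    def test_uniform_phases_rarely_exceed_half(self, rng):
        # Rayleigh-statistic tail: 20 uniform phases give PC < 0.5 in >= 99%
        theta = rng.uniform(0, 2 * np.pi, size=(10_000, 20))
        pc = np.hypot(np.cos(theta).sum(1), np.sin(theta).sum(1)) / 20
        assert (pc < 0.5).mean() >= 0.99

    @given(st.lists(st.floats(0, 2 * np.pi), min_size=2, max_size=50))
    def test_bounded_in_unit_interval(self, phases):
        pc = phase_coherence_from_phases(np.array(phases))
        assert -1e-12 <= pc <= 1 + 1e-12

    def test_needs_two_epochs(self):
        x = sine(F_M, 2000.0, 0.6)
        ep = epoch_signal(x, F_M, 20)
        with pytest.raises(ValueError):
            phase_coherence(ep)

    def test_zero_amplitude_epochs_excluded_with_warning(self):
        fs = 1000.0
        n_ep = int(round(20 * fs / F_M))
        epochs = np.zeros((3, n_ep))
        t = np.arange(n_ep) / fs
        epochs[0] = np.sin(2 * np.pi * F_M * t)
        epochs[1] = np.sin(2 * np.pi * F_M * t)
        from assrmix.metrics import EpochSet

        ep = EpochSet(epochs, fs, F_M, 20)
        with pytest.warns(UserWarning, match="zero amplitude"):
            pc = phase_coherence(ep)
        assert pc == pytest.approx(1.0, abs=1e-9)


class TestEstimationError:
    def test_exact_recovery_is_zero(self):
        err, excl = estimation_error(np.ones(5), np.ones(5))
        np.testing.assert_allclose(err, 0.0)
        assert excl.size == 0

    def test_ten_percent_overshoot(self):
        err, _ = estimation_error(np.array([1.1]), np.array([1.0]))
        assert err[0] == pytest.approx(10.0)

    def test_sign_semantics(self):
        err, _ = estimation_error(np.array([0.8, 1.2]), np.array([1.0, 1.0]))
        assert err[0] < 0 < err[1]

    def test_zero_truth_excluded(self):
        err, excl = estimation_error(np.array([1.0, 2.0]), np.array([1.0, 0.0]))
        assert list(excl) == [1]
        assert np.isnan(err[1])


class TestMutualInformation:
    def test_self_information_is_entropy(self, rng):
        x = rng.standard_normal(50_000)
        mi = mutual_information(x, x, bins=40)
        counts, _ = np.histogram(x, bins=40)
        p = counts / counts.sum()
        h = -(p[p > 0] * np.log(p[p > 0])).sum()
        assert mi.raw == pytest.approx(h, rel=1e-9)

    def test_symmetry(self, rng):
        x, y = rng.standard_normal((2, 30_000))
        a = mutual_information(x, y, bins=30)
        b = mutual_information(y, x, bins=30)
        assert a.raw == pytest.approx(b.raw, rel=1e-12)

    def test_bias_formula_arithmetic(self, rng):
        x, y = rng.standard_normal((2, 100_000))
        mi = mutual_information(x, y, bins=160)
        assert mi.bias == pytest.approx(159**2 / (2 * 100_000))
        assert mi.corrected == pytest.approx(mi.raw - mi.bias)

    def test_independent_uniforms_corrected_near_zero(self, rng):
        # raw MI of independent streams sits at the bias level
        vals = []
        for _ in range(10):
            x = rng.uniform(size=200_000)
            y = rng.uniform(size=200_000)
            vals.append(mutual_information(x, y, bins=60).corrected)
        se = np.std(vals) / np.sqrt(len(vals))
        assert abs(np.mean(vals)) < 2 * max(se, 1e-5)

    def test_raw_nonnegative_and_dependence_increases_it(self, rng):
        x = rng.standard_normal(50_000)
        y = x + 0.1 * rng.standard_normal(50_000)
        z = rng.standard_normal(50_000)
        assert mutual_information(x, z, bins=30).raw >= 0
        assert (mutual_information(x, y, bins=30).raw
                > mutual_information(x, z, bins=30).raw)

    def test_scott_rule_auto_selects_smaller_count(self, rng):
        x = rng.standard_normal(100_000)
        y = rng.uniform(size=100_000)
        mi = mutual_information(x, y, bins="auto")
        assert mi.n_bins == min(scott_bins(x), scott_bins(y))

    def test_constant_signal_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            mutual_information(np.ones(2000), np.arange(2000.0), bins="auto")

    def test_unequal_lengths_rejected(self, rng):
        with pytest.raises(ValueError):
            mutual_information(rng.normal(size=10), rng.normal(size=11))


class TestNegentropy:
    def test_gaussian_near_zero(self, rng):
        assert negentropy(rng.standard_normal(1_000_000)) < 1e-4

    def test_affine_invariance(self, rng):
        y = rng.laplace(size=100_000)
        assert negentropy(7.3 * y - 11.0) == pytest.approx(negentropy(y), rel=1e-9)

    def test_laplace_positive_and_above_gaussian(self, rng):
        # the log-cosh contrast is only mildly sensitive to the Laplace
        # tails (J ~ 1.3e-3) but still far above the Gaussian null
        jl = negentropy(rng.laplace(size=200_000))
        jg = negentropy(rng.standard_normal(200_000))
        assert jl > 1e-3 and jl > 50 * jg

    def test_constant_rejected(self):
        with pytest.raises(ValueError):
            negentropy(np.ones(100))

    def test_raw_scale_variant_is_scale_dependent(self, rng):
        y = rng.laplace(size=50_000)
        assert negentropy(5 * y, standardize=False) != pytest.approx(
            negentropy(y, standardize=False), rel=0.01)


class TestSourceStats:
    def test_gaussian_not_rejected(self, rng):
        kurt, rejected = source_stats(rng.standard_normal(100_000))
        assert abs(kurt) < 0.1
        assert not rejected

    def test_uniform_rejected(self, rng):
        kurt, rejected = source_stats(rng.uniform(size=100_000))
        assert rejected
        assert kurt < 0  # platykurtic

    def test_artifact_source_rejected(self, default_sim):
        kurt, rejected = source_stats(default_sim.sources.artifact)
        assert rejected and kurt > 10

    def test_short_or_constant_input_rejected(self):
        with pytest.raises(ValueError):
            source_stats(np.arange(10.0))
        with pytest.raises(ValueError):
            source_stats(np.ones(1000))
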
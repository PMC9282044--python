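"""Spectrum computation, peak-tempo extraction, strikes, retention."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from drumpose.tempo import (
    PowerSpectrum,
    StrikeTrain,
    TempoEstimate,
    best_hand,
    detect_strikes,
    ioi_from_frequency,
    peak_tempo,
    power_spectrum,
    retention,
)

from test_kinematics import make_signal


def sine_signal(freq, n=600, fps=30.0, amp=1.0, phase=0.0):
    t = np.arange(n) / fps
    return make_signal(amp * np.sin(2 * np.pi * freq * t + phase), fps=fps)


class TestPowerSpectrum:
    def test_pure_sine_single_dominant_peak(self):
        spec = power_spectrum(sine_signal(2.0))
        k = int(np.argmax(spec.power))
        assert spec.freq[k] == pytest.approx(2.0)
        others = np.delete(spec.power, k)
        assert others.max() <= 1e-6 * spec.power[k]

    def test_zero_signal_all_zero_power(self):
        spec = power_spectrum(make_signal(np.zeros(100)))
        assert np.all(spec.power == 0.0)

    def test_amplitude_to_power_scaling(self):
        # amp 2 at 1.5 Hz vs amp 1 at 2.5 Hz: power ratio = (2/1)^2 = 4
        t = np.arange(600) / 30.0
        v = 2.0 * np.sin(2 * np.pi * 1.5 * t) + 1.0 * np.sin(2 * np.pi * 2.5 * t)
        spec = power_spectrum(make_signal(v))
        p_15 = spec.power[np.argmin(np.abs(spec.freq - 1.5))]
        p_25 = spec.power[np.argmin(np.abs(spec.freq - 2.5))]
        assert p_15 / p_25 == pytest.approx(4.0, rel=1e-9)

    def test_grid_step_is_one_over_duration(self):
        spec = power_spectrum(sine_signal(2.0, n=600, fps=30.0))
        assert spec.df == pytest.approx(1.0 / 20.0)
        assert spec.freq[0] == 0.0

    def test_non_uniform_grid_rejected(self):
        sig = make_signal(np.ones(10))
        sig.t = sig.t.copy()
        sig.t[5] += 0.001
        with pytest.raises(ValueError, match="uniform"):
            power_spectrum(sig)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.integers(0, 2**32 - 1))
    def test_parseval_with_one_sided_doubling(self, seed):
        rng = np.random.default_rng(seed)
        n = 600
        v = rng.normal(size=n)
        v -= v.mean()
        spec = power_spectrum(make_signal(v))
        # full-spectrum energy from the one-sided half (even n: Nyquist unpaired)
        total = spec.power[0] + spec.power[-1] + 2.0 * spec.power[1:-1].sum()
        assert total == pytest.approx(n * (v**2).sum(), rel=1e-6)
        assert total == pytest.approx(n * n * v.var(), rel=1e-6)


class TestPeakTempo:
    def test_sub_cutoff_peak_ignored(self):
        freq = np.arange(0, 61) * 0.05
        power = np.zeros_like(freq)
        power[np.argmin(np.abs(freq - 0.5))] = 10.0
        power[np.argmin(np.abs(freq - 2.0))] = 5.0
        est = peak_tempo(PowerSpectrum(freq=freq, power=power), min_freq=1.0)
        assert est.frequency == pytest.approx(2.0)
        assert est.ioi == pytest.approx(500.0)

    def test_sine_at_2_5_hz_gives_400_ms(self):
        est = peak_tempo(power_spectrum(sine_signal(2.5)))
        assert est.frequency == pytest.approx(2.5)
        assert est.ioi == pytest.approx(400.0)
        assert est.valid

    def test_flat_spectrum_above_cutoff_is_invalid_not_error(self):
        freq = np.arange(0, 61) * 0.05
        power = np.zeros_like(freq)
        power[5] = 3.0  # 0.25 Hz, below the cutoff
        est = peak_tempo(PowerSpectrum(freq=freq, power=power), min_freq=1.0)
        assert not est.valid
        assert np.isnan(est.frequency)

    def test_cutoff_at_or_above_nyquist_rejected(self):
        spec = power_spectrum(sine_signal(2.0))
        with pytest.raises(ValueError, match="Nyquist"):
            peak_tempo(spec, min_freq=15.0)

    def test_exact_tie_resolves_to_lowest_frequency(self):
        freq = np.arange(0, 61) * 0.05
        power = np.zeros_like(freq)
        power[30] = power[60] = 7.0  # 1.5 Hz and 3.0 Hz
        est = peak_tempo(PowerSpectrum(freq=freq, power=power))
        assert est.frequency == pytest.approx(1.5)

    @pytest.mark.parametrize("f0", [1.05, 1.5, 2.0, 2.5, 7.0])
    def test_on_grid_frequency_recovered_exactly(self, f0):
        est = peak_tempo(power_spectrum(sine_signal(f0)))
        assert est.frequency == f0

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.floats(1.06, 7.0))
    def test_off_grid_frequency_within_one_bin(self, f0):
        est = peak_tempo(power_spectrum(sine_signal(f0)))
        assert abs(est.frequency - f0) <= 1.0 / 20.0 + 1e-12

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.integers(0, 2**32 - 1))
    def test_agrees_with_dense_grid_periodogram_oracle(self, seed):
        rng = np.random.default_rng(seed)
        t = np.arange(600) / 30.0
        # one dominant rhythmic component plus weaker distractors and noise
        v = rng.uniform(2.0, 3.0) * np.sin(
            2 * np.pi * rng.uniform(1.1, 6.0) * t + rng.uniform(0, 2 * np.pi)
        )
        for _ in range(2):
            v += rng.uniform(0.2, 0.8) * np.sin(
                2 * np.pi * rng.uniform(1.1, 6.0) * t + rng.uniform(0, 2 * np.pi)
            )
        v += 0.1 * rng.normal(size=len(t))
        v -= v.mean()
        est = peak_tempo(power_spectrum(make_signal(v)))
        # independent maximiser on a 10x zero-padded grid
        dense = np.abs(np.fft.rfft(v, n=10 * len(v))) ** 2
        dense_freq = np.fft.rfftfreq(10 * len(v), d=1 / 30.0)
        keep = dense_freq >= 1.0
        f_dense = dense_freq[keep][np.argmax(dense[keep])]
        assert abs(est.frequency - f_dense) <= 1.0 / 20.0 + 1e-12


class TestIoiFromFrequency:
    @pytest.mark.parametrize("f,ioi", [(2.0, 500.0), (1.0, 1000.0)])
    def test_reciprocal_in_ms(self, f, ioi):
        assert ioi_from_frequency(f) == ioi

    def test_two_point_two_two_hz(self):
        assert ioi_from_frequency(2.22) == pytest.approx(450.45, abs=0.005)

    @pytest.mark.parametrize("f", [0.0, -1.0])
    def test_non_positive_rejected(self, f):
        with pytest.raises(ValueError):
            ioi_from_frequency(f)


class TestBestHand:
    def left(self, power=8.0, valid=True):
        return TempoEstimate(2.0, 500.0, power, "left", valid)

    def right(self, power=3.0, valid=True):
        return TempoEstimate(2.5, 400.0, power, "right", valid)

    def test_higher_peak_power_wins(self):
        assert best_hand(self.left(8), self.right(3)).hand == "left"

    def test_single_valid_estimate_wins(self):
        assert best_hand(TempoEstimate.invalid("left"), self.right()).hand == "right"

    def test_both_invalid_flagged_not_raised(self):
        est = best_hand(TempoEstimate.invalid("left"), TempoEstimate.invalid("right"))
        assert not est.valid

    def test_exact_tie_goes_right(self):
        assert best_hand(self.left(5.0), self.right(5.0)).hand == "right"

    def test_synthetic_drummer_right_hand_selected(self, clean_trial):
        from drumpose.pipeline import process_series

        res = process_series(clean_trial.to_series())
        assert res.record.tempo.hand == clean_trial.truth.drumming_hand == "right"


def brute_force_minima(v, prominence):
    """Oracle: exhaustive scan for local minima with simple prominence."""
    idx = []
    for i in range(1, len(v) - 1):
        if v[i] < v[i - 1] and v[i] <= v[i + 1]:
            left = v[: i + 1].max()
            right = v[i:].max()
            if min(left, right) - v[i] >= prominence:
                idx.append(i)
    return idx


class TestDetectStrikes:
    def test_sine_strikes_at_troughs(self):
        fps, period_s = 100.0, 0.5
        t = np.arange(int(2.0 * fps)) / fps
        v = np.sin(2 * np.pi * t / period_s)
        sig = make_signal(v, fps=fps)
        strikes = detect_strikes(sig)
        assert len(strikes) == 4
        np.testing.assert_allclose(np.diff(strikes.times), period_s, atol=2 / fps)
        oracle = brute_force_minima(v, 0.25 * np.ptp(v))
        np.testing.assert_allclose(strikes.times, np.asarray(oracle) / fps, atol=1 / fps)

    def test_flat_signal_empty_train(self):
        assert len(detect_strikes(make_signal(np.zeros(50)))) == 0

    def test_small_ripple_below_prominence_excluded(self):
        fps = 100.0
        t = np.arange(int(3.0 * fps)) / fps
        v = np.sin(2 * np.pi * t / 1.0) + 0.05 * np.sin(2 * np.pi * t / 0.07)
        strikes = detect_strikes(make_signal(v, fps=fps), min_prominence_frac=0.25)
        assert len(strikes) == 3  # only the three deep troughs survive


class TestRetention:
    @pytest.mark.parametrize(
        "times,expected",
        [
            ([0.0, 0.5, 1.0, 1.5], True),
            ([0.0, 2.5, 5.0, 7.5], False),
            ([0.0, 0.5, 1.0], False),
            ([0.0, 0.5, 3.0, 3.5, 4.0, 4.5], True),  # qualifying run after a break
            ([0.0, 1.9999, 3.9, 5.8], True),  # gaps just under 2000 ms
            ([0.0, 2.0, 4.0, 6.0], False),  # exactly 2000 ms is not < 2000
        ],
    )
    def test_rule_examples(self, times, expected):
        assert retention(StrikeTrain(times=np.asarray(times))) is expected

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(0, 2**32 - 1))
    def test_monotone_adding_strike_inside_run(self, seed):
        rng = np.random.default_rng(seed)
        times = np.cumsum(rng.uniform(0.3, 1.9, size=5))
        assert retention(StrikeTrain(times=times))
        insert = (times[1] + times[2]) / 2
        augmented = np.sort(np.append(times, insert))
        assert retention(StrikeTrain(times=augmented))
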
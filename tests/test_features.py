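"""HRV metric correctness: hand values, oracles, invariances."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hrvseizure import (
    RRGenConfig,
    band_power,
    compute_feature_vector,
    csi,
    cvi,
    gen_rr_series,
    lorenz_axes,
    rmssd,
    sampen,
    sdnn,
)
from hrvseizure.errors import InsufficientDataError, ParameterError

FIVE = np.array([800.0, 810.0, 790.0, 805.0, 795.0])

rr_lists = st.lists(
    st.floats(min_value=300.0, max_value=2000.0, allow_nan=False), min_size=4, max_size=60
)


def sampen_bruteforce(x, m=2, r=None):
    """O(n²) double-loop template-matching oracle."""
    x = np.asarray(x, dtype=float)
    if r is None:
        r = 0.2 * np.std(x, ddof=1)
    n = len(x)
    nt = n - m
    b = a = 0
    for i in range(nt):
        for j in range(i + 1, nt):
            if max(abs(x[i + k] - x[j + k]) for k in range(m)) < r:
                b += 1
            if max(abs(x[i + k] - x[j + k]) for k in range(m + 1)) < r:
                a += 1
    if a == 0 or b == 0:
        return math.inf
    return -math.log(a / b)


class TestTimeDomain:
    def test_sdnn_hand_value(self):
        # deviations 0,10,-10,5,-5 -> variance 250/4 = 62.5
        assert sdnn(FIVE) == pytest.approx(math.sqrt(62.5), abs=1e-4)

    def test_rmssd_hand_value(self):
        # successive diffs 10,-20,15,-10 -> mean square 825/4
        assert rmssd(FIVE) == pytest.approx(math.sqrt(825.0 / 4.0), abs=1e-4)

    def test_constant_series(self):
        assert sdnn(np.full(10, 800.0)) == 0.0
        assert rmssd(np.full(10, 800.0)) == 0.0

    @given(rr_lists, st.floats(min_value=-200, max_value=200))
    @settings(max_examples=50, deadline=None)
    def test_shift_invariance(self, rr, shift):
        rr = np.asarray(rr)
        if np.min(rr) + shift <= 0:
            return
        assert sdnn(rr + shift) == pytest.approx(sdnn(rr), abs=1e-9)
        assert rmssd(rr + shift) == pytest.approx(rmssd(rr), abs=1e-9)

    @given(rr_lists, st.floats(min_value=0.5, max_value=2.0))
    @settings(max_examples=50, deadline=None)
    def test_sdnn_homogeneity(self, rr, scale):
        rr = np.asarray(rr)
        assert sdnn(rr * scale) == pytest.approx(scale * sdnn(rr), rel=1e-9)

    def test_minimum_lengths(self):
        with pytest.raises(InsufficientDataError):
            sdnn([800.0])
        with pytest.raises(InsufficientDataError):
            rmssd([800.0, 810.0])


class TestBandPower:
    @staticmethod
    def _modulated(freq, amp=20.0, duration=180.0, base=800.0):
        times, rr = [], []
        t = 0.0
        while t < duration:
            val = base + amp * np.sin(2 * np.pi * freq * t)
            t += val / 1000.0
            times.append(t)
            rr.append(val)
        return np.array(times), np.array(rr)

    def test_lf_tone_concentrates_in_lf_band(self):
        times, rr = self._modulated(0.10)
        lf = band_power(times, rr, 0.04, 0.15)
        hf = band_power(times, rr, 0.15, 0.40)
        assert lf / (lf + hf) > 0.95
        assert lf == pytest.approx(20.0**2 / 2.0, rel=0.20)

    def test_hf_tone_concentrates_in_hf_band(self):
        times, rr = self._modulated(0.30)
        lf = band_power(times, rr, 0.04, 0.15)
        hf = band_power(times, rr, 0.15, 0.40)
        assert hf / (lf + hf) > 0.95

    def test_constant_tachogram_has_no_power(self):
        times = np.cumsum(np.full(240, 0.8))
        rr = np.full(240, 800.0)
        assert band_power(times, rr, 0.04, 0.15) == pytest.approx(0.0, abs=1e-9)

    def test_parseval_total_power_matches_variance(self, interictal_rr):
        times = interictal_rr.interval_times
        rr = interictal_rr.rr
        total = band_power(times, rr, 0.01, 1.99)
        assert total == pytest.approx(np.var(rr - rr.mean()), rel=0.15)

    def test_window_too_short_rejected(self):
        times, rr = self._modulated(0.10, duration=30.0)
        with pytest.raises(InsufficientDataError):
            band_power(times, rr, 0.04, 0.15)


class TestSampEn:
    def test_constant_series_is_zero(self):
        assert sampen(np.full(20, 800.0)) == 0.0

    def test_period_two_series_is_zero(self):
        x = np.array([1, 2, 1, 2, 1, 2, 1, 2, 1, 2], dtype=float)
        assert sampen(x, m=2, r=0.5) == 0.0

    @pytest.mark.parametrize("n", [30, 100, 300])
    def test_matches_bruteforce_oracle_exactly(self, n):
        rng = np.random.default_rng(n)
        x = 800.0 + 30.0 * rng.standard_normal(n)
        assert sampen(x) == sampen_bruteforce(x)

    def test_too_short_rejected(self):
        with pytest.raises(InsufficientDataError):
            sampen(np.array([1.0, 2.0, 3.0]), m=2)


class TestLorenz:
    def test_constant_series_degenerate(self):
        L, T = lorenz_axes(np.full(10, 800.0))
        assert L == 0.0 and T == 0.0
        with pytest.raises(ParameterError):
            csi(L, T)

    def test_iid_series_nearly_circular(self):
        rng = np.random.default_rng(3)
        x = 800.0 + 25.0 * rng.standard_normal(500)
        L, T = lorenz_axes(x)
        assert L / T == pytest.approx(1.0, rel=0.15)

    @given(rr_lists)
    @settings(max_examples=50, deadline=None)
    def test_rotation_identity(self, rr):
        # SD1² + SD2² = Var(first) + Var(last lagged pair sets)
        x = np.asarray(rr)
        d = (x[1:] - x[:-1]) / np.sqrt(2)
        s = (x[1:] + x[:-1]) / np.sqrt(2)
        lhs = np.var(d, ddof=1) + np.var(s, ddof=1)
        rhs = np.var(x[1:], ddof=1) + np.var(x[:-1], ddof=1)
        assert lhs == pytest.approx(rhs, rel=1e-9, abs=1e-9)

    def test_csi_cvi_closed_forms(self):
        assert csi(10.0, 10.0) == 1.0
        assert csi(40.0, 10.0) == 4.0
        assert cvi(10.0, 10.0) == pytest.approx(2.0)
        assert cvi(100.0, 1.0) == pytest.approx(2.0)
        # doubling both axes adds log10(4)
        assert cvi(20.0, 20.0) - cvi(10.0, 10.0) == pytest.approx(math.log10(4.0))

    def test_csi_scale_invariance(self):
        assert csi(30.0, 10.0) == pytest.approx(csi(90.0, 30.0))

    def test_round_trip_identities(self, interictal_rr):
        L, T = lorenz_axes(interictal_rr.rr)
        assert csi(L, T) * T == pytest.approx(L, rel=1e-12)
        assert 10 ** cvi(L, T) == pytest.approx(L * T, rel=1e-9)


class TestFeatureVector:
    def test_interictal_fixture_all_finite_positive(self, interictal_rr):
        from hrvseizure.records import RRSeries

        window = RRSeries(
            interictal_rr.beat_times[:301], interictal_rr.rr[:300]
        )
        vec = compute_feature_vector(window)
        arr = vec.as_array()
        assert np.all(np.isfinite(arr))
        assert vec.sdnn > 0 and vec.rmssd > 0 and vec.lf > 0 and vec.hf > 0
        assert vec.csi > 0

    def test_preictal_shift_raises_csi_lowers_sampen(self):
        base = RRGenConfig(duration=1020.0, seed=77)
        pre = RRGenConfig(
            duration=1020.0, preictal_onset=600.0, preictal_ramp=180.0, seed=77
        )
        rr_i, _ = gen_rr_series(base)
        rr_p, _ = gen_rr_series(pre)

        def tail_window(rr):
            from hrvseizure.records import RRSeries

            mask = rr.interval_times > 800.0
            idx = np.flatnonzero(mask)
            return RRSeries(rr.beat_times[idx[0] :], rr.rr[idx])

        vec_i = compute_feature_vector(tail_window(rr_i))
        vec_p = compute_feature_vector(tail_window(rr_p))
        assert vec_p.csi > vec_i.csi
        assert vec_p.sampen < vec_i.sampen
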
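"""Peak detection, integration, S/N and ion-ratio primitives."""

import math

import numpy as np
import pytest
from hypothesis import given, settings as hsettings, strategies as st

from thyroquant.peaks import (
    ChromatogramTrace,
    Peak,
    TraceDataError,
    detect_peak,
    integrate_area,
    points_across_peak,
    quantifier_qualifier_ratio,
    signal_to_noise,
)
from thyroquant.synthdata import NoiseModel, simulate_trace


def gaussian_trace(rt=4.12, area=1.0e5, sigma_sec=3.0, duty=0.73, span=1.0,
                   baseline=0.0):
    sigma = sigma_sec / 60.0
    dt = duty / 60.0
    n = int(round(2 * span / dt)) + 1
    t = rt - span + np.arange(n) * dt
    area_min = area / 60.0
    h = area_min / (sigma * math.sqrt(2 * math.pi))
    y = baseline + h * np.exp(-0.5 * ((t - rt) / sigma) ** 2)
    return ChromatogramTrace("T0", "quantifier", t, y, duty)


class TestIntegration:
    @pytest.mark.parametrize("area", [1.0e3, 5.0e4, 2.0e6])
    def test_gaussian_area_matches_closed_form(self, area):
        tr = gaussian_trace(area=area)
        got = integrate_area(tr, (4.12 - 4 * 3 / 60, 4.12 + 4 * 3 / 60))
        assert got == pytest.approx(area, rel=0.01)

    def test_constant_trace_integrates_to_zero(self):
        t = np.linspace(0, 1, 101)
        tr = ChromatogramTrace("x", "quantifier", t, np.full(101, 50.0), 0.6)
        assert integrate_area(tr, (0.1, 0.9)) == 0.0

    def test_zero_length_bounds(self):
        tr = gaussian_trace()
        assert integrate_area(tr, (4.12, 4.12)) == 0.0

    def test_inverted_bounds_rejected(self):
        with pytest.raises(ValueError):
            integrate_area(gaussian_trace(), (4.2, 4.0))

    def test_negative_net_area_clipped_to_zero(self):
        # a dip below the endpoint baseline must not yield negative area
        t = np.linspace(0, 1, 101)
        y = 100.0 - 80.0 * np.exp(-0.5 * ((t - 0.5) / 0.05) ** 2)
        tr = ChromatogramTrace("x", "quantifier", t, y, 0.6)
        assert integrate_area(tr, (0.2, 0.8)) == 0.0

    @given(shift=st.floats(-5.0, 5.0))
    @hsettings(max_examples=25, deadline=None)
    def test_shift_invariance(self, shift):
        base = gaussian_trace()
        a0 = integrate_area(base, (4.0, 4.24))
        shifted = ChromatogramTrace("T0", "quantifier", base.times + shift,
                                    base.intensities, base.sampling_interval_sec)
        a1 = integrate_area(shifted, (4.0 + shift, 4.24 + shift))
        assert a1 == pytest.approx(a0, rel=1e-9)

    def test_additivity_over_adjacent_intervals(self):
        # two baseline-separated peaks: splitting between them is additive
        tr = gaussian_trace(rt=4.1, span=1.2)
        y2 = tr.intensities + np.roll(tr.intensities, 40)
        tr2 = ChromatogramTrace("x", "quantifier", tr.times, y2,
                                tr.sampling_interval_sec)
        mid = 4.34  # flat region between the two apices (4.10 and 4.59)
        whole = integrate_area(tr2, (3.9, 4.9))
        parts = integrate_area(tr2, (3.9, mid)) + integrate_area(tr2, (mid, 4.9))
        assert parts == pytest.approx(whole, rel=1e-3)


class TestDetection:
    def test_apex_found_at_expected_rt(self):
        tr = gaussian_trace(rt=4.12)
        pk = detect_peak(tr, expected_rt_min=4.12, rt_window_min=0.1)
        assert pk is not None
        assert pk.apex_rt_min == pytest.approx(4.12, abs=0.73 / 60)
        assert pk.n_points >= 15

    def test_flat_zero_trace_gives_absent(self):
        t = 4.12 + np.arange(100) * 0.73 / 60 - 0.5
        tr = ChromatogramTrace("T0", "quantifier", t, np.zeros(100), 0.73)
        assert detect_peak(tr, 4.12, 0.1) is None

    def test_short_trace_is_data_error(self):
        t = np.array([0.0, 0.1, 0.2])
        tr = ChromatogramTrace("x", "quantifier", t, np.ones(3), 6.0)
        with pytest.raises(TraceDataError):
            detect_peak(tr, 0.1, 0.05)

    def test_closest_of_two_candidate_apices_wins(self):
        # brute-force oracle: enumerate local maxima, pick min |rt - expected|
        duty = 0.73
        dt = duty / 60.0
        t = 4.0 + np.arange(200) * dt
        y = (1000 * np.exp(-0.5 * ((t - 4.50) / 0.02) ** 2)
             + 2000 * np.exp(-0.5 * ((t - 4.58) / 0.02) ** 2))
        tr = ChromatogramTrace("x", "quantifier", t, y, duty)
        maxima = [i for i in range(1, len(y) - 1)
                  if y[i] >= y[i - 1] and y[i] >= y[i + 1] and y[i] > 0]
        expected = 4.52
        oracle = min((i for i in maxima if abs(t[i] - expected) <= 0.1),
                     key=lambda i: (abs(t[i] - expected), -y[i]))
        pk = detect_peak(tr, expected, 0.1)
        assert pk.apex_rt_min == pytest.approx(t[oracle], abs=1e-9)

    def test_isobaric_isomers_assigned_to_distinct_peaks(self):
        # di-iodothyronine isomers co-monitored on one transition must be
        # separated chromatographically (5.16 vs 5.35 min)
        duty = 0.73
        dt = duty / 60.0
        t = 4.8 + np.arange(100) * dt
        sigma = 3.0 / 60.0
        y = (5e4 * np.exp(-0.5 * ((t - 5.16) / sigma) ** 2)
             + 4e4 * np.exp(-0.5 * ((t - 5.35) / sigma) ** 2))
        tr = ChromatogramTrace("T2", "quantifier", t, y, duty)
        quiet = (4.8, 4.95)  # signal-free stretch ahead of both peaks
        p1 = detect_peak(tr, 5.16, 0.09, noise_region=quiet)
        p2 = detect_peak(tr, 5.35, 0.09, noise_region=quiet)
        assert p1.apex_rt_min == pytest.approx(5.16, abs=dt)
        assert p2.apex_rt_min == pytest.approx(5.35, abs=dt)
        assert abs(p1.apex_rt_min - p2.apex_rt_min) > 0.1


class TestSignalToNoise:
    def _trace_with_noise_region(self, noise_sd):
        rng = np.random.default_rng(7)
        duty = 0.73
        dt = duty / 60.0
        t = 3.0 + np.arange(300) * dt
        y = 1000 * np.exp(-0.5 * ((t - 5.0) / 0.05) ** 2)
        if noise_sd:
            y = y + rng.normal(0, noise_sd, t.size)
        y = np.clip(y, 0, None)
        y[y < 1e-12] = 0.0  # far tails are true zeros, not denormals
        return ChromatogramTrace("x", "quantifier", t, y, duty)

    def test_ratio_matches_direct_formula(self):
        tr = self._trace_with_noise_region(noise_sd=10.0)
        pk = Peak(5.0, 1.0, height=110.0, baseline_level=10.0,
                  signal_to_noise=0.0, n_points=10, width_sec_at_base=12.0)
        region = (3.0, 4.0)
        seg = tr.intensities[(tr.times >= 3.0) & (tr.times <= 4.0)]
        expect = 110.0 / np.std(seg, ddof=1)
        assert signal_to_noise(tr, pk, region) == pytest.approx(expect)

    def test_zero_noise_gives_infinity(self):
        tr = self._trace_with_noise_region(noise_sd=0.0)
        pk = Peak(5.0, 1.0, height=50.0, baseline_level=0.0,
                  signal_to_noise=0.0, n_points=10, width_sec_at_base=12.0)
        assert signal_to_noise(tr, pk, (3.0, 4.0)) == math.inf

    def test_empty_region_rejected(self):
        tr = self._trace_with_noise_region(10.0)
        pk = Peak(5.0, 1.0, 100.0, 0.0, 0.0, 10, 12.0)
        with pytest.raises(ValueError):
            signal_to_noise(tr, pk, (4.0, 4.0))


class TestIonRatio:
    @pytest.mark.parametrize("aq,ac,expect", [(200.0, 100.0, 2.0), (5.0, 5.0, 1.0)])
    def test_direct_ratio(self, aq, ac, expect):
        pq = Peak(1.0, aq, 10, 0, 0, 10, 12)
        pc = Peak(1.0, ac, 10, 0, 0, 10, 12)
        assert quantifier_qualifier_ratio(pq, pc) == expect

    def test_zero_or_absent_qualifier_is_undefined(self):
        pq = Peak(1.0, 200.0, 10, 0, 0, 10, 12)
        pc = Peak(1.0, 0.0, 10, 0, 0, 10, 12)
        assert math.isnan(quantifier_qualifier_ratio(pq, pc))
        assert math.isnan(quantifier_qualifier_ratio(pq, None))

    def test_generator_ratio_recovered_noise_free(self, registry):
        comp = registry["3-T1Ac"]
        tq, tc = simulate_trace(comp, amount=10.0, noise=NoiseModel(0, 0, 0))
        pq = detect_peak(tq, comp.expected_rt_min)
        pc = detect_peak(tc, comp.expected_rt_min)
        assert quantifier_qualifier_ratio(pq, pc) == pytest.approx(
            comp.expected_qc_ratio, rel=1e-3)


class TestGeometry:
    @pytest.mark.parametrize("width,duty,expect", [(12.0, 0.73, 16), (12.0, 12.0, 1),
                                                   (20.0, 0.73, 27)])
    def test_points_across_peak_floor(self, width, duty, expect):
        assert points_across_peak(width, duty) == expect

    def test_narrowest_peak_satisfies_minimum(self, settings):
        assert points_across_peak(12.0, settings.duty_cycle_sec) >= settings.min_points_per_peak

    def test_inconsistent_sampling_interval_rejected(self):
        t = np.linspace(0, 1, 101)
        with pytest.raises(ValueError):
            ChromatogramTrace("x", "quantifier", t, np.zeros(101), 5.0)
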
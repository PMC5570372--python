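"""Synthetic-data generator: determinism, geometry, truth exposure."""

import numpy as np
import pandas as pd
import pytest

from thyroquant import pipeline
from thyroquant.calibration import weighted_linear_fit
from thyroquant.peaks import integrate_area, points_across_peak
from thyroquant.registry import AcquisitionSettings
from thyroquant.synthdata import (
    GeometryError,
    HEPG2_LYSATE,
    KineticScenario,
    MatrixModel,
    NoiseModel,
    ScenarioError,
    IS_AMOUNT_NM,
    RESPONSE_FACTOR,
    simulate_batch,
    simulate_metabolism_timecourse,
    simulate_spiking_triplet,
    simulate_trace,
    t1am_uptake_scenario,
)


class TestTrace:
    def test_zero_amount_noise_free_is_flat_zero(self, registry):
        tq, tc = simulate_trace(registry["T0"], 0.0, noise=NoiseModel(0, 0, 0))
        assert np.all(tq.intensities == 0) and np.all(tc.intensities == 0)

    def test_noise_free_area_matches_analytic_gaussian(self, registry):
        comp = registry["T3"]
        amount = 5.0
        tq, _ = simulate_trace(comp, amount, noise=NoiseModel(0, 0, 0))
        rt = comp.expected_rt_min
        got = integrate_area(tq, (rt - 0.2, rt + 0.2))
        assert got == pytest.approx(RESPONSE_FACTOR * amount, rel=0.01)

    def test_minimum_points_across_default_peak(self, settings):
        # 12 s base width sampled at the 0.73 s duty cycle
        assert points_across_peak(12.0, settings.duty_cycle_sec) >= 15
        tq, _ = simulate_trace(
            t1am_registry_compound(), 1.0, settings, NoiseModel(0, 0, 0))
        rt = tq.times[np.argmax(tq.intensities)]
        window = (tq.times >= rt - 0.1) & (tq.times <= rt + 0.1)
        assert window.sum() >= 15

    def test_duty_cycle_slower_than_peak_is_geometry_error(self, registry):
        slow = AcquisitionSettings(duty_cycle_sec=15.0)
        with pytest.raises(GeometryError):
            simulate_trace(registry["T0"], 1.0, slow, NoiseModel(0, 0, 0))

    def test_matrix_factors_scale_area(self, registry):
        comp = registry["T4"]
        m = MatrixModel("test", 0.9, 0.8, {})
        tq, _ = simulate_trace(comp, 2.0, noise=NoiseModel(0, 0, 0), matrix=m)
        rt = comp.expected_rt_min
        got = integrate_area(tq, (rt - 0.2, rt + 0.2))
        assert got == pytest.approx(RESPONSE_FACTOR * 2.0 * 0.9 * 0.8, rel=0.01)


def t1am_registry_compound():
    from thyroquant.registry import default_registry
    return default_registry()["3-T1AM"]


class TestBatch:
    def _batch(self, seed=0, cv=0.05, n_days=1):
        design = pipeline.hepg2_design(n_days=n_days, seed=seed)
        from thyroquant.registry import default_registry
        reg = default_registry()
        return simulate_batch(design, HEPG2_LYSATE,
                              NoiseModel(proportional_cv=cv, seed=seed), reg)

    def test_deterministic_under_seed(self):
        t1, _ = self._batch(seed=42)
        t2, _ = self._batch(seed=42)
        pd.testing.assert_frame_equal(t1, t2)

    def test_different_seeds_differ(self):
        t1, _ = self._batch(seed=1)
        t2, _ = self._batch(seed=2)
        assert not t1["area"].equals(t2["area"])

    def test_calibrator_series_spans_design_levels(self):
        table, _ = self._batch()
        cal = table[(table["role"] == "calibrator")
                    & ~table["compound"].str.startswith(("13C6", "2H4"))]
        levels = sorted(cal["nominal_conc"].unique())
        assert levels == sorted(pipeline.hepg2_design().calibrator_levels)
        assert len(levels) == 11
        assert (min(levels), max(levels)) == (0.016, 50.0)

    def test_blank_contains_only_configured_background(self):
        table, _ = self._batch()
        blank = table[(table["role"] == "blank")
                      & (table["transition_role"] == "quantifier")]
        with_signal = set(blank[blank["area"] > 0]["compound"])
        # endogenous T0 plus the internal standards, nothing else
        assert "T0" in with_signal
        analyte_signal = {c for c in with_signal
                          if not c.startswith(("13C6", "2H4"))}
        assert analyte_signal == {"T0"}
        t0 = blank[blank["compound"] == "T0"]
        implied = t0["true_conc"].iloc[0]
        assert 0.06 <= implied <= 0.10

    def test_is_present_at_fixed_amount(self):
        table, truth = self._batch(cv=0.0)
        is_rows = table[table["compound"].isin(set(truth["is_map"].values()))
                        & (table["transition_role"] == "quantifier")]
        assert (is_rows["nominal_conc"] == IS_AMOUNT_NM).all()

    def test_ratio_slope_recovered_within_2pct(self):
        table, truth = self._batch(seed=3, cv=0.05, n_days=3)
        ratios = pipeline.area_ratio_table(table, truth["is_map"])
        cal = ratios[(ratios["role"] == "calibrator")
                     & (ratios["compound"] == "T3")]
        curve = weighted_linear_fit(cal, "1/x", "T3")
        assert curve.slope == pytest.approx(truth["expected_ratio_slope_per_nM"],
                                            rel=0.02)

    def test_unknown_role_rejected(self):
        design = pipeline.hepg2_design()
        from thyroquant.registry import default_registry
        table, _ = simulate_batch(design, HEPG2_LYSATE, NoiseModel(0, 0, 0),
                                  default_registry())
        assert set(table["role"]) <= {"calibrator", "qc", "blank"}
        from thyroquant.synthdata import _KNOWN_ROLES
        assert not ({"calibrator", "qc", "blank", "matrix_control", "unknown"}
                    - _KNOWN_ROLES)


class TestTriplet:
    def test_noise_free_triplet_forces_me_re(self):
        m = MatrixModel("t", 0.90, 0.85, {})
        t = simulate_spiking_triplet(1.0, m, NoiseModel(0, 0, 0))
        assert np.mean(t.post_spike_areas) / np.mean(t.solvent_areas) == pytest.approx(0.90)
        assert np.mean(t.pre_spike_areas) / np.mean(t.post_spike_areas) == pytest.approx(0.85)
        assert np.mean(t.pre_spike_areas) / np.mean(t.solvent_areas) == pytest.approx(0.765)

    def test_lossless_matrix_gives_equal_areas(self):
        m = MatrixModel("t", 1.0, 1.0, {})
        t = simulate_spiking_triplet(1.0, m, NoiseModel(0, 0, 0))
        assert np.allclose(t.pre_spike_areas, t.solvent_areas)

    def test_pccl3_like_pe_magnitude(self):
        # suppression 0.93, recovery 0.85 -> PE ~ 79%
        m = MatrixModel("t", 0.93, 0.85, {})
        t = simulate_spiking_triplet(1.0, m, NoiseModel(0, 0, 0))
        pe = 100 * np.mean(t.pre_spike_areas) / np.mean(t.solvent_areas)
        assert pe == pytest.approx(79.05, abs=0.01)

    def test_nonpositive_conc_rejected(self):
        with pytest.raises(ValueError):
            simulate_spiking_triplet(0.0, HEPG2_LYSATE, NoiseModel())


class TestTimecourse:
    def test_builtin_scenario_reproduces_cell_uptake_amounts(self):
        df = simulate_metabolism_timecourse(t1am_uptake_scenario())
        cells = df[(df["compound"] == "3-T1AM") & (df["compartment"] == "cells")]
        assert list(cells.sort_values("time_min")["amount_pmol"].round(0)) == [238, 276, 334]

    def test_zero_conversion_means_no_products(self):
        sc = KineticScenario(
            parent="3-T1", incubated_pmol=750.0, times_min=(5.0, 30.0),
            fractions={("3-T1", "cells"): (0.1, 0.2),
                       ("3-T1", "supernatant"): (0.6, 0.6),
                       ("T0", "cells"): (0.0, 0.0)},
        )
        df = simulate_metabolism_timecourse(sc)
        t0 = df[df["compound"] == "T0"]
        assert (t0["amount_pmol"] == 0).all() and (~t0["detected"]).all()

    def test_noise_free_bookkeeping_conserves_mass(self):
        sc = t1am_uptake_scenario()
        df = simulate_metabolism_timecourse(sc)
        for t, grp in df.groupby("time_min"):
            accounted = grp["amount_pmol"].sum()
            assert accounted <= sc.incubated_pmol + 1e-9
            # loss closes the balance exactly
            loss = sc.incubated_pmol - accounted
            assert loss >= 0

    def test_overcommitted_fractions_rejected(self):
        with pytest.raises(ScenarioError):
            KineticScenario(
                parent="x", incubated_pmol=100.0, times_min=(5.0,),
                fractions={("x", "cells"): (0.7,), ("x", "supernatant"): (0.5,)},
            )

    def test_deterministic_with_noise_seed(self):
        sc = t1am_uptake_scenario()
        a = simulate_metabolism_timecourse(sc, noise=NoiseModel(0.05, 0, 9))
        b = simulate_metabolism_timecourse(sc, noise=NoiseModel(0.05, 0, 9))
        pd.testing.assert_frame_equal(a, b)
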
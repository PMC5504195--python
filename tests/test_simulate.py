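import time

import numpy as np
import pandas as pd
import pytest

from siplant import (ControlConfig, Stability, build_standard_plant,
                     default_config, detect_cyclic_stability,
                     generate_standard_forcing, investment_efficiency,
                     read_field_forcing, run_simulation, run_standard)
from siplant.simulate import (LATENT_HEAT_VAPORIZATION, Forcing,
                              STANDARD_TRANSPIRATION)

from conftest import day_slice


class TestStandardForcing:
    def test_night_floor_is_ten_percent_of_standard(self):
        f = generate_standard_forcing(2, 0.05)
        night = f.transpiration[~f.day_mask]
        assert np.allclose(night, 0.1 * STANDARD_TRANSPIRATION)
        assert np.allclose(night, 0.04)

    def test_ten_hours_of_darkness_per_day(self):
        dt = 0.05
        f = generate_standard_forcing(3, dt)
        per_day = (~f.day_mask[:int(24 / dt)]).sum() * dt
        assert per_day == pytest.approx(10.0)

    def test_photosynthesis_zero_in_the_dark(self):
        f = generate_standard_forcing(1, 0.05)
        assert np.all(f.photosynthesis[~f.day_mask] == 0.0)
        assert f.photosynthesis.max() == pytest.approx(0.0015)

    def test_two_hour_peak_plateau(self):
        f = generate_standard_forcing(1, 0.05)
        at_peak = f.transpiration == f.transpiration.max()
        assert at_peak.sum() * 0.05 == pytest.approx(2.0, abs=0.1)

    def test_grid_snapping_warns(self):
        with pytest.warns(UserWarning, match="snapped"):
            generate_standard_forcing(1, 0.07)

    def test_csv_round_trip_bit_identical(self, tmp_path):
        f = generate_standard_forcing(2, 0.05)
        path = tmp_path / "forcing.csv"
        f.to_csv(path)
        g = Forcing.from_csv(path)
        for attr in ("t", "transpiration", "photosynthesis", "temperature"):
            assert np.array_equal(getattr(f, attr), getattr(g, attr))
        assert np.array_equal(f.day_mask, g.day_mask)


class TestFieldForcing:
    def _write(self, path, t, le, nee, temp=None):
        d = {"time": t, "LE": le, "NEE": nee}
        if temp is not None:
            d["temperature"] = temp
        pd.DataFrame(d).to_csv(path, index=False)

    def test_zero_le_means_zero_transpiration(self, tmp_path):
        p = tmp_path / "f.csv"
        self._write(p, [0.0, 1.0, 2.0], [0.0, 0.0, 0.0], [0.0, -1.0, 0.0])
        f = read_field_forcing(p)
        assert np.all(f.transpiration == 0.0)

    def test_latent_heat_conversion_unit(self, tmp_path):
        # LE that converts to exactly 1 ml cm^-2 day^-1
        le_unit = LATENT_HEAT_VAPORIZATION / (86400.0 * 0.1)
        p = tmp_path / "f.csv"
        self._write(p, [0.0, 1.0], [le_unit, le_unit], [0.0, 0.0])
        f = read_field_forcing(p)
        assert np.allclose(f.transpiration, 1.0)

    def test_photosynthesis_is_negated_clipped_nee(self, tmp_path):
        p = tmp_path / "f.csv"
        self._write(p, [0.0, 1.0], [0.0, 0.0], [-0.5, 0.3])
        f = read_field_forcing(p)
        assert np.allclose(f.photosynthesis, [0.5, 0.0])

    def test_missing_column_rejected(self, tmp_path):
        p = tmp_path / "f.csv"
        pd.DataFrame({"time": [0, 1], "LE": [0, 0]}).to_csv(p, index=False)
        with pytest.raises(ValueError, match="NEE"):
            read_field_forcing(p)

    def test_gap_interpolation_warns(self, tmp_path):
        p = tmp_path / "f.csv"
        self._write(p, [0.0, 1.0, 2.0], [10.0, np.nan, 30.0], [0, 0, 0])
        with pytest.warns(UserWarning, match="interpolated"):
            f = read_field_forcing(p)
        assert f.transpiration[1] == pytest.approx(
            20.0 / LATENT_HEAT_VAPORIZATION * 86400.0 * 0.1)


class TestRunSimulation:
    def test_constant_mode_alpha_is_one(self, constant_run):
        assert np.all(constant_run.alpha == 1.0)

    def test_deterministic_rerun_is_bitwise_identical(self):
        ctrl = ControlConfig.for_mode("water_stress", 0.1, 0.2,
                                      trans_signal_scale=12.0)
        a = run_standard(ctrl, days=1)
        b = run_standard(ctrl, days=1)
        assert np.array_equal(a.alpha, b.alpha)
        assert np.array_equal(a.c_m, b.c_m)
        assert np.array_equal(a.c_r, b.c_r)

    def test_accumulation_grid_monotone_ordering(self):
        """Final expression decreases with the generation rate slp at fixed
        decay, and increases with decay at fixed slp."""
        final = {}
        for slp in (0.005, 0.02):
            for dec in (0.05, 0.2):
                ctrl = ControlConfig.for_mode("accumulation", slp, dec)
                final[(slp, dec)] = run_standard(ctrl).alpha[-1]
        assert final[(0.02, 0.05)] < final[(0.005, 0.05)]
        assert final[(0.02, 0.2)] < final[(0.005, 0.2)]
        assert final[(0.005, 0.05)] < final[(0.005, 0.2)]
        assert final[(0.02, 0.05)] < final[(0.02, 0.2)]

    def test_halving_dt_changes_day4_by_under_one_percent(self):
        ctrl = ControlConfig.for_mode("constant", 0.0, 0.0)
        a = run_standard(ctrl, dt=0.05)
        b = run_standard(ctrl, dt=0.025, record_stride=2)
        d4a, d4b = day_slice(a, 4), day_slice(b, 4)
        for attr in ("c_s", "c_m"):
            xa = getattr(a, attr)[d4a].mean(axis=0)
            xb = getattr(b, attr)[d4b].mean(axis=0)
            assert np.allclose(xa, xb, rtol=0.01, atol=1e-6)

    def test_forcing_must_cover_span(self, plant, config):
        forcing = generate_standard_forcing(1, 0.05)
        with pytest.raises(ValueError, match="cover"):
            run_simulation(plant, forcing, ControlConfig(), config, days=4)

    def test_runtime_guard(self):
        start = time.perf_counter()
        run_standard(ControlConfig.for_mode("accumulation", 0.01, 0.1))
        assert time.perf_counter() - start < 60.0

    def test_field_and_artificial_forcing_same_alpha_pattern(self, tmp_path):
        """A field forcing with the same diurnal shape as the artificial one
        yields the same qualitative expression pattern under water-stress
        control: daytime maxima, nighttime minima."""
        std = generate_standard_forcing(4, 0.05)
        le = std.transpiration / (86400.0 * 0.1) * LATENT_HEAT_VAPORIZATION
        pd.DataFrame({"time": std.t, "LE": le,
                      "NEE": -std.photosynthesis}).to_csv(
            tmp_path / "field.csv", index=False)
        field = read_field_forcing(tmp_path / "field.csv")
        cfg = default_config()
        ctrl = ControlConfig.for_mode("water_stress", 0.2, 0.2,
                                      trans_signal_scale=12.0)
        traj = run_simulation(build_standard_plant(cfg), field, ctrl, cfg)
        d4 = day_slice(traj, 4)
        tod = traj.t[d4] % 24.0
        alpha = traj.alpha[d4]
        light, dark = tod < 14.0, tod >= 14.0
        assert alpha[light].max() > alpha[dark].max()
        assert alpha[dark].min() <= alpha[light].min()
        assert alpha[light].mean() > alpha[dark].mean()


class TestInvestmentEfficiency:
    def test_constant_alpha_ie_is_si_over_span(self, constant_run):
        rep = investment_efficiency(constant_run, 0.0, 24.0)
        t = constant_run.t
        m = (t >= 0.0) & (t <= 24.0)
        si = np.trapezoid(constant_run.j_unload[m, constant_run.top_leaf], t[m])
        assert rep.ie == pytest.approx(si / 24.0, rel=1e-9)
        # and the quadrature of the flux tracks the actual cell accumulation
        v_cyt = 2.0
        gained = (constant_run.c_m_cyt[m][-1, constant_run.top_leaf]
                  - constant_run.c_m_cyt[m][0, constant_run.top_leaf]) * v_cyt
        assert si == pytest.approx(gained, rel=0.01)

    def test_night_day_split_is_photoperiod_ratio(self, constant_run):
        rep = investment_efficiency(constant_run)
        assert rep.investment_night / rep.investment_day == \
            pytest.approx(10.0 / 14.0, rel=1e-3)

    def test_zero_alpha_is_undefined(self, constant_run):
        import copy
        traj = copy.copy(constant_run)
        traj.alpha = np.zeros_like(traj.alpha)
        with pytest.raises(ZeroDivisionError):
            investment_efficiency(traj)

    def test_stride_invariance(self):
        ctrl = ControlConfig.for_mode("constant", 0.0, 0.0)
        a = run_standard(ctrl, record_stride=1)
        b = run_standard(ctrl, record_stride=2)
        ra, rb = investment_efficiency(a), investment_efficiency(b)
        assert rb.ie == pytest.approx(ra.ie, rel=1e-3)

    def test_experiment_table(self, efficiency_table):
        tab = efficiency_table
        assert list(tab["label"]) == ["constant", "low", "intermediate", "high"]
        assert tab["IE_change_vs_constant_pct"][0] == 0.0
        gains = tab["IE_change_vs_constant_pct"].to_numpy()[1:]
        assert np.all(np.diff(gains) > 0)            # gains rise with sensitivity
        ratios = tab["night_day_ratio"].to_numpy()
        assert np.all(np.diff(ratios) < 0)           # night share falls


class TestCyclicStability:
    def test_pure_daily_sinusoid_is_stable(self):
        t = np.arange(0, 96, 0.05)
        s = 2.0 + np.sin(2 * np.pi * t / 24.0)
        assert detect_cyclic_stability(s, 480) == Stability.CYCLIC_STABLE

    def test_growing_mean_is_drifting(self):
        t = np.arange(0, 96, 0.05)
        s = np.exp(t / 40.0) * (2.0 + np.sin(2 * np.pi * t / 24.0))
        assert detect_cyclic_stability(s, 480) == Stability.DRIFTING

    def test_vanishing_amplitude_is_decaying(self):
        t = np.arange(0, 96, 0.05)
        s = 5.0 + np.exp(-t / 4.0) * np.sin(2 * np.pi * t / 24.0)
        assert detect_cyclic_stability(s, 480) == Stability.DECAYING

    def test_short_series_rejected(self):
        with pytest.raises(ValueError, match="3"):
            detect_cyclic_stability(np.ones(960), 480)


class TestTrajectoryIO:
    def test_tidy_long_format(self, tmp_path):
        traj = run_standard(ControlConfig.for_mode("constant", 0.0, 0.0),
                            days=1, record_stride=20)
        df = traj.to_dataframe()
        assert list(df.columns) == ["time_h", "node_id", "variable", "value"]
        assert set(df["variable"]) >= {"psi_x", "c_s", "c_m", "alpha"}
        out = tmp_path / "traj.csv"
        df.to_csv(out, index=False)
        assert pd.read_csv(out).shape == df.shape
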
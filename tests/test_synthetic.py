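"""Synthetic experiment generator: climate, flux surfaces, closures."""

import numpy as np
import pandas as pd
import pytest
from scipy.integrate import solve_ivp

from soilnflux import (ChamberGeometry, SimConfig, compute_flux,
                       daily_true_fluxes, make_study_table,
                       mole_fraction_to_mass, simulate_climate,
                       simulate_closure, simulate_flux_records,
                       true_flux_surface)


class TestConfigValidation:
    @pytest.mark.parametrize("kwargs", [
        {"n_years": 0},
        {"warming_delta_t": -1.0},
        {"moisture_curvature": 0.001},
        {"rel_moisture_change_o": -1.5},
        {"plots": (("P1", "heated"),)},
    ])
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SimConfig(**kwargs)


class TestClimate:
    def test_seed_determinism(self):
        a = simulate_climate(SimConfig(seed=7, n_years=1))
        b = simulate_climate(SimConfig(seed=7, n_years=1))
        c = simulate_climate(SimConfig(seed=8, n_years=1))
        pd.testing.assert_frame_equal(a, b)
        assert not np.allclose(a["temp_mineral"], c["temp_mineral"])

    def test_null_treatment_is_exactly_invariant(self):
        cfg = SimConfig(seed=5, n_years=1, warming_delta_t=0.0,
                        rel_moisture_change_o=0.0,
                        rel_moisture_change_mineral=0.0,
                        plots=(("P1", "control"), ("P1", "warmed")))
        clim = simulate_climate(cfg)
        a = clim[clim["treatment"] == "control"].drop(
            columns="treatment").reset_index(drop=True)
        b = clim[clim["treatment"] == "warmed"].drop(
            columns="treatment").reset_index(drop=True)
        pd.testing.assert_frame_equal(a, b)

    def test_warming_delta_t_realized(self, small_climate):
        grow = small_climate[small_climate["season"] == "growing"]
        means = grow.groupby("treatment")["temp_mineral"].mean()
        assert means["warmed"] - means["control"] == pytest.approx(2.0,
                                                                   abs=0.2)

    def test_moisture_deficits_match_config_targets(self, small_config,
                                                    small_climate):
        grow = small_climate[small_climate["season"] == "growing"]
        for col, target in (("theta_o", small_config.rel_moisture_change_o),
                            ("vwc_mineral",
                             small_config.rel_moisture_change_mineral)):
            means = grow.groupby("treatment")[col].mean()
            realized = means["warmed"] / means["control"] - 1.0
            assert realized == pytest.approx(target, rel=0.2)

    def test_temperature_continuity_and_frozen_flag(self, small_climate):
        for _, sub in small_climate.groupby("plot_id"):
            steps = np.abs(np.diff(sub["temp_mineral"].to_numpy()))
            assert steps.max() < 10.0
            frozen = sub[sub["frozen"]]
            assert (frozen["temp_mineral"] <= 0.0).all()

    def test_monsoon_precipitation_structure(self, small_config,
                                             small_climate):
        p1 = small_climate[small_climate["plot_id"] == "P1"]
        wet = p1[p1["date"].dt.month.isin([5, 6, 7, 8, 9])]
        assert wet["precip_mm"].sum() / p1["precip_mm"].sum() > 0.6
        assert (p1["precip_mm"] >= small_config.heavy_precip_threshold).any()

    def test_thaw_advanced_in_warmed_plots(self, small_climate):
        by_trt = {}
        for trt, sub in small_climate.groupby("treatment"):
            year = sub[sub["year"] == sub["year"].min()]
            thawed = year[year["days_since_thaw"] >= 0]
            by_trt[trt] = thawed["doy"].min()
        advance = by_trt["control"] - by_trt["warmed"]
        assert 8.0 <= advance <= 11.0

    def test_bucket_conserves_water(self):
        cfg = SimConfig(seed=9, n_years=1, moisture_noise_sd=0.0)
        clim = simulate_climate(cfg)
        for _, sub in clim.groupby("plot_id"):
            store = (sub["vwc_mineral"].to_numpy() * cfg.bucket_depth_mm
                     + sub["snow_mm"].to_numpy())
            gains = np.diff(store)
            assert gains[gains > 0].sum() <= sub["precip_mm"].sum() + 1e-6

    def test_wfps_within_bounds(self, small_climate):
        assert small_climate["wfps"].between(0.0, 100.0).all()


class TestFluxSurface:
    def test_q10_by_construction(self):
        cfg = SimConfig()
        lo = true_flux_surface(15.0, 35.0, "NO", cfg)
        hi = true_flux_surface(25.0, 35.0, "NO", cfg)
        assert hi / lo == pytest.approx(3.5, rel=1e-12)

    def test_moisture_parabola_symmetric_about_optimum(self):
        cfg = SimConfig()
        for d in (3.0, 7.0, 12.0):
            assert true_flux_surface(15.0, 35.0 + d, "NO", cfg) == \
                pytest.approx(true_flux_surface(15.0, 35.0 - d, "NO", cfg),
                              rel=1e-12)

    def test_dry_soil_clipped_to_zero(self):
        assert true_flux_surface(20.0, 0.0, "NO", SimConfig()) == 0.0

    def test_never_nan_and_never_negative(self):
        cfg = SimConfig()
        t = np.linspace(-10, 30, 41)
        w = np.linspace(0, 100, 41)
        for sp in ("NO", "N2O"):
            out = true_flux_surface(t, w, sp, cfg,
                                    days_since_thaw=np.linspace(-5, 20, 41))
            assert np.all(np.isfinite(out)) and np.all(out >= 0)

    def test_unknown_species_rejected(self):
        with pytest.raises(ValueError):
            true_flux_surface(10.0, 30.0, "CH4", SimConfig())

    def test_freeze_thaw_pulse_confined_to_window(self):
        cfg = SimConfig()
        base = true_flux_surface(2.0, 50.0, "N2O", cfg, days_since_thaw=100.0)
        pulsed = true_flux_surface(2.0, 50.0, "N2O", cfg,
                                   days_since_thaw=cfg.pulse_onset_days)
        assert pulsed > 10 * base


class TestClosureSimulator:
    def test_zero_flux_noiseless_is_flat_at_ambient(self):
        closure = simulate_closure(0.0, species="NO", noise_sd=0.0,
                                   ambient_conc=2.0)
        assert np.allclose(closure.conc_nmol_mol, 2.0)

    def test_positive_flux_rises_to_known_asymptote(self):
        f, temp_k = 50.0, 288.0
        closure = simulate_closure(f, species="NO", noise_sd=0.0,
                                   ambient_conc=1.0, temp_k=temp_k)
        geom = closure.geometry
        closed = closure.t_s <= geom.closure_minutes * 60.0
        post_flush = closed & (closure.t_s > geom.flush_minutes * 60.0)
        c = closure.conc_nmol_mol[post_flush]
        assert np.all(np.diff(c) > 0)
        conv = mole_fraction_to_mass("NO", temp_k, 1013.0)
        asymptote = 1.0 + f * geom.area_m2 / (geom.flow_m3_h * conv)
        assert c[-1] < asymptote
        assert c.max() == pytest.approx(
            asymptote * (1 - np.exp(-(1200 - 180) / (geom.turnover_h * 3600)))
            + 1.0 * np.exp(-(1200 - 180) / (geom.turnover_h * 3600)),
            rel=0.02)

    def test_matches_numerically_integrated_mass_balance(self):
        """Forward model vs an independent ODE integration, < 0.1 %."""
        f, temp_k, ambient = 80.0, 283.0, 330.0
        geom = ChamberGeometry()
        closure = simulate_closure(f, species="N2O", noise_sd=0.0,
                                   ambient_conc=ambient, temp_k=temp_k)
        conv = mole_fraction_to_mass("N2O", temp_k, 1013.0)
        t0 = geom.flush_minutes * 60.0

        def dcdt(t, c):  # V dC/dt = F*A/conv + Q*(C_in - C), per second
            return (f * geom.area_m2 / conv
                    + geom.flow_m3_h * (ambient - c[0])) / geom.volume_m3 \
                / 3600.0

        sel = (closure.t_s > t0) & (closure.t_s <= geom.closure_minutes * 60)
        sol = solve_ivp(dcdt, (t0, 1200.0), [ambient],
                        t_eval=closure.t_s[sel], rtol=1e-10, atol=1e-10)
        ours = closure.conc_nmol_mol[sel]
        assert np.max(np.abs(ours - sol.y[0]) / sol.y[0]) < 1e-3

    def test_flush_and_ambient_segments_present(self):
        closure = simulate_closure(30.0, species="NO", noise_sd=0.0,
                                   ambient_conc=1.0)
        geom = closure.geometry
        flush = closure.t_s < geom.flush_minutes * 60.0
        post = closure.t_s > geom.closure_minutes * 60.0
        assert np.allclose(closure.conc_nmol_mol[flush], 1.0)
        assert post.sum() == 3  # 30 s at 10 s spacing
        assert closure.true_flux == 30.0

    def test_monte_carlo_recovery_under_default_noise(self):
        cfg = SimConfig(seed=2)
        f_true = 8.0
        rng = cfg.rng(42)
        est = []
        for _ in range(1000):
            closure = simulate_closure(f_true, species="NO", config=cfg,
                                       temp_k=288.0, rng=rng)
            est.append(compute_flux(closure).flux)
        bias = np.mean(est) / f_true - 1.0
        assert abs(bias) < 0.10


class TestFluxRecords:
    def test_determinism_and_seed_sensitivity(self):
        cfg = SimConfig(seed=3, n_years=1, plots=(("P1", "control"),),
                        chambers_per_plot=2, closures_per_day=2)
        a = simulate_flux_records(cfg)
        b = simulate_flux_records(SimConfig(**{**cfg.__dict__}))
        pd.testing.assert_frame_equal(a, b)
        c = simulate_flux_records(SimConfig(**{**cfg.__dict__, "seed": 4}))
        assert not np.allclose(a["flux"], c["flux"])

    def test_adding_chambers_preserves_existing_streams(self):
        base = dict(seed=3, n_years=1, plots=(("P1", "control"),),
                    closures_per_day=2)
        two = simulate_flux_records(SimConfig(chambers_per_plot=2, **base))
        three = simulate_flux_records(SimConfig(chambers_per_plot=3, **base))
        two_ids = set(two["chamber_id"])
        sub = three[three["chamber_id"].isin(two_ids)].reset_index(drop=True)
        pd.testing.assert_frame_equal(sub, two.reset_index(drop=True))

    def test_estimates_track_true_fluxes(self, small_config):
        rec = simulate_flux_records(
            small_config, species=("NO",), treatments=("control",))
        strong = rec[rec["true_flux"] > 5.0]
        ratio = strong["flux"] / strong["true_flux"]
        assert ratio.mean() == pytest.approx(1.0, abs=0.05)


class TestStudyTable:
    def test_schema_and_construction_r2(self):
        from soilnflux import meta_regression
        df = make_study_table(seed=1234)
        assert len(df) == 10
        assert {"site_id", "delta_t", "delta_wfps_pct", "n2o_control",
                "n2o_warmed"} <= set(df.columns)
        res = meta_regression(df)
        assert res.r2 == pytest.approx(0.45, abs=1e-9)

    def test_rrn_consistent_with_flux_columns(self):
        from soilnflux import rrn
        df = make_study_table(seed=7)
        back = rrn(df["n2o_warmed"], df["n2o_control"], df["delta_t"])
        assert np.allclose(back, df["rrn"], rtol=1e-9)
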
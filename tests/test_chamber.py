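"""Chamber flux estimator and temporal aggregation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import soilnflux.chamber as chamber
from soilnflux import (ChamberGeometry, ClosureSeries, SimConfig,
                       compute_flux, compute_flux_batch, cumulative_flux,
                       daily_aggregate, mole_fraction_to_mass,
                       seasonal_partition, simulate_closure)
from tests.conftest import constant_daily

GEOM = ChamberGeometry()


def linear_closure(slope_per_h=60.0, ambient=1.0, species="NO",
                   temp_k=273.0, pressure=1013.0, center_on_ambient=True):
    """Closure whose window concentration is exactly linear in time."""
    t = np.arange(0.0, 1201.0, 10.0)
    lo, hi = chamber.REGRESSION_WINDOWS_MIN[species]
    tbar = (lo + hi) / 2.0 * 60.0
    c = ambient + slope_per_h * (t - (tbar if center_on_ambient else 0.0)) / 3600.0
    return ClosureSeries(species=species, t_s=t, conc_nmol_mol=c,
                         temp_k=temp_k, pressure_hpa=pressure,
                         ambient_c=ambient)


class TestComputeFlux:
    def test_constant_at_ambient_gives_exactly_zero(self):
        t = np.arange(0.0, 1201.0, 10.0)
        closure = ClosureSeries(species="NO", t_s=t,
                                conc_nmol_mol=np.full_like(t, 5.0),
                                temp_k=290.0, pressure_hpa=1000.0,
                                ambient_c=5.0)
        rec = compute_flux(closure)
        assert rec.flux == 0.0
        assert rec.accumulation == 0.0 and rec.dynamic == 0.0

    def test_accumulation_term_dimensional_oracle(self):
        # 60 nmol/mol/h at STP: 60 * (14/22.4) µg m⁻³ * 0.091/0.18 m
        rec = compute_flux(linear_closure(60.0))
        expected = 60.0 * (14.0 / 22.4) * (0.091 / 0.18)
        assert rec.dynamic == pytest.approx(0.0, abs=1e-9)
        assert rec.flux == pytest.approx(expected, rel=1e-9)
        assert rec.flux == pytest.approx(18.96, abs=0.01)

    def test_flux_is_sum_of_terms(self):
        rec = compute_flux(linear_closure(30.0, center_on_ambient=False))
        assert rec.flux == pytest.approx(rec.accumulation + rec.dynamic,
                                         rel=1e-12)

    @pytest.mark.parametrize("species", ["NO", "N2O"])
    @pytest.mark.parametrize("true_flux", [1.0, 10.0, 100.0])
    def test_recovers_true_flux_from_noiseless_closures(self, species,
                                                        true_flux):
        closure = simulate_closure(true_flux, species=species, noise_sd=0.0,
                                   temp_k=288.0)
        rec = compute_flux(closure)
        assert rec.flux == pytest.approx(true_flux, rel=0.10)

    def test_estimator_matches_discrete_closed_form_expectation(self):
        """The noiseless estimate equals the analytic OLS expectation.

        With C(t) = C_in + S(1-e^(-(t-t0)/tau)), the estimator's expected
        value has a closed form in the sample times; the simulated path
        must reproduce it to high precision for both windows.
        """
        for species in ("NO", "N2O"):
            f_true, temp_k = 25.0, 285.0
            closure = simulate_closure(f_true, species=species, noise_sd=0.0,
                                       temp_k=temp_k)
            rec = compute_flux(closure)
            lo, hi = chamber.REGRESSION_WINDOWS_MIN[species]
            t = np.arange(lo * 60.0, hi * 60.0 + 5.0, 10.0)
            tau = GEOM.turnover_h * 3600.0
            t0 = GEOM.flush_minutes * 60.0
            conv = mole_fraction_to_mass(species, temp_k, 1013.0)
            s_amp = f_true * GEOM.area_m2 / (GEOM.flow_m3_h * conv)
            f = 1.0 - np.exp(-(t - t0) / tau)
            th = t / 3600.0
            slope = np.polyfit(th, s_amp * f, 1)[0]
            expected = (slope * GEOM.volume_m3 / GEOM.area_m2
                        + s_amp * f.mean() * GEOM.flow_m3_h / GEOM.area_m2) \
                * conv
            assert rec.flux == pytest.approx(expected, rel=1e-9)
            # the two terms compensate: slope decays as the dilution grows
            assert rec.flux == pytest.approx(f_true, rel=0.01)

    @given(alpha=st.floats(0.1, 10.0))
    def test_linearity_about_ambient(self, alpha):
        base = linear_closure(40.0, ambient=5.0, center_on_ambient=False)
        scaled = ClosureSeries(
            species="NO", t_s=base.t_s,
            conc_nmol_mol=5.0 + alpha * (base.conc_nmol_mol - 5.0),
            temp_k=base.temp_k, pressure_hpa=base.pressure_hpa, ambient_c=5.0)
        assert compute_flux(scaled).flux == pytest.approx(
            alpha * compute_flux(base).flux, rel=1e-9)

    def test_gas_symmetry_under_forced_equal_windows(self, monkeypatch):
        monkeypatch.setitem(chamber.REGRESSION_WINDOWS_MIN, "NO", (6.0, 20.0))
        t = np.arange(0.0, 1201.0, 10.0)
        c = 10.0 + 0.02 * t
        kw = dict(t_s=t, conc_nmol_mol=c, temp_k=280.0, pressure_hpa=1000.0,
                  ambient_c=10.0)
        f_no = compute_flux(ClosureSeries(species="NO", **kw)).flux
        f_n2o = compute_flux(ClosureSeries(species="N2O", **kw)).flux
        assert f_n2o == pytest.approx(2.0 * f_no, rel=1e-12)  # M ratio 28/14

    def test_too_few_samples_flagged_not_raised(self):
        t = np.array([0.0, 370.0, 380.0, 1210.0])
        closure = ClosureSeries(species="NO", t_s=t,
                                conc_nmol_mol=np.ones(4), temp_k=280.0,
                                pressure_hpa=1000.0, ambient_c=1.0)
        rec = compute_flux(closure)
        assert np.isnan(rec.flux)
        assert "too_few_samples" in rec.qc_flags

    def test_nonfinite_concentration_raises(self):
        t = np.arange(0.0, 1201.0, 10.0)
        c = np.ones_like(t)
        c[50] = np.nan
        closure = ClosureSeries(species="NO", t_s=t, conc_nmol_mol=c,
                                temp_k=280.0, pressure_hpa=1000.0,
                                ambient_c=1.0)
        with pytest.raises(ValueError, match="non-finite"):
            compute_flux(closure)

    def test_spike_removed_and_flagged(self):
        closure = linear_closure(60.0)
        clean = compute_flux(closure).flux
        idx = np.searchsorted(closure.t_s, 480.0)
        closure.conc_nmol_mol[idx] += 500.0
        rec = compute_flux(closure)
        assert "spikes_removed" in rec.qc_flags
        assert rec.flux == pytest.approx(clean, rel=0.05)

    def test_batch_agrees_with_scalar_path(self):
        cfg = SimConfig(seed=0)
        fluxes = np.array([2.0, 20.0, 80.0])
        t = np.arange(360.0, 1201.0, 10.0)
        from soilnflux.synthetic import closure_concentration
        conc = closure_concentration(t, fluxes, "N2O", GEOM, 330.0, 288.0,
                                     1013.0, 180.0)
        batch = compute_flux_batch(t, conc, "N2O", 288.0, 1013.0, 330.0, GEOM)
        for i, f in enumerate(fluxes):
            rec = compute_flux(simulate_closure(
                f, species="N2O", noise_sd=0.0, temp_k=288.0, config=cfg))
            assert batch["flux"][i] == pytest.approx(rec.flux, rel=1e-9)


class TestDailyAggregate:
    @staticmethod
    def _rec(date, plot, chamberid, trt, sp, flux, qc=""):
        return {"date": pd.Timestamp(date), "plot_id": plot,
                "chamber_id": chamberid, "treatment": trt, "species": sp,
                "flux": flux, "qc_flags": qc}

    def test_single_flux_day(self):
        daily = daily_aggregate(pd.DataFrame(
            [self._rec("2019-06-01", "P1", "C1", "control", "NO", 5.0)]))
        row = daily.iloc[0]
        assert row["mean_flux"] == 5.0
        assert np.isnan(row["se"])
        assert row[["n_fluxes", "n_chambers"]].tolist() == [1, 1]

    def test_partitions_by_treatment(self):
        daily = daily_aggregate(pd.DataFrame([
            self._rec("2019-06-01", "P1", "C1", "control", "NO", 5.0),
            self._rec("2019-06-01", "P4", "C1", "warmed", "NO", 7.0),
        ]))
        assert len(daily) == 2
        assert set(daily["treatment"]) == {"control", "warmed"}

    def test_chamber_mean_weighting_and_exclusions(self):
        rows = [self._rec("2019-06-01", "P1", "C1", "control", "NO", 4.0),
                self._rec("2019-06-01", "P1", "C1", "control", "NO", 6.0),
                self._rec("2019-06-01", "P1", "C2", "control", "NO", 10.0),
                self._rec("2019-06-01", "P1", "C3", "control", "NO", 99.0,
                          qc="spikes_removed;low_r2")]
        daily = daily_aggregate(pd.DataFrame(rows))
        row = daily.iloc[0]
        # chamber means are (5, 10); pooled mean would be 20/3
        assert row["mean_flux"] == pytest.approx(7.5)
        assert row["n_excluded"] == 1

    def test_simulated_constant_day_recovers_flux(self):
        cfg = SimConfig(seed=4)
        rows = []
        for plot in ("P1", "P2", "P3"):
            for ch in range(5):
                for k in range(4):
                    closure = simulate_closure(
                        12.0, species="NO", config=cfg, temp_k=288.0,
                        rng=cfg.rng(99, hash(plot) % 1000, ch, k),
                        plot_id=plot, chamber_id=f"{plot}-C{ch}")
                    rec = compute_flux(closure)
                    rows.append(self._rec("2019-06-01", plot,
                                          f"{plot}-C{ch}", "control", "NO",
                                          rec.flux))
        daily = daily_aggregate(pd.DataFrame(rows))
        row = daily.iloc[0]
        assert row["n_fluxes"] == 60
        assert row["mean_flux"] == pytest.approx(12.0, rel=0.05)


class TestCumulativeFlux:
    def test_constant_year_arithmetic(self):
        cum = cumulative_flux(constant_daily(10.0, 365), snow_zero=False)
        assert cum.kg_n_ha == pytest.approx(0.876, rel=1e-9)
        assert cum.coverage == 1.0 and not cum.flagged

    def test_snow_policy_scales_by_day_count(self):
        full = cumulative_flux(constant_daily(10.0, 365), snow_zero=False)
        snow = cumulative_flux(constant_daily(10.0, 365), snow_zero=True)
        assert snow.kg_n_ha == pytest.approx(
            full.kg_n_ha * (365 - 121) / 365, rel=1e-9)

    def test_no_defaults_to_snow_masked(self):
        assert cumulative_flux(constant_daily(10.0, 365)).kg_n_ha == \
            pytest.approx(0.876 * 244 / 365, rel=1e-9)

    def test_single_interior_gap_interpolates_exactly(self):
        daily = constant_daily(10.0, 60, start="2019-06-01")
        gapped = daily[daily["date"] != "2019-06-15"]
        full = cumulative_flux(daily, snow_zero=False)
        filled = cumulative_flux(gapped, snow_zero=False)
        assert filled.kg_n_ha == pytest.approx(full.kg_n_ha, rel=1e-12)
        assert filled.coverage == 1.0

    def test_long_gap_flagged_with_partial_coverage(self):
        daily = constant_daily(10.0, 60, start="2019-06-01")
        gapped = daily[(daily["date"] < "2019-06-10")
                       | (daily["date"] > "2019-06-25")]
        cum = cumulative_flux(gapped, snow_zero=False, max_gap_days=7)
        assert cum.flagged and cum.coverage < 1.0

    def test_interval_additivity(self):
        rng = np.random.default_rng(0)
        daily = constant_daily(0.0, 90, start="2019-04-01")
        daily["mean_flux"] = rng.uniform(0.0, 30.0, len(daily))
        kw = dict(snow_zero=False)
        left = cumulative_flux(daily, end="2019-05-15", **kw).kg_n_ha
        right = cumulative_flux(daily, start="2019-05-16", **kw).kg_n_ha
        total = cumulative_flux(daily, **kw).kg_n_ha
        assert left + right == pytest.approx(total, rel=1e-12)

    def test_empty_period_rejected(self):
        with pytest.raises(ValueError):
            cumulative_flux(constant_daily(1.0, 10), start="2020-01-01",
                            end="2019-01-01")


class TestSeasonalPartition:
    def test_uniform_flux_shares_follow_day_counts(self):
        seasons = seasonal_partition(constant_daily(10.0, 365),
                                     snow_zero=False)
        by = {s.label: s.kg_n_ha for s in seasons}
        n_growing = 184  # May-Oct
        assert by["growing"] / sum(by.values()) == pytest.approx(
            n_growing / 365, rel=1e-9)

    def test_shares_sum_to_cumulative(self, small_daily):
        sub = small_daily[(small_daily["species"] == "N2O")
                          & (small_daily["treatment"] == "control")]
        seasons = seasonal_partition(sub, snow_zero=False)
        total = cumulative_flux(sub, snow_zero=False).kg_n_ha
        assert sum(s.kg_n_ha for s in seasons) == pytest.approx(total,
                                                               rel=1e-6)

    def test_one_season_calendar_equals_cumulative(self):
        daily = constant_daily(7.0, 100, start="2019-03-01")
        one = seasonal_partition(daily, {"all": set(range(1, 13))},
                                 snow_zero=False)
        assert one[0].kg_n_ha == pytest.approx(
            cumulative_flux(daily, snow_zero=False).kg_n_ha, rel=1e-12)

    def test_overlapping_or_partial_calendars_rejected(self):
        daily = constant_daily(1.0, 30)
        with pytest.raises(ValueError, match="overlap"):
            seasonal_partition(daily, {"a": {1, 2}, "b": {2, 3},
                                       "c": set(range(4, 13))})
        with pytest.raises(ValueError, match="cover"):
            seasonal_partition(daily, {"a": {1, 2, 3}})

    def test_growing_season_share_of_synthetic_no(self, small_daily):
        sub = small_daily[(small_daily["species"] == "NO")
                          & (small_daily["treatment"] == "control")]
        seasons = {s.label: s.kg_n_ha for s in seasonal_partition(sub)}
        share = seasons["growing"] / sum(seasons.values())
        assert 0.70 <= share <= 0.95
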
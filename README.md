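# soilnflux

Chamber-based estimation of soil NO and N₂O fluxes and analysis of their
response to experimental warming, built for multi-year forest
soil-warming experiments with automated closed chambers. The package
covers the full computational chain of such a study — flux estimation
from closure time series, soil-moisture physics, temperature/moisture
response fitting with Q10 counterfactuals, moisture-based N₂ upscaling,
net N-transformation kinetics, and warming effect sizes with a
cross-study synthesis — and ships a seeded synthetic soil-climate and
chamber generator so every stage is testable without field data.

It is written for biogeochemists and flux-tower/chamber groups who work
in Python and want the estimator and the downstream statistics as
importable, tested functions rather than site-specific scripts.

## The science in brief

**Flux estimation.** The chambers are vented: during a 20-min closure
the analyzer withdraws air that is replaced by ambient makeup air at
flow Q, so the soil flux appears partly as a concentration rise and
partly as a chamber−ambient offset. The hybrid estimator sums both:

    F = [ dC/dt · V/A + (C_out − C_in) · Q/A ] · M/V₀ · (P/P₀) · (T₀/T)

with dC/dt from OLS over minutes 6–10 (NO) or 6–20 (N₂O) of the
closure, C_in the post-opening ambient reading, and the trailing factor
the ideal-gas conversion from mole fraction (nmol mol⁻¹) to µg N m⁻³.

**Soil moisture.** WFPS (%) = VWC / (1 − BD/2.65) · 100; the
warming-induced change is ΔWFPS (%) = (WFPS_W − WFPS_C)/WFPS_C · 100.

**Temperature sensitivity.** Fluxes binned at 0.5 °C are fitted with
F = A·e^(kT); the apparent sensitivity is Q10 = e^(10k). The
Q10-expected counterfactual F·Q10^(ΔT/10) is the flux warming should
produce if temperature were the only control — the yardstick against
which observed warming responses (and their shortfalls) are measured.

**N₂ upscaling.** F_N2 = max(0, 0.13·WFPS − 1.10) · F_N2O, a
moisture-driven denitrification-completeness ratio with no temperature
term.

**Rates and effect sizes.** Net N mineralization/nitrification from
one-week incubations, R_M = Δ(NH₄⁺+NO₃⁻)/T and R_N = ΔNO₃⁻/T,
extrapolated with R = a·e^(bT); warming responses as lnRR = ln(X_W/X_C)
and RRn = ((X_W−X_C)/X_C)/ΔT, with an OLS cross-study regression of RRn
on ΔWFPS.

## Worked example

Estimate the apparent Q10 of ambient NO emissions from a fully synthetic
two-year experiment (`examples/03_temperature_response.py`):

```python
import pandas as pd
from soilnflux import (SimConfig, bin_fluxes, daily_aggregate,
                       fit_temperature_response, simulate_climate,
                       simulate_flux_records)

config = SimConfig(seed=1)
climate = simulate_climate(config)
records = simulate_flux_records(config, climate, species=("NO",),
                                treatments=("control",))
daily = daily_aggregate(records)
state = (climate[climate.treatment == "control"]
         .groupby("date")[["temp_mineral", "wfps"]].mean().reset_index())
grow = daily.merge(state, on="date")
grow = grow[pd.DatetimeIndex(grow.date).month.isin(range(5, 11))]
fit = fit_temperature_response(bin_fluxes(grow, "temp_mineral", 0.5))
print(fit.q10)
```

prints

```
bins fitted:   43 (0.5 degC each, 4.8..25.8 degC)
A = 1.29 ug N m-2 h-1,  k = 0.1152 per degC
apparent Q10 = 3.16   (R^2 = 0.97)
```

The generator builds its NO surface with Q10 = 3.5; the value recovered
through the whole measurement chain (chamber forward model, analyzer
noise, hybrid estimator, daily aggregation, binning, nonlinear fit) sits
close to that, and its median over ten seeds is ≈3.5. The warming
contrast (`examples/06_warming_summary.py`) prints, for the same seed:

```
NO: control 0.65 kg N/ha, observed -23 %, Q10-expected +28 %, shortfall -40 %
N2O: control 1.23 kg N/ha, observed -22 %, Q10-expected +16 %, shortfall -33 %
```

i.e. warming *lowers* both gases although its temperature effect alone
predicts increases — the moisture channel overrides the thermal one.

The other `examples/` scripts cover climate simulation, single-closure
estimation, the moisture optimum, N₂ upscaling with rate extrapolation,
and the cross-study regression. A thin CLI runs the pipeline end to end:

```bash
soilnflux --seed 1 --out-dir run all    # simulate → … → meta, with manifest
```

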
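"""Fit the quadratic moisture response of growing-season NO emissions and
locate the WFPS optimum."""

import pandas as pd

from soilnflux import (SimConfig, bin_fluxes, daily_aggregate,
                       fit_moisture_response, simulate_climate,
                       simulate_flux_records)

config = SimConfig(seed=1)
climate = simulate_climate(config)
records = simulate_flux_records(config, climate, species=("NO",),
                                treatments=("control",))
daily = daily_aggregate(records)

state = (climate[climate["treatment"] == "control"]
         .groupby("date")[["temp_mineral", "wfps"]].mean().reset_index())
joined = daily.merge(state, on="date")
grow = joined[pd.DatetimeIndex(joined["date"]).month.isin(range(5, 11))]

bins = bin_fluxes(grow, "wfps", 1.0)
fit = fit_moisture_response(bins)

print(f"bins fitted:     {len(bins)} (1 % WFPS each)")
print(f"quadratic coefficients: c2={fit.c2:.3f}, c1={fit.c1:.3f}, "
      f"c0={fit.c0:.3f}")
if fit.optimum_wfps is not None:
    print(f"optimum WFPS:    {fit.optimum_wfps:.1f} %  (R^2 = {fit.r2:.2f})")
# NO production peaks at intermediate moisture: dry soils are substrate-
# diffusion limited, wet soils oxygen limited. The generator places the
# optimum at 35 % WFPS; the binned quadratic should recover a nearby vertex.
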
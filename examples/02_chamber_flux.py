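"""Forward-model one automated chamber closure and estimate its flux with
the hybrid accumulation + dynamic (dilution) estimator."""

from soilnflux import SimConfig, compute_flux, simulate_closure

config = SimConfig(seed=3)
true_flux = 25.0  # µg N m⁻² h⁻¹

closure = simulate_closure(true_flux, species="NO", config=config,
                           temp_k=288.0, rng=config.rng(0))
record = compute_flux(closure)

print(f"true flux:          {true_flux:.2f} ug N m-2 h-1")
print(f"estimated flux:     {record.flux:.2f} ug N m-2 h-1")
print(f"  accumulation term: {record.accumulation:.2f}")
print(f"  dynamic term:      {record.dynamic:.2f}")
print(f"  slope R^2:         {record.slope_r2:.3f}")
# The chamber is vented: the analyzer withdraws air replaced by ambient
# makeup air, so part of the soil flux shows up as a chamber-ambient
# concentration offset (dynamic term) rather than as slope. Summing both
# terms recovers the true flux to within a fraction of a percent.
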
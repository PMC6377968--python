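"""Open-loop controller behavior on a hand-made SpO2 recording.

Feeds a fixed saturation series (no patient model) to the device algorithm
and prints the commanded flow after each 3-s sample.
"""

import oxyloop as ox

cfg = ox.default_config(ox.Phenotype.HYPERCAPNIC)  # band 88-92%
print(f"band [{cfg.target_low:g}, {cfg.target_high:g}]%, "
      f"steps +{cfg.increase_step:g} L/min per >= {cfg.increase_interval:g} s / "
      f"-{cfg.decrease_step:g} L/min per >= {cfg.decrease_interval:g} s")

# low start -> in band -> above band -> back in band
series = [85, 85, 85, 85, 90, 90, 93, 93, 93, 93, 90, 90]
flows = ox.run_controller_trace(cfg, series)

print(f"{'t (s)':>6} {'SpO2 (%)':>9} {'flow (L/min)':>13}")
for i, (s, f) in enumerate(zip(series, flows)):
    print(f"{i * cfg.sample_period:6.0f} {s:9.0f} {f:13.1f}")

# Below the band the valve opens +2 L/min but no more often than every 5 s
# (so every other 3-s sample); inside the band flow holds; above the band it
# closes -0.5 L/min at up to every sample (the 2-s gate is shorter than the
# 3-s cadence).
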
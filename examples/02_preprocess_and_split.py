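"""SNV preprocessing and the SPXY calibration/validation split.

SNV removes per-spectrum scatter (centre and scale each spectrum); SPXY
picks a calibration set that spans both the spectral and the concentration
space, so the validation range nests inside the calibration range.
"""

from nirselect import benchmark_config, simulate, snv, spxy_split

ds = simulate(benchmark_config(seed=0))
Xs = snv(ds.X)
print(f"after SNV each spectrum has mean 0, sd 1: "
      f"row-0 mean {Xs[0].mean():.1e}, sd {Xs[0].std(ddof=1):.3f}")

sp = spxy_split(Xs, ds.y, ratio=2.0)
y_cal = ds.y[sp.calibration_indices]
y_val = ds.y[sp.validation_indices]
print(f"SPXY 2:1 split: {y_cal.size} calibration / {y_val.size} validation")
print(f"calibration range {y_cal.min():.3f}..{y_cal.max():.3f} contains "
      f"validation range {y_val.min():.3f}..{y_val.max():.3f}")
# The nesting matters: a calibration model should interpolate, never
# extrapolate, over the validation concentrations.
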
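"""The five comparison selectors on one small calibration set.

All share the same PLS/CV machinery, so differences reflect selection logic
only: interval methods (FiPLS/BiPLS) keep contiguous blocks, the UVE family
thresholds coefficient stability, CARS culls by an exponential schedule.
"""

from nirselect import simulate, snv, spxy_split
from nirselect.baselines import bipls, cars, fipls, mc_uve, uve
from nirselect.synthetic import SimulationConfig, BandSpec

cfg = SimulationConfig(
    wn_start=5600, wn_end=4600, wn_step=10,
    conc_start=0.05, conc_end=0.85, conc_step=0.01,
    bands=(BandSpec(5162, 60, 1.0, "analyte"), BandSpec(5200, 45, 0.5, "matrix")),
    seed=0,
)
ds = simulate(cfg)
Xs = snv(ds.X)
sp = spxy_split(Xs, ds.y, 2.0)
Xc, yc = Xs[sp.calibration_indices], ds.y[sp.calibration_indices]
m = Xc.shape[1]

for name, selected in [
    ("FiPLS ", fipls(Xc, yc, k=10, folds=5)),
    ("BiPLS ", bipls(Xc, yc, k=10, folds=5)),
    ("UVE   ", uve(Xc, yc, threshold=0.9, folds=5, seed=0)),
    ("MC-UVE", mc_uve(Xc, yc, runs=10, eval_step=10, folds=5, seed=0)),
    ("CARS  ", cars(Xc, yc, runs=50, folds=5, seed=0)),
]:
    print(f"{name}: kept {selected.size:4d} of {m} channels")
# Interval methods keep whole blocks around the bands; UVE-family counts
# depend on how sharply stability separates signal from the noise block;
# CARS is typically the most aggressive.
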
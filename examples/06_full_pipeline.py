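"""End-to-end run: preprocess -> SPXY -> select -> fit -> evaluate.

A RunConfig is the single source of truth; the same config + seed always
reproduces the identical report.
"""

from nirselect import RunConfig, run_pipeline, simulate
from nirselect.synthetic import benchmark_config

ds = simulate(benchmark_config(seed=0))

config = RunConfig(
    preprocess_method="snv",
    selector="ebspa",
    model="pls",
    H=10,
    T=5,
    cv_folds=5,
    seed=0,
    k0_subsample=100,  # scan 100 evenly spaced start channels for speed
)
report = run_pipeline(config, ds)

print(f"selector={report.selector}, model={report.model}, "
      f"preprocess={report.preprocess_method}")
print(f"kept {report.n_selected} of {ds.n_channels} channels")
print(f"R(calibration) = {report.R_calibration:.4f},  RMSEC  = {report.RMSEC:.4f}")
print(f"RMSECV         = {report.RMSECV:.4f}")
print(f"R(validation)  = {report.R_validation:.4f},  RMSEP  = {report.RMSEP:.4f}")
# RMSEC < RMSECV <= RMSEP is the usual ordering; a large gap between RMSEC
# and RMSEP signals overfitting of the selection or the model.
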
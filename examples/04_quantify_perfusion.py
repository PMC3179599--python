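"""Full pipeline on an infarct phantom: simulate, undersample, reconstruct,
extract curves and quantify perfusion.

The metrics table holds, per ROI: baseline and peak signal, enhancement
ratio (SI max - SI baseline)/SI baseline, five-point maximal upslope,
upslope normalized by the LV, and absolute myocardial blood flow from
Fermi-constrained deconvolution (mL/g/min).  The anterolateral sector is
the simulated infarct (true MBF 1.2 vs 7.3 remote).
"""

import ktperf as kp
from ktperf.io import metrics_to_frame

cfg = kp.RunConfig(
    phantom=kp.PhantomConfig.infarct(),
    seed=1,
    output_dir="scratch_run",
    log_level="WARNING",
)
result = kp.run_pipeline(cfg)

df = metrics_to_frame(result.metrics)
cols = ["roi", "baseline_si", "peak_si", "enhancement_ratio", "normalized_upslope", "mbf_ml_g_min"]
print(df[cols].round(3).to_string(index=False))
print(f"\nreconstruction NRMSE vs fully sampled reference: {result.nrmse_vs_reference:.4f}")
print(f"run directory with NIfTI/HDF5/CSV/JSON artifacts: {result.output_dir}")
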
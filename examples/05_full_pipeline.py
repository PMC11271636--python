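"""Run the complete pipeline on a synthetic world from a single configuration.

Stages: inputs -> network -> metrics -> screen -> featurize -> train -> risk.
Every artifact lands in the output directory with a content hash recorded in
manifest.json; the run is bit-reproducible under its seed.
"""

from shipflow import PipelineConfig, run_pipeline

cfg = PipelineConfig(
    out_dir="scratch/example_pipeline",
    seed=5,
    synthetic={"n_ports": 50, "n_countries": 16, "n_regions": 8},
    train={"max_epochs": 15},
    model="transformer",
    layers=1,
)
manifest = run_pipeline(cfg)

print("completed stages:", ", ".join(manifest["stages"]))
t = manifest["stages"]["train"]
r = manifest["stages"]["risk"]
print(f"cross-validated CPC mean/max/min: {t['cpc_mean']:.3f} / {t['cpc_max']:.3f} / "
      f"{t['cpc_min']:.3f}")
print(f"NRMSE {t['nrmse']:.3f}, correlation {t['corr']:.3f}, "
      f"{t['parameters']:,} parameters")
print(f"risk-distribution correlation (predicted vs observed flows): "
      f"{r['pearson']:.3f}")
print("\nRe-running with the same config reproduces identical artifact hashes;"
      "\nsee manifest.json in the output directory for the full record.")
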
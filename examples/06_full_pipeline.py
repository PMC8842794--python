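"""Run the whole pipeline from files, exactly as the CLI does.

Simulated inputs are written as plain-text files (TSV matrices, GMT gene
sets, an edge list, a clinical table, a TF-target table) plus a ready
config.yaml; the pipeline then reads everything back, runs all eight
stages, and writes per-stage TSVs, a manifest and a plain-text report.
Equivalent shell session:

    pertnet simulate --seed 11 --out-dir study/
    pertnet run --config study/config.yaml
"""

from pathlib import Path

from pertnet import run_pipeline, simulate_study, write_study_inputs

out = Path("scratch/example_study")
study = simulate_study(11, n_genes=800, n_tumor=80, n_normal=40, de_fraction=0.08)
cfg = write_study_inputs(study, out)
cfg.seed = 11
cfg.n_random = 200   # keep the demo quick; the CLI default is 1000

manifest = run_pipeline(cfg)
print((out / "results" / "report.txt").read_text())
print("planted regulator:", study.true_regulator)
print("stage outputs:", ", ".join(manifest["outputs"]))
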
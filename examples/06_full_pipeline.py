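"""Run the whole workflow from files on disk, the way the CLI does.

Writes a synthetic cohort as TSV inputs, builds a YAML config, and runs
drugs → preprocess → cluster → signature → LOO → projection → circos,
leaving JSON/TSV outputs plus a manifest under the output directory.
Equivalent shell usage:

    pharmsig simulate --seed 7 --out cohort/
    pharmsig run --config pipeline.yaml
"""

from pathlib import Path

import yaml

from pharmsig.pipeline import load_config, run_pipeline
from pharmsig.simulate import CohortConfig, generate_cohort, write_cohort

base = Path("scratch") / "pipeline_demo"
cohort_dir = base / "cohort"
write_cohort(generate_cohort(CohortConfig(seed=7)), cohort_dir)

config = {
    "schema_version": 1,
    "seed": 7,
    "out_dir": str(base / "out"),
    "inputs": {
        "ic50": str(cohort_dir / "ic50.tsv"),
        "probes": str(cohort_dir / "probes.tsv"),
        "probe_map": str(cohort_dir / "probe_map.tsv"),
        "cnv": str(cohort_dir / "cnv.tsv"),
        "mutations": str(cohort_dir / "mutations.tsv"),
        "genes": str(cohort_dir / "genes.bed.tsv"),
        "tumor_counts": str(cohort_dir / "tumor_counts.tsv"),
    },
    "params": {"resamples": 250, "drug": "PLKi-A"},
}
config_path = base / "pipeline.yaml"
config_path.write_text(yaml.safe_dump(config))

manifest = run_pipeline(load_config(config_path))
for stage, info in manifest["stages"].items():
    print(f"{stage:<12} {info['status']}")
print(f"outputs in {base / 'out'} (seed {manifest['seed']}, "
      f"parameter hash {manifest['parameter_hash']})")
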
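"""End-to-end synthetic cohort analysis with per-stage artifacts on disk.

Runs simulate → preprocess → power/SSD → coupling → time delay →
statistics → connectomics for a small cohort (3 subjects, OFF vs ON
levodopa) and prints where each stage left its outputs.  The manifest
records a SHA-256 hash of every file, so a rerun with the same seed is
verifiably identical.
"""

import json
from pathlib import Path

from ctxstn.pipeline import PipelineConfig, run_pipeline

config = PipelineConfig(
    seed=13,
    sim={"n_subjects": 3, "duration": 40.0, "sampling_rate": 1000.0},
    coupling={"n_segments": 20},
    tde={"n_segments": 40},
    stats={"n_perm": 2000},
)
out = run_pipeline(config, Path("scratch") / "pipeline_demo")

manifest = json.loads((out / "manifest.json").read_text())
print(f"pipeline wrote {len(manifest['files'])} files under {out}")
for stage in config.stages:
    n = sum(1 for f in manifest["files"] if f.startswith(stage + "/"))
    print(f"  {stage:12s} {n:3d} files")

delays = (out / "tde" / "delays.tsv").read_text().splitlines()
print("\nper-recording delay estimates (tau_ms column; true delay 25 ms):")
for line in delays[:4]:
    print("  " + "\t".join(line.split("\t")[:5]))
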
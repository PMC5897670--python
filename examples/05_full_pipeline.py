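"""Run the whole workflow from files, exactly as the `depna run` CLI does.

Writes a synthetic cohort to disk in the package's input layout (manifest,
per-subject CSVs, ratings, behavior, ROI roster), then runs: epoch
selection -> per-subject dependency analysis -> group contrasts with FDR
-> edge-graph exports -> behavior correlations, and prints where every
result file landed.
"""

import tempfile
from pathlib import Path

import depna
from depna import io as dio
from depna.pipeline import PipelineConfig, run_pipeline

workdir = Path(tempfile.mkdtemp(prefix="depna_example_"))
cohort = depna.simulate_cohort(depna.CohortSpec(n_subjects=30, seed=5))
paths = dio.write_cohort(cohort, workdir / "inputs")

cfg = PipelineConfig(
    manifest=str(paths["manifest"]),
    roiset=str(paths["roiset"]),
    ratings=str(paths["ratings"]),
    behavior=str(paths["behavior"]),
    out_dir=str(workdir / "results"),
    seed=5,
)
results = run_pipeline(cfg)

pair = results["epochs"]
print(f"epochs: low {pair.low_window} s, high {pair.high_window} s "
      f"({pair.tr_windows['n_volumes']} volumes each)")

deg = results["contrasts"]["global_degree"]
top = deg["t"].abs().idxmax()
print(f"strongest influencing-degree contrast: {top} "
      f"(t = {deg.loc[top, 't']:.2f}, q = {deg.loc[top, 'q']:.4f})")
print(f"significant edges (p < 0.05): {results['graph'].number_of_edges()}")
print(f"\nresult bundle in {workdir / 'results'}:")
for f in sorted((workdir / "results").iterdir()):
    print(f"  {f.name}")
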
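"""Full quantification run: control vs DRB, normalized means, SEM and stars.

Runs the end-to-end pipeline on a small synthetic experiment (2 conditions ×
3 replicates), writing per-nucleolus measurements and the per-channel
comparison table, then prints the comparison.
"""

import tempfile
from pathlib import Path

import pandas as pd

from nucleoseg import PipelineConfig, SceneSpec, run_pipeline

config = PipelineConfig(
    scene=SceneSpec(noise_sigma=100.0),
    conditions=("control", "DRB"),
    n_replicates=3,
    fields_per_replicate=2,
    base_seed=11,
    demarcation_mode="dark",
    demarcation_markers=("cas",),
    measure_channels=("nucleolin", "eu"),
)

out = Path(tempfile.mkdtemp(prefix="nucleoseg_"))
paths = run_pipeline(config, out)
res = pd.read_csv(paths["comparison"])
res["annotation"] = res["annotation"].fillna("")
cols = ["condition", "channel", "normalized_mean", "sem", "n_nucleoli",
        "p_value", "annotation"]
print(res[cols].to_string(index=False))
print(f"\nartifacts in {out}")

# Control rows are 1 by construction.  Under the DRB phenotype the
# nucleolin channel loses its nucleolar enrichment and the EU (nascent RNA)
# channel drops to about half of control; stars follow * p<0.05, ** p<0.01
# from a replicate-level t-test.
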
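"""Ask whether the memory code keeps one format across the delay:
leave-one-run-out cross-temporal generalization on distractor-present
trials.

Encoding models trained at each epoch (and each TR) of the remaining
runs reconstruct the held-out run at every other epoch/TR. A stable
code generalizes (all delay cells positive); a morphing code would
empty the PRE->POST and POST->PRE cells. Writes the epoch matrix and
the TR x TR matrix under results/generalization/.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from wmdecode.analyses import loro_generalization
from wmdecode.io import save_table
from wmdecode.pipeline import RunConfig, simulate_participant

OUT = Path("results/generalization")
OUT.mkdir(parents=True, exist_ok=True)

config = RunConfig(seed=1, n_participants=7, n_runs=12, n_voxels=120)
epoch_mats, tp_mats = [], []
for p in range(config.n_participants):
    part = simulate_participant(config, p)
    mat, labels = loro_generalization(part["ts"], part["design"],
                                      part["basis"], mode="epoch")
    epoch_mats.append(mat)
    tp, tp_labels = loro_generalization(part["ts"], part["design"],
                                        part["basis"], mode="timepoint")
    tp_mats.append(tp)

epoch_mean = np.mean(epoch_mats, axis=0)
df = pd.DataFrame(epoch_mean, index=labels,
                  columns=[f"test_{l}" for l in labels])
df.insert(0, "train", labels)
save_table(df, OUT / "epoch_generalization.tsv")

tp_mean = np.mean(tp_mats, axis=0)
save_table(pd.DataFrame(tp_mean, columns=tp_labels),
           OUT / "timepoint_generalization.tsv")

print("epoch-level generalization (train x test, group mean fidelity):")
print(df.round(3).to_string(index=False))
off = min(epoch_mean[0, 2], epoch_mean[2, 0])
diag = min(epoch_mean[0, 0], epoch_mean[2, 2])
print(f"\nPRE<->POST transfer {off:.3f} vs diagonal {diag:.3f} -> "
      f"{'stable' if off > 0.5 * diag else 'morphing'} code")
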
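"""Generate a synthetic granulation campaign and look at its structure.

Builds a 6-batch campaign (two corrupted into outliers), writes it to CSV
and prints per-batch endpoint granule sizes and moisture spans.
"""

import numpy as np

from granupls.data import write_campaign
from granupls.simulate import SimConfig, simulate_campaign

cfg = SimConfig(n_batches=6, rows_per_batch=(240, 360), seed=42,
                outlier_ids=("1003", "1005"))
campaign, truths = simulate_campaign(cfg)

write_campaign(campaign, "scratch/example_campaign")

print(f"{'batch':>6} {'rows':>5} {'endpoint Dv50 (um)':>19} {'moisture max (%)':>17} outlier")
for b, t in zip(campaign.batches, truths):
    print(f"{b.batch_id:>6} {b.n_rows:>5} {b.sizes[-1, 2]:>19.1f} "
          f"{t.moisture.max():>17.2f} {'yes' if t.is_outlier else 'no'}")

# Endpoint Dv50 varies with each batch's airflow/atomization/spray settings;
# corrupted batches have shifted process parameters and distorted spectra but
# untouched size trajectories, so they are outliers in X, not in y.
total = campaign.n_rows
print(f"\ntotal rows: {total}; LOD points: "
      f"{sum(len(b.lod) for b in campaign.batches)} "
      f"(sparse moisture references)")
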
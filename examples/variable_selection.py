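"""Uninformative variable elimination on the merged predictor block.

Fits UVE-PLS for Dv50 on a pooled 6-batch campaign and reports how many
spectral channels versus process parameters survive the stability cutoff.
"""

import numpy as np

from granupls.evaluate import predictor_matrix
from granupls.pls import sequential_plan
from granupls.simulate import SimConfig, simulate_campaign
from granupls.uve import uve_pls_fit

campaign, _ = simulate_campaign(
    SimConfig(n_batches=6, rows_per_batch=(120, 160), seed=23))

X = np.vstack([predictor_matrix(b, "merged") for b in campaign.batches])
y = np.concatenate([b.sizes[:, 2] for b in campaign.batches])  # Dv50

model, result = uve_pls_fit(X, y, sequential_plan(len(y), 10), seed=0)

spec = result.retained[:256]
pars = result.retained[256:]
print(f"latent variables: {result.n_lv}; chosen cutoff: {result.chosen_cutoff:.3g}")
print(f"spectral channels retained: {spec.sum()}/256 ({100 * spec.mean():.0f}%)")
print(f"process parameters retained: {pars.sum()}/17 ({100 * pars.mean():.0f}%)")
print(f"final model predictors: {model.n_predictors}")

# A larger fraction of process parameters than spectral channels survives:
# neighbouring NIR channels are nearly collinear so most are redundant,
# while the parameter block is low-dimensional and informative.
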
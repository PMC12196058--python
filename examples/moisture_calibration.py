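"""NIR moisture (LOD) calibration with the sequential one-fifth hold-out.

Pools the sparse loss-on-drying reference rows of a clean campaign,
holds out every 5th row, and reports calibration/CV/test errors in %LOD.
"""

from granupls.evaluate import lod_holdout
from granupls.simulate import SimConfig, simulate_campaign

campaign, _ = simulate_campaign(
    SimConfig(n_batches=10, rows_per_batch=(200, 280), seed=31,
              lod_points_per_batch=15))

rep = lod_holdout(campaign)
print(f"LOD rows: {rep['n_train']} calibration / {rep['n_test']} test")
print(f"latent variables: {rep['n_lv']}")
print(f"RMSEC  = {rep['rmsec']:.3f} %   (calibration error)")
print(f"RMSECV = {rep['rmsecv']:.3f} %   (cross-validation error)")
print(f"RMSEP  = {rep['rmsep']:.3f} %   (hold-out prediction error)")
print(f"R2(cal) = {rep['r2_cal']:.3f}, R2(test) = {rep['r2_test']:.3f}")

# The water bands at 1450/1934 nm carry the moisture signal, so a few
# latent variables suffice; RMSEP close to RMSECV indicates the
# calibration transfers to unseen sampling instants.
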
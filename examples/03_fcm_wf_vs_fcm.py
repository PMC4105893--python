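"""Position-only FCM vs feature-space FCM-WF on an interleaved scene.

The scene holds one bright, homogeneous cluster of micros whose region
also contains dimmer, more variable noise objects.  Position alone
cannot keep the noise out of the reconstructed cluster; the intensity
features can.  The merit figure F_M = (N_ini - N_miss)/(N_ini + N_noise)
scores each reconstruction.
"""

import numpy as np

from microcalc import FcmConfig, paired_merit
from microcalc.scenes import overlap_scene

ms, mw = [], []
for seed in range(10):
    scene = overlap_scene(seed=seed, n_true=8, n_overlap=5, n_far=12)
    r = paired_merit(scene.X_norm, scene.positions_px, scene.truth_clusters[0],
                     k=3, fcm_cfg=FcmConfig(K=3, seed=seed))
    ms.append(r["merit_spatial_only"])
    mw.append(r["merit_with_features"])
    print(f"scene {seed}: F_M spatial-only={r['merit_spatial_only']:.3f}  "
          f"with-features={r['merit_with_features']:.3f}")

print(f"\nmean F_M: spatial-only {np.mean(ms):.3f}, "
      f"with-features {np.mean(mw):.3f}")
print("Values near 1 mean the reconstructed cluster contains every true "
      "micro and\nnothing else; the gap is the benefit of clustering in the "
      "9-D feature space.")
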
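"""Multimodal framework-extension units (not part of the benchmark model).

Demonstrates adaptive modality weighting, the cross-modal fusion stage,
the alignment regularizer, and the focal-style risk loss.  These
formalize how temporal/biomechanical and auxiliary streams would enter
the model once such data exists; the benchmarked visual-only
configuration activates none of them.
"""

import numpy as np

from kneemil.extensions import (CrossModalParams, ModalityFeatures,
                                adaptive_weighted_fusion, alignment_loss,
                                benchmark_extension_flags, cross_modal_fuse,
                                focal_risk_loss)

rng = np.random.default_rng(0)
features = ModalityFeatures(visual=rng.normal(size=4),
                            temporal=rng.normal(size=4),
                            auxiliary=rng.normal(size=4))

fused, weights = adaptive_weighted_fusion(features, np.array([1.0, 0.0, -1.0]))
print("adaptive modality weights (sum to 1):",
      {k: round(v, 3) for k, v in weights.items()})

joint = cross_modal_fuse(features.visual, features.temporal,
                         features.auxiliary,
                         CrossModalParams.random(4, rng))
print("cross-modal joint embedding (tanh-bounded):", joint.round(3))

print(f"alignment loss across the three modalities: "
      f"{alignment_loss(features):.3f}  (0 would mean identical directions)")

for gamma in (0.0, 2.0):
    print(f"focal risk loss at P=0.9, y=1, gamma={gamma}: "
          f"{focal_risk_loss(0.9, 1, gamma):.6f}")
print("gamma=0 recovers plain cross-entropy; larger gamma down-weights "
      "easy examples.")

print("\nbenchmark configuration extension audit:",
      benchmark_extension_flags())
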
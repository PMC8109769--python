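"""Generate a synthetic crop/weed field dataset and probe its separability.

Builds 200 single-class field patches (broad-leaf crop rosettes vs
thin-blade grass-weed tufts on brown soil), prints channel statistics, and
scores the 2-feature linear separability probe.  The probe accuracy bounds
how much signal the designed morphology carries: well above 90% means any
classifier failing here is limited by learning, not by the data.
"""

import numpy as np

import sganfield as sf
from sganfield.synthetic_fields import shape_features, vegetation_mask

params = sf.FieldParams(seed=42)
samples = sf.generate_dataset(100, params)

soil = sf.make_soil_background(params, np.random.default_rng(0))
r, g, b = soil.reshape(-1, 3).astype(float).mean(axis=0)
print(f"soil background channel means: R={r:.1f} G={g:.1f} B={b:.1f} (brown: R > G > B)")

for label, name in ((0, "crop"), (1, "weed")):
    feats = np.stack([shape_features(s.image) for s in samples if s.label == label])
    cover = np.mean([vegetation_mask(s.image).mean() for s in samples if s.label == label])
    print(f"{name}: vegetation cover {cover*100:5.1f}%  "
          f"green fraction {feats[:,0].mean():.3f}  compactness {feats[:,1].mean():.4f}")

acc = sf.separability_oracle(samples, seed=0)
print(f"2-feature separability probe: {acc:.1f}% accuracy (80/20 split)")
print("=> the two classes differ by morphology (compact rosettes vs sprawling blades),")
print("   not by color, mirroring early-growth crops vs grass weeds in field imagery.")
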
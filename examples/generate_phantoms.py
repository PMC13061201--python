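"""Generate a small set of synthetic B-mode phantoms and summarize them.

Each phantom is a speckled tissue field inside a sector/convex/rect
viewport (zero-valued outside, as on a scanner display) containing one
hypoechoic target organ plus distractor structures.  The size mixture
concentrates 70% of targets below the 3% small-structure threshold.
"""

import numpy as np

from sasus import generate_dataset

rng = np.random.default_rng(0)
samples = generate_dataset(10, rng=rng, canvas=256)

print(f"{'sample':<14} {'area_ratio':>10} {'class':>6}  viewport")
for s in samples:
    viewport = s.history[0][1]["viewport"]
    print(f"{s.sample_id:<14} {s.original_area_ratio:>10.4f} "
          f"{s.size_class:>6}  {viewport}")

n_small = sum(s.size_class == "small" for s in samples)
print(f"\n{n_small}/10 phantoms are small structures (<= 3% of image area);"
      "\nthe mixture draws ~70% small, mirroring how clinical targets"
      "\nconcentrate below the 3% threshold.")
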
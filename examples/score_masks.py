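"""Score predicted masks with DSC and NSD and bootstrap a confidence interval.

DSC measures area overlap; NSD measures what fraction of the two boundaries
lie within a clinical tolerance tau (here 2 px) of each other, so it is the
more sensitive metric for small structures whose area forgives little.
"""

import numpy as np

from sasus import bootstrap_ci, dsc, nsd

rng = np.random.default_rng(0)


def disk(n, cy, cx, r):
    rows, cols = np.mgrid[0:n, 0:n]
    return ((rows - cy) ** 2 + (cols - cx) ** 2 <= r * r).astype(np.uint8)


reference = disk(64, 32, 32, 10)
cases = {
    "perfect": reference,
    "shifted 1px": disk(64, 33, 32, 10),
    "shifted 5px": disk(64, 37, 32, 10),
    "too large": disk(64, 32, 32, 14),
}
print(f"{'prediction':<12} {'DSC':>6} {'NSD(tau=2)':>11}")
for name, pred in cases.items():
    print(f"{name:<12} {dsc(pred, reference):>6.3f} "
          f"{nsd(pred, reference, tau=2.0):>11.3f}")

scores = [dsc(disk(64, 32 + rng.integers(-3, 4), 32, 10), reference)
          for _ in range(30)]
lo, hi = bootstrap_ci(scores, n_boot=10_000, rng=rng)
print(f"\nmean DSC over 30 jittered predictions: {np.mean(scores):.3f} "
      f"[95% CI {lo:.3f}, {hi:.3f}] (10,000 bootstrap resamples)")
print("note how a 5px shift keeps a DSC near 0.7 but is heavily "
      "penalized by NSD: boundary metrics expose localization errors.")
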
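"""Quadrant folding: double the SNR and fill detector gaps.

Builds a noisy fiber pattern with a vertical detector-gap stripe, folds the
four Friedel-equivalent quadrants, and reports the noise reduction and how
many quadrant copies contributed at the gap.
"""

import dataclasses

import numpy as np

from fiberfold import PatternFrame, fold_quadrants
from fiberfold.synthgen import SyntheticSpec, generate_pattern

spec = SyntheticSpec(
    shape=(256, 256),
    background=(("exp", 500.0, 200.0),),
    noise="poisson",
    seed=1,
    gaps=(("v", 150, 6),),  # a Pilatus-style module gap, painted to -1
)
img, truth = generate_pattern(spec)
clean = generate_pattern(dataclasses.replace(spec, noise="none", gaps=()))[0]

frame = PatternFrame(truth["center"], 0.0)
res = fold_quadrants(img, frame, mask_threshold=0.0)

hi = clean >= 100.0
s_raw = np.std(np.where(img > 0, img, clean)[hi] - clean[hi])
s_fold = np.std(res.full_image[hi] - clean[hi])
print(f"residual noise, raw pattern:    {s_raw:8.3f} counts")
print(f"residual noise, folded pattern: {s_fold:8.3f} counts")
print(f"noise ratio folded/raw:         {s_fold / s_raw:8.3f}  (~0.5: SNR doubled)")
n_at_gap = sorted(int(v) for v in set(res.counts[:, 22:28].ravel()))
print(f"contributions at the gap:       {n_at_gap}"
      "  (the two left-side quadrants replace the gapped right-side ones)")
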
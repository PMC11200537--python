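"""Evaluate segmentations with Dice/HD95 and compare two methods.

Treats two corruption levels of the phantom labels as if they were the
outputs of two competing segmentation methods, scores both against the
exact ground truth per phantom, and runs a Bonferroni-corrected paired
t-test on the per-case macro Dice — the same comparison machinery used for
model benchmarking.
"""

import numpy as np

from mscaseg import (
    CorruptionSpec,
    PhantomConfig,
    corrupt_labels,
    evaluate_segmentation,
    generate_phantom,
    paired_test_bonferroni,
)

scores_mild, scores_severe = [], []
for seed in range(8):
    _, labels = generate_phantom(PhantomConfig(shape=(48, 48, 48)), seed=seed)
    mild = corrupt_labels(labels, CorruptionSpec("boundary_jitter", 1), seed=seed)
    severe = corrupt_labels(labels, CorruptionSpec("boundary_jitter", 3), seed=seed)
    rep_m = evaluate_segmentation(mild, labels)
    rep_s = evaluate_segmentation(severe, labels)
    scores_mild.append(rep_m.macro_dice_pct)
    scores_severe.append(rep_s.macro_dice_pct)

print(f"method A (mild corruption):   macro Dice {np.mean(scores_mild):.2f}%")
print(f"method B (severe corruption): macro Dice {np.mean(scores_severe):.2f}%")
res = paired_test_bonferroni(scores_mild, scores_severe, n_comparisons=2)
print(f"paired t-test: t = {res.t:.2f}, raw p = {res.p:.2e}, "
      f"Bonferroni-adjusted p = {res.p_adjusted:.2e}")
# The adjusted p value stays well below 0.05: the per-case Dice gap between
# the two "methods" is systematic, not sampling noise.
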
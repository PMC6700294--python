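"""Generate a phantom cohort and inspect its geometry and contrast.

Each case mimics a skull-stripped multi-modal brain MRI: four co-registered
channels on a zero background, nested ellipsoidal tumor subregions
(enhancing ⊆ core ⊆ whole, codes 4/1/2), FLAIR/T2 bright over the whole
tumor and T1ce bright over the enhancing core, plus Gaussian noise.  A
minority of cases is LGG-like (no enhancing core).
"""

import numpy as np

from tumorcascade import generate_cohort
from tumorcascade.volume_io import labels_to_task_mask

cohort = generate_cohort(6, seed=42, lgg_fraction=0.3)

print("case  whole  core  enh   FLAIR tumor/brain contrast")
for i, (volume, labels, spec) in enumerate(cohort):
    whole = labels_to_task_mask(labels, "whole").mask.astype(bool)
    flair = volume.channels["FLAIR"]
    brain = (flair != 0) & ~whole
    counts = [int((labels.labels != 0).sum()),
              int(np.isin(labels.labels, (1, 4)).sum()),
              int((labels.labels == 4).sum())]
    ratio = flair[whole].mean() / flair[brain].mean()
    tag = "LGG-like" if spec.is_lgg_like else ""
    print(f"{i:>4}  {counts[0]:>5}  {counts[1]:>4}  {counts[2]:>4}   "
          f"{ratio:.2f}x  {tag}")

# Volumes are voxel counts (1 mm isotropic); the contrast column is the mean
# FLAIR intensity inside the whole tumor over the mean in normal brain —
# the elevated signal the first cascade stage learns to detect.
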
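"""Extract the 13-entry hybrid feature vector from benign vs malignant ROIs.

Five GLCM texture statistics, six redundant-wavelet LL-band statistics and
two color moments; malignant interiors carry injected texture, which shows
up as higher LL-band entropy and lower GLCM homogeneity.
"""

import numpy as np

from btfsc.features import FEATURE_NAMES, hybrid_vector, roi_from_mask
from btfsc.phantom import PhantomSpec, generate_phantom_pair

kw = dict(noise_sigma=0.0, seed=7)
benign = generate_phantom_pair(PhantomSpec(**kw))
malignant = generate_phantom_pair(
    PhantomSpec(tumor_class="malignant", boundary_irregularity=0.3, **kw)
)

vb = hybrid_vector(roi_from_mask(benign.mr, benign.truth_mask)).as_array()
vm = hybrid_vector(roi_from_mask(malignant.mr, malignant.truth_mask)).as_array()

print(f"{'feature':<18s}{'benign':>10s}{'malignant':>12s}")
for name, b, m in zip(FEATURE_NAMES, vb, vm):
    print(f"{name:<18s}{b:>10.4f}{m:>12.4f}")
print("\nNote the malignant ROI's much higher LL-band entropy and its lower")
print("homogeneity/ASM — the discriminative signal the classifier trains on.")
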
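"""Generate a domain-randomized pseudo-photograph volume and cut training
triplets out of it.

The generator starts from a label phantom, deforms it, renders it with a
random per-label Gaussian intensity model, gamma-skews and shades it,
then "digitally slabs" it into (x1, x2, y, d1, d2) training samples.
"""

import numpy as np

import slabimpute as si

phantom = si.generate_phantom(si.PhantomSpec(seed=0))
print(f"phantom: shape {phantom.labels.shape}, "
      f"labels {np.unique(phantom.labels).tolist()}")

rng = np.random.default_rng(7)
image, deformed = si.generate_synthetic_volume(phantom, rng)
print(f"synthetic volume: intensity range [{image.min():.3f}, {image.max():.3f}]")

batch = si.make_minibatch(image, rng)
t = batch[0]
print(f"minibatch of {len(batch)} triplets; first: slab {t.thickness:.2f} mm, "
      f"target {t.d1:.2f} mm from the anterior face")
# Each triplet is one supervised example: predict y from (x1, x2, d1, d2).
# Thickness is uniform in [2, 12] mm, matching real slabbing protocols.
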
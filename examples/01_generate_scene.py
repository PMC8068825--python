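"""Generate one synthetic sticky-trap scene and inspect its annotations.

The generator renders dark, randomly rotated elliptical insects on a
noisy yellow background, plus pale wing-like distractors that are never
annotated.  The ground-truth box of each insect is the bounding
rectangle of its actually rendered pixels, so the scene is its own
census.
"""

import numpy as np

from trapcount import SceneConfig, generate_scene

# quarter-scale trap: 1500 x 1000 px with ~15 px insects (full scale is
# 6000 x 4000 with ~60 px insects; the geometry is proportional)
config = SceneConfig(n_insects=250, cluster_fraction=0.05, n_distractors=20, seed=7).scaled(0.25)
image, truth = generate_scene(config)

sides = [(b.width + b.height) / 2 for b in truth]
print(f"image: {image.shape[1]} x {image.shape[0]} px, dtype {image.dtype}")
print(f"insects annotated: {len(truth)} (configured {config.n_insects})")
print(f"mean box side: {np.mean(sides):.1f} px (configured {config.insect_size_mean:.0f} px)")
print(f"density band: {config.density_band}")

# the count of annotations always equals the configured density exactly;
# distractors are visible in the image but absent from `truth`.
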
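"""Extract the five heterogeneous texture descriptor sets from one image.

Each set summarizes the protein channel (plus, for SLFs, its spatial
relation to the DNA channel) as a fixed-length vector: SLFs (840),
LBP (256), CLBP (906), RICLBP (408), LET (413).
"""

import numpy as np

from subloc2l.features import extract_all
from subloc2l.fixtures import SyntheticSpec, generate_dataset
from subloc2l.imaging import separate_stains

spec = SyntheticSpec(images_per_class=1, image_size=(128, 128), seed=0)
images, _, manifest = generate_dataset(spec)
cp = separate_stains(images[0].astype(float), spec.stain_basis)

vectors = extract_all(cp)
for name, vec in vectors.items():
    v = vec.values
    print(f"{name:<7} dim={v.size:<4} min={v.min():8.3f} max={v.max():8.3f}")
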
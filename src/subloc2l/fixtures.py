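"""Synthetic two-stain IHC-like image generation.

Desk-scale stand-in for an IHC image corpus: each image mixes a "DNA"
stain concentration map (random nuclei discs) with a class-specific
"protein" concentration map, rendered to RGB through the inverse
Beer-Lambert stain model with additive Gaussian concentration noise.
The seven default classes are texture archetypes (nuclear, diffuse
cytoplasmic, small and large vesicles, perinuclear rings, fine and
coarse reticular stripes) chosen for controllable spatial-scale
contrast; they make no biological claim beyond matching the class count
of a typical subcellular-location label set.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from subloc2l.imaging import StainBasis, rgb_from_density

#: name, parameters of the seven texture archetypes.
DEFAULT_CLASSES = (
    {"name": "nuclear"},
    {"name": "cytoplasmic", "smooth": 8.0},
    {"name": "vesicles_small", "n_spots": 220, "radius": (1, 2)},
    {"name": "vesicles_large", "n_spots": 25, "radius": (5, 7)},
    {"name": "perinuclear", "ring_width": (2.0, 7.0)},
    {"name": "reticular_fine", "freq": 0.35},
    {"name": "reticular_coarse", "freq": 0.07},
)


@dataclass(frozen=True)
class SyntheticSpec:
    """Study conditions of the synthetic corpus."""

    n_classes: int = 7
    images_per_class: int = 15
    image_size: tuple = (128, 128)
    noise_sd: float = 0.05  # additive Gaussian, concentration units
    n_nuclei: tuple = (3, 6)
    nucleus_radius: tuple = (10, 16)
    stain_basis: StainBasis = field(default_factory=StainBasis)
    seed: int = 0

    def __post_init__(self):
        if not (1 <= self.n_classes <= len(DEFAULT_CLASSES)):
            raise ValueError(f"n_classes must be in 1..{len(DEFAULT_CLASSES)}")
        if self.images_per_class < 1 or min(self.image_size) < 32:
            raise ValueError("need >= 1 image per class and images >= 32 px")


def _disc_mask(shape, cy, cx, r):
    yy, xx = np.ogrid[0 : shape[0], 0 : shape[1]]
    return (yy - cy) ** 2 + (xx - cx) ** 2 <= r**2


def _dna_map(shape, rng: np.random.Generator, spec: SyntheticSpec):
    dna = np.zeros(shape)
    n = rng.integers(spec.n_nuclei[0], spec.n_nuclei[1] + 1)
    centers = []
    for _ in range(n):
        r = rng.uniform(*spec.nucleus_radius)
        cy = rng.uniform(r, shape[0] - r)
        cx = rng.uniform(r, shape[1] - r)
        dna[_disc_mask(shape, cy, cx, r)] = 1.0
        centers.append((cy, cx, r))
    return ndimage.gaussian_filter(dna, 1.0), centers


def _protein_map(shape, cls_params, dna, centers, rng: np.random.Generator):
    name = cls_params["name"]
    if name == "nuclear":
        prot = dna.copy()
    elif name == "cytoplasmic":
        prot = ndimage.gaussian_filter(rng.random(shape), cls_params["smooth"])
        lo, hi = prot.min(), prot.max()
        prot = (prot - lo) / (hi - lo + 1e-12)
    elif name.startswith("vesicles"):
        prot = np.zeros(shape)
        for _ in range(cls_params["n_spots"]):
            r = rng.uniform(*cls_params["radius"])
            cy = rng.uniform(r, shape[0] - r)
            cx = rng.uniform(r, shape[1] - r)
            prot[_disc_mask(shape, cy, cx, r)] = 1.0
        prot = ndimage.gaussian_filter(prot, 0.6)
    elif name == "perinuclear":
        prot = np.zeros(shape)
        w0, w1 = cls_params["ring_width"]
        yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
        for cy, cx, r in centers:
            d = np.hypot(yy - cy, xx - cx) - r
            prot[(d >= w0) & (d <= w1)] = 1.0
        prot = ndimage.gaussian_filter(prot, 1.0)
    elif name.startswith("reticular"):
        f = cls_params["freq"]
        theta = rng.uniform(0, np.pi)
        phase = rng.uniform(0, 2 * np.pi)
        yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
        wave = np.sin(2 * np.pi * f * (xx * np.cos(theta) + yy * np.sin(theta)) + phase)
        prot = (wave > 0.2).astype(float)
        prot = ndimage.gaussian_filter(prot, 0.8)
    else:
        raise ValueError(f"unknown class archetype {name!r}")
    if prot.max() <= 0:
        raise ValueError(f"class {name!r} produced an empty protein channel")
    return prot


def generate_image(
    spec: SyntheticSpec, class_index: int, rng: np.random.Generator
):
    """One synthetic image: (rgb uint8, true dna map, true protein map)."""
    shape = tuple(spec.image_size)
    dna, centers = _dna_map(shape, rng, spec)
    prot = _protein_map(shape, DEFAULT_CLASSES[class_index - 1], dna, centers, rng)
    dna_noisy = np.clip(dna + rng.normal(0, spec.noise_sd, shape), 0, None)
    prot_noisy = np.clip(prot + rng.normal(0, spec.noise_sd, shape), 0, None)
    rgb = rgb_from_density(dna_noisy, prot_noisy, spec.stain_basis)
    return np.round(rgb).astype(np.uint8), dna, prot


def generate_dataset(spec: SyntheticSpec | None = None):
    """Generate the full synthetic corpus.

    Returns ``(images, labels, manifest)``: a list of HxWx3 uint8 arrays,
    an int label array (classes 1..n_classes), and a manifest of dicts
    retaining ground truth (class name, per-image seed) for
    parameter-recovery tests.  Deterministic given ``spec.seed``.
    """
    if spec is None:
        spec = SyntheticSpec()
    ss = np.random.SeedSequence(spec.seed)
    children = ss.spawn(spec.n_classes * spec.images_per_class)
    images, labels, manifest = [], [], []
    idx = 0
    for cls in range(1, spec.n_classes + 1):
        for j in range(spec.images_per_class):
            rng = np.random.default_rng(children[idx])
            rgb, dna, prot = generate_image(spec, cls, rng)
            source_id = f"class{cls}_{DEFAULT_CLASSES[cls - 1]['name']}_{j:03d}"
            images.append(rgb)
            labels.append(cls)
            manifest.append(
                {
                    "source_id": source_id,
                    "label": cls,
                    "class_name": DEFAULT_CLASSES[cls - 1]["name"],
                    "seed_index": idx,
                    "true_dna": dna,
                    "true_protein": prot,
                }
            )
            idx += 1
    return images, np.asarray(labels, dtype=int), manifest


def write_dataset(spec: SyntheticSpec, out_dir) -> str:
    """Write the corpus as PNGs + a manifest TSV; returns the manifest path."""
    import os
    from PIL import Image

    os.makedirs(out_dir, exist_ok=True)
    images, labels, manifest = generate_dataset(spec)
    man_path = os.path.join(out_dir, "manifest.tsv")
    with open(man_path, "w") as fh:
        fh.write("image_path\tlabel\tclass_name\n")
        for img, rec in zip(images, manifest):
            fname = rec["source_id"] + ".png"
            Image.fromarray(img).save(os.path.join(out_dir, fname))
            fh.write(f"{fname}\t{rec['label']}\t{rec['class_name']}\n")
    return man_path


# ---------------------------------------------------------------------------
# Direct feature-matrix fixtures for classifier-level tests

def make_separable_feature_set(
    name: str = "SLFs",
    n_classes: int = 4,
    n_per_class: int = 20,
    n_informative: int | None = None,
    n_noise: int = 6,
    separation: float = 5.0,
    seed: int = 0,
):
    """A linearly separable labeled feature set (class means shifted by
    ``separation`` standard deviations on one informative axis each)."""
    from subloc2l.features.base import LabeledFeatureSet

    if n_informative is None:
        n_informative = n_classes
    rng = np.random.default_rng(seed)
    n = n_classes * n_per_class
    X = rng.normal(0, 1, (n, n_informative + n_noise))
    y = np.repeat(np.arange(1, n_classes + 1), n_per_class)
    for cls in range(n_classes):
        X[y == cls + 1, cls % n_informative] += separation
    return LabeledFeatureSet(name=name, matrix=X, labels=y)


def make_complementary_feature_sets(
    n_classes: int = 4,
    n_per_class: int = 20,
    n_noise: int = 4,
    separation: float = 5.0,
    seed: int = 0,
):
    """Two views, each resolving only half the classes.

    View 1 shifts class means only for the first half of the classes
    (the rest coincide); view 2 only for the second half.  Neither view
    alone can separate all classes; their union can, so an ensemble that
    integrates both must beat the best single view.
    """
    from subloc2l.features.base import LabeledFeatureSet

    rng = np.random.default_rng(seed)
    n = n_classes * n_per_class
    y = np.repeat(np.arange(1, n_classes + 1), n_per_class)
    half = n_classes // 2
    sets = []
    for view, resolved in enumerate(
        (range(half), range(half, n_classes)), start=1
    ):
        resolved = list(resolved)
        X = rng.normal(0, 1, (n, len(resolved) + n_noise))
        for k, cls in enumerate(resolved):
            X[y == cls + 1, k] += separation
        sets.append(LabeledFeatureSet(name=f"view{view}", matrix=X, labels=y))
    return sets
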
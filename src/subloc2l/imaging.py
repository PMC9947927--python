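"""Stain separation of brightfield IHC-style RGB images.

A two-stain IHC image is modelled with the Beer-Lambert law: the light
transmitted at each pixel is ``I = I0 * exp(-OD)`` where the optical
density ``OD`` is a non-negative combination of the two stains' unit
absorbance vectors.  Linear spectral separation inverts this model
pixel-wise, recovering a DNA-stain density map and a protein-stain
density map from the RGB image.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from PIL import Image

#: Canonical hematoxylin (DNA) and DAB (protein) absorbance vectors for
#: brightfield IHC, unit-normalized.
HEMATOXYLIN = (0.650, 0.704, 0.286)
DAB = (0.269, 0.568, 0.778)


@dataclass(frozen=True)
class StainBasis:
    """Absorbance basis of a two-stain image.

    Parameters
    ----------
    dna_vector, protein_vector
        3-vectors of per-channel optical-density absorbance.  Stored
        unit-normalized.
    background_intensity
        Intensity of unstained background (I0), > 0.
    """

    dna_vector: tuple = HEMATOXYLIN
    protein_vector: tuple = DAB
    background_intensity: float = 255.0

    def __post_init__(self):
        for name in ("dna_vector", "protein_vector"):
            v = np.asarray(getattr(self, name), dtype=float)
            if v.shape != (3,):
                raise ValueError(f"{name} must be a 3-vector")
            if np.any(v < 0) or not np.any(v > 0):
                raise ValueError(f"{name} must be non-negative and non-zero")
            object.__setattr__(self, name, tuple(v / np.linalg.norm(v)))
        if self.background_intensity <= 0:
            raise ValueError("background_intensity must be > 0")
        if np.linalg.matrix_rank(self.matrix(), tol=1e-8) < 2:
            raise ValueError("stain vectors are collinear (degenerate basis)")

    def matrix(self) -> np.ndarray:
        """3x2 matrix with the stain vectors as columns [dna, protein]."""
        return np.column_stack(
            [np.asarray(self.dna_vector), np.asarray(self.protein_vector)]
        )

    def swapped(self) -> "StainBasis":
        return StainBasis(self.protein_vector, self.dna_vector, self.background_intensity)


@dataclass
class ChannelPair:
    """DNA and protein stain-density maps separated from one RGB image."""

    dna: np.ndarray
    protein: np.ndarray
    source_id: str = ""

    def __post_init__(self):
        self.dna = np.asarray(self.dna, dtype=float)
        self.protein = np.asarray(self.protein, dtype=float)
        if self.dna.shape != self.protein.shape or self.dna.ndim != 2:
            raise ValueError("dna and protein channels must be 2-D and same shape")
        if np.any(self.dna < 0) or np.any(self.protein < 0):
            raise ValueError("stain-density maps must be non-negative")


def _check_rgb(img: np.ndarray) -> np.ndarray:
    img = np.asarray(img, dtype=float)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError(f"expected an HxWx3 RGB array, got shape {img.shape}")
    return img


def optical_density(img: np.ndarray, background_intensity: float = 255.0) -> np.ndarray:
    """Convert an RGB image to per-channel optical density.

    ``OD_c = -log((pixel_c + 1) / (I0 + 1))``, clipped below at 0.  The +1
    offset avoids log(0) for fully absorbing pixels.
    """
    img = _check_rgb(img)
    if background_intensity <= 0:
        raise ValueError("background_intensity must be > 0")
    od = -np.log((img + 1.0) / (background_intensity + 1.0))
    return np.clip(od, 0.0, None)


def rgb_from_density(
    dna: np.ndarray, protein: np.ndarray, basis: StainBasis
) -> np.ndarray:
    """Render stain-density maps back to RGB via the inverse Beer-Lambert map.

    Inverse of :func:`optical_density` composed with the stain mixing:
    ``pixel = (I0 + 1) * exp(-OD) - 1``.
    """
    od = (
        np.asarray(dna)[..., None] * np.asarray(basis.dna_vector)
        + np.asarray(protein)[..., None] * np.asarray(basis.protein_vector)
    )
    rgb = (basis.background_intensity + 1.0) * np.exp(-od) - 1.0
    return np.clip(rgb, 0.0, basis.background_intensity)


def separate_stains(
    img: np.ndarray, basis: StainBasis | None = None, source_id: str = ""
) -> ChannelPair:
    """Separate an RGB image into DNA and protein stain-density maps.

    Solves, per pixel, the least-squares system ``OD = A @ [c_dna, c_prot]``
    with ``A`` the 3x2 stain-absorbance matrix; negative concentrations are
    clipped to 0 (stain densities are physical quantities).
    """
    if basis is None:
        basis = StainBasis()
    img = _check_rgb(img)
    od = optical_density(img, basis.background_intensity)
    A = basis.matrix()
    # Normal-equations pseudoinverse: 2x3, applied to every pixel at once.
    pinv = np.linalg.solve(A.T @ A, A.T)
    conc = od.reshape(-1, 3) @ pinv.T
    conc = np.clip(conc, 0.0, None).reshape(img.shape[0], img.shape[1], 2)
    return ChannelPair(dna=conc[..., 0], protein=conc[..., 1], source_id=source_id)


def read_rgb(path) -> np.ndarray:
    """Read a PNG/TIFF image as an HxWx3 float array in [0, 255].

    16-bit images are rescaled to the 8-bit range.
    """
    with Image.open(path) as im:
        arr = np.asarray(im)
    if arr.ndim == 3 and arr.shape[2] == 4:
        arr = arr[..., :3]
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ValueError(f"{path}: expected an RGB image, got shape {arr.shape}")
    arr = arr.astype(float)
    if arr.max() > 255:
        arr = arr * (255.0 / 65535.0)
    return arr


def write_gray(path, channel: np.ndarray) -> None:
    """Dump a stain-density map as an 8-bit grayscale PNG for inspection."""
    ch = np.asarray(channel, dtype=float)
    hi = ch.max()
    scaled = np.zeros_like(ch) if hi <= 0 else ch * (255.0 / hi)
    Image.fromarray(scaled.round().astype(np.uint8)).save(path)
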
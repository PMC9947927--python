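"""Locally encoded transform feature histogram (LET).

A multiscale descriptor built from Gaussian-derivative transforms of the
image.  At each scale sigma three transforms are computed:

* a scale-normalized gradient magnitude, quantized into 7 levels;
* the sign pattern of the two second derivatives (4 codes);
* a binary above/below-mean magnitude indicator.

The first two codes are jointly histogrammed *across* scales (capturing
cross-scale co-occurrence of local structure), the third per scale, for
a default total of 7^3 + 4^3 + 3*2 = 413 features.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage


@dataclass(frozen=True)
class LETRISTConfig:
    sigmas: tuple = (1.0, 2.0, 4.0)
    magnitude_levels: int = 7
    border: int = 8  # interior margin excluded from histograms

    @property
    def n_features(self) -> int:
        s = len(self.sigmas)
        return self.magnitude_levels**s + 4**s + 2 * s


def _transforms(img: np.ndarray, sigma: float):
    """(scale-normalized gradient magnitude, curvature sign code) at one scale."""
    ix = ndimage.gaussian_filter(img, sigma, order=(0, 1), mode="reflect")
    iy = ndimage.gaussian_filter(img, sigma, order=(1, 0), mode="reflect")
    ixx = ndimage.gaussian_filter(img, sigma, order=(0, 2), mode="reflect")
    iyy = ndimage.gaussian_filter(img, sigma, order=(2, 0), mode="reflect")
    mag = sigma * np.hypot(ix, iy)
    sign_code = 2 * (ixx >= 0).astype(np.int32) + (iyy >= 0).astype(np.int32)
    return mag, sign_code


def extract_letrist(img: np.ndarray, cfg: LETRISTConfig | None = None) -> np.ndarray:
    """LET descriptor (413-d by default).

    Degenerate (constant) images are well defined: all magnitudes are
    zero, so every magnitude code falls in the lowest quantization bin.
    """
    if cfg is None:
        cfg = LETRISTConfig()
    img = np.asarray(img, dtype=float)
    if img.ndim != 2:
        raise ValueError("expected a 2-D grayscale image")
    if min(img.shape) < 2 * cfg.border + 4:
        raise ValueError(
            f"image of shape {img.shape} too small for border {cfg.border}"
        )
    b = cfg.border
    L = cfg.magnitude_levels
    mag_codes, sign_codes = [], []
    per_scale_binary = []
    for sigma in cfg.sigmas:
        mag, sign = _transforms(img, sigma)
        mag = mag[b:-b, b:-b]
        sign = sign[b:-b, b:-b]
        hi = mag.max()
        if hi <= 0:
            code = np.zeros(mag.shape, dtype=np.int32)
        else:
            code = np.minimum((mag * (L / hi)).astype(np.int32), L - 1)
        mag_codes.append(code)
        sign_codes.append(sign)
        binary = (mag >= mag.mean()).astype(np.int32)
        h = np.bincount(binary.ravel(), minlength=2).astype(float)
        per_scale_binary.append(h / h.sum())

    s = len(cfg.sigmas)
    joint_mag = np.zeros(mag_codes[0].shape, dtype=np.int64)
    joint_sign = np.zeros(sign_codes[0].shape, dtype=np.int64)
    for k in range(s):
        joint_mag = joint_mag * L + mag_codes[k]
        joint_sign = joint_sign * 4 + sign_codes[k]
    h_mag = np.bincount(joint_mag.ravel(), minlength=L**s).astype(float)
    h_sign = np.bincount(joint_sign.ravel(), minlength=4**s).astype(float)
    return np.concatenate(
        [h_mag / h_mag.sum(), h_sign / h_sign.sum()] + per_scale_binary
    )
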
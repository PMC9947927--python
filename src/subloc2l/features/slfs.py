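"""Global subcellular-location features (SLFs).

SLFs concatenate a 4-dimensional DNA-distribution block — statistics
relating the protein channel to the DNA channel — with 836 Haralick
gray-level co-occurrence (GLCM) statistics of the protein channel.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.feature import graycomatrix
from skimage.filters import threshold_otsu

from subloc2l.features.base import rescale_u8

#: GLCM statistic names, in output order per (distance, angle) block.
HARALICK_STATS = (
    "asm",
    "contrast",
    "correlation",
    "variance",
    "homogeneity",
    "sum_average",
    "sum_variance",
    "sum_entropy",
    "entropy",
    "difference_variance",
    "difference_entropy",
)


@dataclass(frozen=True)
class HaralickConfig:
    """GLCM configuration.

    The default — 64 gray levels, 4 directions, distances 1..19, 11
    statistics per co-occurrence matrix — yields 11 * 4 * 19 = 836
    features.
    """

    levels: int = 64
    distances: tuple = tuple(range(1, 20))
    angles: tuple = (0.0, np.pi / 4, np.pi / 2, 3 * np.pi / 4)

    @property
    def n_features(self) -> int:
        return len(HARALICK_STATS) * len(self.distances) * len(self.angles)

    def feature_ids(self) -> list:
        ids = []
        for d in self.distances:
            for k, _ in enumerate(self.angles):
                for s in HARALICK_STATS:
                    ids.append(f"har_d{d}_a{k}_{s}")
        return ids


def _glcm_stats(P: np.ndarray, levels: int) -> np.ndarray:
    """The 11 Haralick statistics of one normalized symmetric GLCM."""
    i = np.arange(levels, dtype=float)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    eps = 1e-12

    asm = np.sum(P * P)
    contrast = np.sum(P * (ii - jj) ** 2)

    mu_i = np.sum(P * ii)
    mu_j = np.sum(P * jj)
    sig_i = np.sqrt(np.sum(P * (ii - mu_i) ** 2))
    sig_j = np.sqrt(np.sum(P * (jj - mu_j) ** 2))
    if sig_i * sig_j < eps:
        correlation = 0.0  # degenerate GLCM: defined limit
    else:
        correlation = np.sum(P * (ii - mu_i) * (jj - mu_j)) / (sig_i * sig_j)

    variance = np.sum(P * (ii - mu_i) ** 2)
    homogeneity = np.sum(P / (1.0 + (ii - jj) ** 2))

    # Sum (p_{x+y}) and difference (p_{x-y}) distributions.
    k_sum = np.arange(2 * levels - 1, dtype=float)
    p_sum = np.zeros(2 * levels - 1)
    np.add.at(p_sum, (ii + jj).astype(int).ravel(), P.ravel())
    k_diff = np.arange(levels, dtype=float)
    p_diff = np.zeros(levels)
    np.add.at(p_diff, np.abs(ii - jj).astype(int).ravel(), P.ravel())

    sum_average = np.sum(k_sum * p_sum)
    sum_variance = np.sum((k_sum - sum_average) ** 2 * p_sum)
    sum_entropy = -np.sum(p_sum[p_sum > eps] * np.log(p_sum[p_sum > eps]))
    entropy = -np.sum(P[P > eps] * np.log(P[P > eps]))
    diff_average = np.sum(k_diff * p_diff)
    difference_variance = np.sum((k_diff - diff_average) ** 2 * p_diff)
    difference_entropy = -np.sum(p_diff[p_diff > eps] * np.log(p_diff[p_diff > eps]))

    return np.array(
        [
            asm,
            contrast,
            correlation,
            variance,
            homogeneity,
            sum_average,
            sum_variance,
            sum_entropy,
            entropy,
            difference_variance,
            difference_entropy,
        ]
    )


def extract_haralick(img: np.ndarray, cfg: HaralickConfig | None = None) -> np.ndarray:
    """Haralick GLCM statistics of a grayscale image (836-d by default).

    The image is min-max rescaled to 8 bits then quantized to
    ``cfg.levels`` gray levels; co-occurrence matrices are symmetric and
    normalized.  Statistics with 0/0 limits (correlation on a degenerate
    matrix) return their defined limit, never NaN.
    """
    if cfg is None:
        cfg = HaralickConfig()
    img = np.asarray(img, dtype=float)
    if img.ndim != 2 or min(img.shape) < 2:
        raise ValueError("image must be 2-D and at least 2x2")
    if min(img.shape) <= max(cfg.distances):
        raise ValueError(
            f"image of shape {img.shape} too small for GLCM distance {max(cfg.distances)}"
        )
    u8 = rescale_u8(img)
    q = (u8.astype(int) * cfg.levels // 256).astype(np.uint8)
    glcm = graycomatrix(
        q,
        distances=cfg.distances,
        angles=cfg.angles,
        levels=cfg.levels,
        symmetric=True,
        normed=True,
    )
    out = np.empty(cfg.n_features)
    pos = 0
    for di in range(len(cfg.distances)):
        for ai in range(len(cfg.angles)):
            out[pos : pos + len(HARALICK_STATS)] = _glcm_stats(
                glcm[:, :, di, ai], cfg.levels
            )
            pos += len(HARALICK_STATS)
    return out


def _otsu_mask(channel: np.ndarray) -> np.ndarray:
    """Foreground mask by Otsu threshold; constant channels give ch > 0."""
    lo, hi = channel.min(), channel.max()
    if hi <= lo:
        return channel > 0
    return channel > threshold_otsu(channel)


def extract_dna_distribution(dna: np.ndarray, protein: np.ndarray) -> np.ndarray:
    """Four statistics relating the protein signal to the DNA region.

    1. fraction of above-threshold protein pixels inside the
       above-threshold DNA region;
    2. fraction of total protein signal inside the DNA region;
    3. distance between the protein and DNA centers of mass, in
       image-diagonal units;
    4. ratio of total protein to total DNA signal.

    Thresholds are Otsu per channel.  Degenerate channels (all-zero DNA
    or protein) yield 0 for the affected statistics, never NaN.
    """
    dna = np.asarray(dna, dtype=float)
    protein = np.asarray(protein, dtype=float)
    if dna.shape != protein.shape or dna.ndim != 2:
        raise ValueError("channels must be 2-D and same shape")

    dna_mask = _otsu_mask(dna)
    prot_mask = _otsu_mask(protein)

    n_prot = prot_mask.sum()
    overlap = (prot_mask & dna_mask).sum() / n_prot if n_prot else 0.0

    tot_prot = protein.sum()
    inside = protein[dna_mask].sum() / tot_prot if tot_prot > 0 else 0.0

    tot_dna = dna.sum()
    if tot_prot > 0 and tot_dna > 0:
        yy, xx = np.mgrid[0 : dna.shape[0], 0 : dna.shape[1]]
        com_p = np.array([np.sum(yy * protein), np.sum(xx * protein)]) / tot_prot
        com_d = np.array([np.sum(yy * dna), np.sum(xx * dna)]) / tot_dna
        diag = np.hypot(dna.shape[0] - 1, dna.shape[1] - 1)
        com_dist = float(np.linalg.norm(com_p - com_d) / diag) if diag > 0 else 0.0
    else:
        com_dist = 0.0

    ratio = tot_prot / tot_dna if tot_dna > 0 else 0.0
    return np.array([overlap, inside, com_dist, ratio])


def extract_slfs(cp, cfg: HaralickConfig | None = None) -> np.ndarray:
    """SLFs: [DNA distribution (4) || protein-channel Haralick (836)]."""
    dna_stats = extract_dna_distribution(cp.dna, cp.protein)
    har = extract_haralick(cp.protein, cfg)
    return np.concatenate([dna_stats, har])
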
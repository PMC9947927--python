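"""Local binary pattern family descriptors: LBP, CLBP, RICLBP.

Conventions shared by all three:

* images are min-max rescaled to uint8 before coding;
* neighbors are sampled at integer offsets (no interpolation), at radius
  R along the 8 (or 4) compass directions;
* codes are computed on interior pixels only (no padding);
* comparison is ``neighbor >= center``; bit 0 sits at the east neighbor
  and bits proceed counter-clockwise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from subloc2l.features.base import rescale_u8

# (dy, dx) unit offsets, bit 0 = east, counter-clockwise.
_OFFSETS8 = [(0, 1), (-1, 1), (-1, 0), (-1, -1), (0, -1), (1, -1), (1, 0), (1, 1)]
_OFFSETS4 = [(0, 1), (-1, 0), (0, -1), (1, 0)]


def _shifted(img: np.ndarray, dy: int, dx: int, r: int) -> np.ndarray:
    """View of img shifted by (dy, dx), cropped to the radius-r interior."""
    h, w = img.shape
    return img[r + dy : h - r + dy, r + dx : w - r + dx]


def _center(img: np.ndarray, r: int) -> np.ndarray:
    return img[r:-r, r:-r]


def lbp_codes(img: np.ndarray, radius: int = 1) -> np.ndarray:
    """Raw 8-neighbor LBP codes (0..255) at interior pixels."""
    img = np.asarray(img, dtype=float)
    if img.ndim != 2 or min(img.shape) < 2 * radius + 1:
        raise ValueError(f"image too small for LBP radius {radius}")
    c = _center(img, radius)
    codes = np.zeros(c.shape, dtype=np.int32)
    for bit, (dy, dx) in enumerate(_OFFSETS8):
        codes |= (_shifted(img, dy * radius, dx * radius, radius) >= c).astype(
            np.int32
        ) << bit
    return codes


def extract_lbp(img: np.ndarray) -> np.ndarray:
    """256-bin histogram of raw LBP(8,1) codes, L1-normalized."""
    u8 = rescale_u8(np.asarray(img, dtype=float))
    if min(u8.shape) < 3:
        raise ValueError("image must be at least 3x3 for LBP")
    codes = lbp_codes(u8.astype(float), radius=1)
    hist = np.bincount(codes.ravel(), minlength=256).astype(float)
    return hist / hist.sum()


# ---------------------------------------------------------------------------
# CLBP

_RIU2_MAP = None


def _riu2(codes: np.ndarray) -> np.ndarray:
    """Rotation-invariant uniform-2 mapping of 8-bit codes (10 bins)."""
    global _RIU2_MAP
    if _RIU2_MAP is None:
        m = np.empty(256, dtype=np.int32)
        for code in range(256):
            bits = [(code >> b) & 1 for b in range(8)]
            transitions = sum(bits[b] != bits[(b + 1) % 8] for b in range(8))
            m[code] = sum(bits) if transitions <= 2 else 9
        _RIU2_MAP = m
    return _RIU2_MAP[codes]


@dataclass(frozen=True)
class CLBPConfig:
    """Completed LBP configuration.

    Per radius the descriptor concatenates the joint sign/magnitude/center
    histogram (10*10*2 = 200 bins), the joint sign/magnitude histogram
    (100 bins) and the center histogram (2 bins): 302 bins per radius.
    The default radii (1, 2, 3) give 906 features.
    """

    radii: tuple = (1, 2, 3)
    n_neighbors: int = 8  # fixed: riu2 bin counts assume P=8

    @property
    def n_features(self) -> int:
        return 302 * len(self.radii)


def clbp_components(img: np.ndarray, radius: int):
    """Per-pixel CLBP sign / magnitude / center codes at one radius.

    Sign: riu2-mapped code of (neighbor >= center).  Magnitude: riu2 code
    of (|neighbor - center| >= c) with c the image-wide mean absolute
    local difference.  Center: center >= image-wide mean gray level.
    """
    img = np.asarray(img, dtype=float)
    if min(img.shape) < 2 * radius + 1:
        raise ValueError(f"image too small for CLBP radius {radius}")
    c = _center(img, radius)
    diffs = np.stack(
        [_shifted(img, dy * radius, dx * radius, radius) - c for dy, dx in _OFFSETS8]
    )
    s_code = np.zeros(c.shape, dtype=np.int32)
    for bit in range(8):
        s_code |= (diffs[bit] >= 0).astype(np.int32) << bit
    mag = np.abs(diffs)
    thr = mag.mean()
    m_code = np.zeros(c.shape, dtype=np.int32)
    for bit in range(8):
        m_code |= (mag[bit] >= thr).astype(np.int32) << bit
    c_code = (c >= img.mean()).astype(np.int32)
    return _riu2(s_code), _riu2(m_code), c_code


def extract_clbp(img: np.ndarray, cfg: CLBPConfig | None = None) -> np.ndarray:
    """Completed LBP descriptor (906-d by default)."""
    if cfg is None:
        cfg = CLBPConfig()
    u8 = rescale_u8(np.asarray(img, dtype=float)).astype(float)
    parts = []
    for r in cfg.radii:
        s, m, c = clbp_components(u8, r)
        joint_smc = np.bincount(
            (s * 20 + m * 2 + c).ravel(), minlength=200
        ).astype(float)
        joint_sm = np.bincount((s * 10 + m).ravel(), minlength=100).astype(float)
        hist_c = np.bincount(c.ravel(), minlength=2).astype(float)
        for h in (joint_smc, joint_sm, hist_c):
            parts.append(h / h.sum())
    return np.concatenate(parts)


# ---------------------------------------------------------------------------
# RICLBP

def _rot4(code: np.ndarray | int, k: int):
    """Rotate a 4-bit LBP code counter-clockwise by k*90 degrees."""
    k = k % 4
    return ((code << k) | (code >> (4 - k))) & 0xF


_RIC_TABLE = None


def _ric_table() -> np.ndarray:
    """Lookup 16x16 -> 136 rotation-invariant pair-label indices.

    A pair (a, b) read along a displacement is equivalent to the pair
    read from the opposite end after a 180-degree rotation:
    (a, b) ~ (rot180(b), rot180(a)).  The 256 ordered pairs collapse to
    (256 + 16)/2 = 136 equivalence classes.
    """
    global _RIC_TABLE
    if _RIC_TABLE is None:
        canon = {}
        table = np.empty((16, 16), dtype=np.int32)
        for a in range(16):
            for b in range(16):
                key = min((a, b), (_rot4(b, 2), _rot4(a, 2)))
                if key not in canon:
                    canon[key] = len(canon)
                table[a, b] = canon[key]
        assert len(canon) == 136
        _RIC_TABLE = table
    return _RIC_TABLE


@dataclass(frozen=True)
class RICLBPConfig:
    """Rotation-invariant co-occurrence LBP configuration.

    Each scale is a (lbp_radius, pair_displacement) pair; each yields a
    136-bin histogram, so the default 3 scales give 408 features.
    """

    scales: tuple = ((1, 2), (2, 4), (4, 8))

    @property
    def n_features(self) -> int:
        return 136 * len(self.scales)


def riclbp_pair_labels(img: np.ndarray, radius: int, disp: int) -> np.ndarray:
    """All rotation-invariant pair labels at one (radius, displacement) scale.

    4-neighbor LBP codes are paired along displacements at 0, 45, 90 and
    135 degrees.  Codes of pairs in the 90/135-degree directions are
    rotated back by 90 degrees before labelling so the histogram is
    exactly invariant under 90-degree image rotation (interior cropping
    aside); the 180-degree pair equivalence of the label table handles
    opposite directions.
    """
    img = np.asarray(img, dtype=float)
    need = 2 * radius + disp + 1
    if min(img.shape) < need:
        raise ValueError(f"image too small for RICLBP radius {radius}, displacement {disp}")
    c = _center(img, radius)
    codes = np.zeros(c.shape, dtype=np.int32)
    for bit, (dy, dx) in enumerate(_OFFSETS4):
        codes |= (_shifted(img, dy * radius, dx * radius, radius) >= c).astype(
            np.int32
        ) << bit
    table = _ric_table()
    labels = []
    # (dy, dx, code rotation applied to both members before labelling)
    for dy, dx, rot in ((0, disp, 0), (-disp, disp, 0), (-disp, 0, 1), (-disp, -disp, 1)):
        h, w = codes.shape
        y0, y1 = max(0, -dy), min(h, h - dy)
        x0, x1 = max(0, -dx), min(w, w - dx)
        a = codes[y0:y1, x0:x1]
        b = codes[y0 + dy : y1 + dy, x0 + dx : x1 + dx]
        labels.append(table[_rot4(a, -rot), _rot4(b, -rot)].ravel())
    return np.concatenate(labels)


def extract_riclbp(img: np.ndarray, cfg: RICLBPConfig | None = None) -> np.ndarray:
    """Rotation-invariant co-occurrence LBP descriptor (408-d by default)."""
    if cfg is None:
        cfg = RICLBPConfig()
    u8 = rescale_u8(np.asarray(img, dtype=float)).astype(float)
    parts = []
    for radius, disp in cfg.scales:
        labels = riclbp_pair_labels(u8, radius, disp)
        hist = np.bincount(labels, minlength=136).astype(float)
        parts.append(hist / hist.sum())
    return np.concatenate(parts)
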
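"""Shared feature containers and conventions."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Declared dimensionality of each heterogeneous feature set.
SET_DIMENSIONS = {"SLFs": 840, "LBP": 256, "CLBP": 906, "RICLBP": 408, "LET": 413}


@dataclass
class FeatureVector:
    """One descriptor vector for one image."""

    values: np.ndarray
    set_name: str
    source_id: str = ""

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float).ravel()
        if self.set_name not in SET_DIMENSIONS:
            raise ValueError(f"unknown feature set {self.set_name!r}")
        expected = SET_DIMENSIONS[self.set_name]
        if self.values.size != expected:
            raise ValueError(
                f"{self.set_name} vector has length {self.values.size}, expected {expected}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError(f"{self.set_name} vector contains non-finite entries")


@dataclass
class LabeledFeatureSet:
    """One heterogeneous feature set over N samples: N x d matrix + labels."""

    name: str
    matrix: np.ndarray
    labels: np.ndarray
    feature_ids: list = field(default_factory=list)
    source_ids: list = field(default_factory=list)

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.matrix.ndim != 2:
            raise ValueError("matrix must be 2-D")
        if self.matrix.shape[0] != self.labels.size:
            raise ValueError("row count must equal label count")
        if not self.feature_ids:
            self.feature_ids = [f"{self.name}_{i}" for i in range(self.matrix.shape[1])]
        if len(self.feature_ids) != self.matrix.shape[1]:
            raise ValueError("feature_ids length must equal column count")

    @property
    def n_samples(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_features(self) -> int:
        return self.matrix.shape[1]


def rescale_u8(img: np.ndarray) -> np.ndarray:
    """Min-max rescale a grayscale image to uint8 [0, 255].

    Constant images map to all zeros; code-based descriptors need integer
    gray levels and this fixes the convention.
    """
    img = np.asarray(img, dtype=float)
    if img.ndim != 2:
        raise ValueError("expected a 2-D grayscale image")
    lo, hi = img.min(), img.max()
    if hi <= lo:
        return np.zeros(img.shape, dtype=np.uint8)
    return np.round((img - lo) * (255.0 / (hi - lo))).astype(np.uint8)
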
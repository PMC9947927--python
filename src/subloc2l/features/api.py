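"""Top-level feature extraction over channel pairs and datasets."""

from __future__ import annotations

import numpy as np

from subloc2l.features.base import FeatureVector, LabeledFeatureSet, SET_DIMENSIONS
from subloc2l.features.lbp import (
    CLBPConfig,
    RICLBPConfig,
    extract_clbp,
    extract_lbp,
    extract_riclbp,
)
from subloc2l.features.letrist import LETRISTConfig, extract_letrist
from subloc2l.features.slfs import HaralickConfig, extract_slfs

SET_NAMES = ("SLFs", "LBP", "CLBP", "RICLBP", "LET")


def feature_ids(set_name: str) -> list:
    """Human-readable identifiers for each feature of a set."""
    if set_name == "SLFs":
        dna = ["dna_overlap", "dna_inside_fraction", "dna_com_distance", "dna_signal_ratio"]
        return dna + HaralickConfig().feature_ids()
    if set_name == "LBP":
        return [f"lbp_{i}" for i in range(256)]
    if set_name == "CLBP":
        ids = []
        for r in CLBPConfig().radii:
            ids += [f"clbp_r{r}_smc_{i}" for i in range(200)]
            ids += [f"clbp_r{r}_sm_{i}" for i in range(100)]
            ids += [f"clbp_r{r}_c_{i}" for i in range(2)]
        return ids
    if set_name == "RICLBP":
        ids = []
        for r, d in RICLBPConfig().scales:
            ids += [f"riclbp_r{r}d{d}_{i}" for i in range(136)]
        return ids
    if set_name == "LET":
        cfg = LETRISTConfig()
        s = len(cfg.sigmas)
        ids = [f"let_mag_{i}" for i in range(cfg.magnitude_levels**s)]
        ids += [f"let_sign_{i}" for i in range(4**s)]
        for k in range(s):
            ids += [f"let_bin_s{k}_{i}" for i in range(2)]
        return ids
    raise ValueError(f"unknown feature set {set_name!r}")


def extract_all(cp) -> dict:
    """Extract the five heterogeneous feature sets from one channel pair.

    SLFs use both channels (DNA-referenced statistics + protein-channel
    Haralick); LBP, CLBP, RICLBP and LET are computed on the protein
    channel.  Returns ``{set_name: FeatureVector}``.
    """
    protein = cp.protein
    vectors = {
        "SLFs": extract_slfs(cp),
        "LBP": extract_lbp(protein),
        "CLBP": extract_clbp(protein),
        "RICLBP": extract_riclbp(protein),
        "LET": extract_letrist(protein),
    }
    return {
        name: FeatureVector(values=v, set_name=name, source_id=cp.source_id)
        for name, v in vectors.items()
    }


def extract_dataset(channel_pairs, labels) -> dict:
    """Extract all five feature sets for a list of channel pairs.

    Returns ``{set_name: LabeledFeatureSet}`` with rows in input order.
    """
    labels = np.asarray(labels, dtype=int)
    if len(channel_pairs) != labels.size:
        raise ValueError("number of channel pairs must equal number of labels")
    rows = {name: [] for name in SET_NAMES}
    ids = []
    for cp in channel_pairs:
        vecs = extract_all(cp)
        for name in SET_NAMES:
            rows[name].append(vecs[name].values)
        ids.append(cp.source_id)
    return {
        name: LabeledFeatureSet(
            name=name,
            matrix=np.vstack(rows[name]),
            labels=labels,
            feature_ids=feature_ids(name),
            source_ids=list(ids),
        )
        for name in SET_NAMES
    }
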
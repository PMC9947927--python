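"""End-to-end orchestration: configuration, artifact I/O, command chains.

A single YAML file configures every stage (stain basis, SDA thresholds,
SAE hyperparameters per level, stacking folds, CV folds, seed).  All
randomness descends from the one root seed through per-component child
seeds, so component runs and end-to-end runs agree.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import asdict, replace

import numpy as np
import pandas as pd
import yaml

from subloc2l.evaluation import compute_metrics, stratified_kfold_cv
from subloc2l.features.api import extract_dataset, feature_ids, SET_NAMES
from subloc2l.features.base import LabeledFeatureSet
from subloc2l.fixtures import SyntheticSpec, write_dataset
from subloc2l.imaging import StainBasis, read_rgb, separate_stains
from subloc2l.sae import SAEConfig, SAEModel
from subloc2l.selection import sda_select
from subloc2l.two_level import TwoLevelConfig, TwoLevelModel, train_two_level, predict_two_level

log = logging.getLogger("subloc2l")

_DEFAULTS = {
    "stain": {
        "dna_vector": [0.650, 0.704, 0.286],
        "protein_vector": [0.269, 0.568, 0.778],
        "background": 255.0,
    },
    "sda": {"f_enter": 3.84, "f_remove": 2.71, "max_features": 15},
    "sae": {
        "first_level": {},
        "second_level": {"hidden1": 7, "hidden2": 7},
    },
    "stacking_folds": 5,
    "cv": {"k": 10},
    "fixtures": {},
    "seed": 0,
}

_SAE_KEYS = {
    "hidden1", "hidden2", "sparsity_target", "sparsity_weight", "l2_weight",
    "pretrain_epochs", "finetune_epochs", "learning_rate", "seed",
}


def load_config(path_or_dict=None) -> dict:
    """Load and validate a pipeline config; unknown keys are collected
    into a single error listing every offending key."""
    if path_or_dict is None:
        raw = {}
    elif isinstance(path_or_dict, dict):
        raw = path_or_dict
    else:
        with open(path_or_dict) as fh:
            raw = yaml.safe_load(fh) or {}
    errors = []
    cfg = json.loads(json.dumps(_DEFAULTS))  # deep copy
    for key, val in raw.items():
        if key not in cfg:
            errors.append(f"unknown config key: {key}")
            continue
        if isinstance(cfg[key], dict):
            if not isinstance(val, dict):
                errors.append(f"config key {key} must be a mapping")
                continue
            for sub, sval in val.items():
                if key == "sae":
                    if sub not in ("first_level", "second_level"):
                        errors.append(f"unknown config key: sae.{sub}")
                        continue
                    bad = set(sval) - _SAE_KEYS
                    errors.extend(f"unknown config key: sae.{sub}.{b}" for b in bad)
                    cfg[key][sub].update({k: v for k, v in sval.items() if k in _SAE_KEYS})
                elif key == "fixtures":
                    cfg[key][sub] = sval
                elif sub not in cfg[key]:
                    errors.append(f"unknown config key: {key}.{sub}")
                else:
                    cfg[key][sub] = sval
        else:
            cfg[key] = val
    if errors:
        raise ValueError("invalid configuration: " + "; ".join(errors))
    return cfg


def stain_basis_from_config(cfg: dict) -> StainBasis:
    s = cfg["stain"]
    return StainBasis(
        tuple(s["dna_vector"]), tuple(s["protein_vector"]), s["background"]
    )


def two_level_config(cfg: dict) -> TwoLevelConfig:
    first = SAEConfig(**cfg["sae"]["first_level"])
    second = SAEConfig(**cfg["sae"]["second_level"])
    return TwoLevelConfig(
        f_enter=cfg["sda"]["f_enter"],
        f_remove=cfg["sda"]["f_remove"],
        max_features=cfg["sda"]["max_features"],
        first_level=first,
        second_level=second,
        stacking_folds=cfg["stacking_folds"],
        seed=cfg["seed"],
    )


# ---------------------------------------------------------------------------
# Feature CSV I/O (header row of feature ids; first columns source_id, label)

def save_feature_set(fs: LabeledFeatureSet, path) -> None:
    df = pd.DataFrame(fs.matrix, columns=fs.feature_ids)
    df.insert(0, "label", fs.labels)
    df.insert(0, "source_id", fs.source_ids or [f"s{i}" for i in range(fs.n_samples)])
    df.to_csv(path, index=False)


def load_feature_set(path, name: str) -> LabeledFeatureSet:
    df = pd.read_csv(path)
    return LabeledFeatureSet(
        name=name,
        matrix=df.drop(columns=["source_id", "label"]).to_numpy(float),
        labels=df["label"].to_numpy(int),
        feature_ids=[c for c in df.columns if c not in ("source_id", "label")],
        source_ids=df["source_id"].tolist(),
    )


# ---------------------------------------------------------------------------
# Commands

def run_make_fixtures(cfg: dict, out_dir) -> str:
    spec = SyntheticSpec(
        seed=cfg["seed"], stain_basis=stain_basis_from_config(cfg), **cfg["fixtures"]
    )
    return write_dataset(spec, out_dir)


def _load_manifest(manifest_path):
    df = pd.read_csv(manifest_path, sep="\t")
    if "image_path" not in df or "label" not in df:
        raise ValueError("manifest must have image_path and label columns")
    return df


def run_extract(cfg: dict, image_dir, manifest_path, out_dir) -> dict:
    """Images + manifest -> per-set feature CSVs; returns {set: path}."""
    os.makedirs(out_dir, exist_ok=True)
    df = _load_manifest(manifest_path)
    basis = stain_basis_from_config(cfg)
    pairs = []
    for _, row in df.iterrows():
        img = read_rgb(os.path.join(image_dir, row["image_path"]))
        pairs.append(separate_stains(img, basis, source_id=str(row["image_path"])))
    sets = extract_dataset(pairs, df["label"].to_numpy(int))
    paths = {}
    for name, fs in sets.items():
        paths[name] = os.path.join(out_dir, f"features_{name}.csv")
        save_feature_set(fs, paths[name])
    return paths


def run_select(cfg: dict, feature_csv, name, out_json, out_csv=None) -> dict:
    fs = load_feature_set(feature_csv, name)
    sel = sda_select(
        fs, cfg["sda"]["f_enter"], cfg["sda"]["f_remove"], cfg["sda"]["max_features"]
    )
    result = {
        "set": name,
        "selected_indices": sel.selected,
        "selected_ids": [fs.feature_ids[i] for i in sel.selected],
        "lambda_trace": sel.lambda_trace,
    }
    with open(out_json, "w") as fh:
        json.dump(result, fh, indent=2)
    if out_csv:
        reduced = LabeledFeatureSet(
            name=name,
            matrix=fs.matrix[:, sel.selected],
            labels=fs.labels,
            feature_ids=[fs.feature_ids[i] for i in sel.selected],
            source_ids=fs.source_ids,
        )
        save_feature_set(reduced, out_csv)
    return result


def _load_sets(feature_dir):
    sets = []
    for name in SET_NAMES:
        path = os.path.join(feature_dir, f"features_{name}.csv")
        if not os.path.exists(path):
            raise FileNotFoundError(f"missing feature CSV: {path}")
        sets.append(load_feature_set(path, name))
    return sets


def save_two_level(model: TwoLevelModel, path) -> None:
    """Self-describing JSON archive of a trained two-level model."""
    payload = {
        "schema": "subloc2l.two-level/1",
        "config": {
            **{k: getattr(model.config, k) for k in
               ("f_enter", "f_remove", "max_features", "stacking_folds", "seed")},
            "first_level": asdict(model.config.first_level),
            "second_level": asdict(model.config.second_level),
        },
        "classes": model.classes_.tolist(),
        "second_level_model": model.second_level.to_dict(),
        "first_level": [
            {
                "set": name,
                "selected": sel.selected,
                "lambda_trace": sel.lambda_trace,
                "f_enter": sel.f_enter,
                "f_remove": sel.f_remove,
                "means": sel.means.tolist(),
                "stds": sel.stds.tolist(),
                "model": sae.to_dict(),
            }
            for name, sel, sae in model.first_level
        ],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def load_two_level(path) -> TwoLevelModel:
    from subloc2l.selection import SelectionResult

    with open(path) as fh:
        d = json.load(fh)
    c = d["config"]
    cfg = TwoLevelConfig(
        f_enter=c["f_enter"], f_remove=c["f_remove"], max_features=c["max_features"],
        first_level=SAEConfig(**c["first_level"]),
        second_level=SAEConfig(**c["second_level"]),
        stacking_folds=c["stacking_folds"], seed=c["seed"],
    )
    first = [
        (
            rec["set"],
            SelectionResult(
                selected=rec["selected"], lambda_trace=rec["lambda_trace"],
                f_enter=rec["f_enter"], f_remove=rec["f_remove"],
                means=np.asarray(rec["means"]), stds=np.asarray(rec["stds"]),
            ),
            SAEModel.from_dict(rec["model"]),
        )
        for rec in d["first_level"]
    ]
    return TwoLevelModel(
        first_level=first,
        second_level=SAEModel.from_dict(d["second_level_model"]),
        config=cfg,
        classes_=np.asarray(d["classes"], dtype=int),
    )


def run_train(cfg: dict, feature_dir, model_path) -> TwoLevelModel:
    sets = _load_sets(feature_dir)
    model = train_two_level(sets, two_level_config(cfg))
    save_two_level(model, model_path)
    return model


def run_predict(cfg: dict, model_path, feature_dir, out_tsv) -> pd.DataFrame:
    model = load_two_level(model_path)
    sets = _load_sets(feature_dir)
    labels, decision = predict_two_level(model, {fs.name: fs.matrix for fs in sets})
    ids = sets[0].source_ids
    out = pd.DataFrame({"source_id": ids, "predicted_label": labels})
    for k, cls in enumerate(model.classes_):
        out[f"p_class{cls}"] = decision.probs[:, k]
    out.to_csv(out_tsv, sep="\t", index=False)
    return out


def run_cv(cfg: dict, feature_dir, out_json) -> dict:
    sets = _load_sets(feature_dir)
    fold_reports, pooled = stratified_kfold_cv(
        sets, k=cfg["cv"]["k"], cfg=two_level_config(cfg), seed=cfg["seed"]
    )
    report = {
        "seed": cfg["seed"],
        "k": cfg["cv"]["k"],
        "pooled": pooled.to_dict(),
        "per_fold": [r.to_dict() for r in fold_reports],
    }
    with open(out_json, "w") as fh:
        json.dump(report, fh, indent=2)
    return report
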
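"""Plain-text containers for datasets, feature matrices and trained models.

A dataset is a directory with ``manifest.json`` (M, p, N, noise_mode, seed,
trials_per_graph and one record per trial) plus one tab-separated file per
trial, N rows x M columns, full float precision.  Unlabeled containers (for
prediction-only use) carry ``graph_index: null``.  Feature matrices are a
TSV with a header row of stable feature names plus a JSON sidecar; trained
models serialise their coefficients and standardiser to a single JSON file.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np

from .simulate import (
    CausalGraph,
    LabeledDataset,
    TrialRecord,
    index_to_graph,
)
from .models import (
    CellBasedGraphClassifier,
    MatrixBasedGraphClassifier,
    _ConstantCell,
)

__all__ = [
    "write_dataset",
    "read_dataset",
    "write_features",
    "read_features",
    "save_model",
    "load_model",
    "RunConfig",
]

_FORMAT_VERSION = 1


def write_dataset(dataset: LabeledDataset, path) -> Path:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    records = []
    for t_id, tr in enumerate(dataset.trials):
        fname = f"trial_{t_id:06d}.tsv"
        np.savetxt(path / fname, tr.X, fmt="%.17g", delimiter="\t")
        records.append(
            {
                "trial_id": t_id,
                "graph_index": None if tr.graph is None else int(
                    tr.graph.index
                ),
                "gamma": float(tr.gamma),
                "file": fname,
            }
        )
    manifest = {
        "format_version": _FORMAT_VERSION,
        "M": dataset.M,
        "p": dataset.p,
        "N": dataset.N,
        "trials_per_graph": dataset.trials_per_graph,
        "noise_mode": dataset.noise_mode,
        "seed": dataset.seed,
        "trials": records,
    }
    (path / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return path


def read_dataset(path) -> LabeledDataset:
    path = Path(path)
    manifest_file = path / "manifest.json"
    if not manifest_file.exists():
        raise FileNotFoundError(f"no manifest.json under {path}")
    manifest = json.loads(manifest_file.read_text())
    M, p, N = manifest["M"], manifest["p"], manifest["N"]
    n_free = M * (M - 1)
    trials = []
    for rec in manifest["trials"]:
        f = path / rec["file"]
        if not f.exists():
            raise FileNotFoundError(f"trial file missing: {f}")
        X = np.loadtxt(f, delimiter="\t", ndmin=2)
        if X.shape != (N, M):
            raise ValueError(
                f"{f}: expected shape ({N}, {M}), got {X.shape}"
            )
        gi = rec["graph_index"]
        if gi is not None and not 0 <= gi < 2**n_free:
            raise ValueError(f"{f}: graph index {gi} out of range")
        trials.append(
            TrialRecord(
                X=X,
                graph=None if gi is None else index_to_graph(gi, M),
                gamma=rec["gamma"],
                seed=manifest["seed"],
                meta={"trial_id": rec["trial_id"]},
            )
        )
    return LabeledDataset(
        trials=trials,
        M=M,
        p=p,
        N=N,
        trials_per_graph=manifest["trials_per_graph"],
        noise_mode=manifest["noise_mode"],
        seed=manifest["seed"],
    )


def write_features(path, matrix, labels, names, config: dict) -> Path:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    header = "\t".join(names)
    np.savetxt(path / "features.tsv", matrix, fmt="%.17g", delimiter="\t",
               header=header, comments="")
    sidecar = {"config": config,
               "labels": None if labels is None else
               [int(v) for v in labels]}
    (path / "features.json").write_text(json.dumps(sidecar))
    return path


def read_features(path):
    path = Path(path)
    with open(path / "features.tsv") as fh:
        names = fh.readline().rstrip("\n").split("\t")
    matrix = np.loadtxt(path / "features.tsv", delimiter="\t", skiprows=1,
                        ndmin=2)
    sidecar = json.loads((path / "features.json").read_text())
    labels = sidecar["labels"]
    labels = None if labels is None else np.asarray(labels, dtype=int)
    return matrix, labels, names, sidecar["config"]


# ---------------------------------------------------------------------------
# model serialisation


def _lr_to_dict(lr) -> dict:
    return {
        "coef": lr.coef_.tolist(),
        "intercept": lr.intercept_.tolist(),
        "classes": lr.classes_.tolist(),
        "n_iter": np.atleast_1d(lr.n_iter_).tolist(),
    }


def _lr_from_dict(d, params: dict):
    from sklearn.linear_model import LogisticRegression

    lr = LogisticRegression(**params)
    lr.coef_ = np.asarray(d["coef"], dtype=float)
    lr.intercept_ = np.asarray(d["intercept"], dtype=float)
    lr.classes_ = np.asarray(d["classes"])
    lr.n_iter_ = np.asarray(d["n_iter"])
    return lr


def save_model(model, path) -> Path:
    path = Path(path)
    common = {
        "format_version": _FORMAT_VERSION,
        "params": model.get_params(),
        "scaler_mean": model.scaler_.mean_.tolist(),
        "scaler_scale": model.scaler_.scale_.tolist(),
        "n_features_in": int(model.n_features_in_),
        "classes": np.asarray(model.classes_).tolist(),
    }
    if isinstance(model, CellBasedGraphClassifier):
        cells = {}
        for (i, j), m in model.models_.items():
            if isinstance(m, _ConstantCell):
                cells[f"{i},{j}"] = {"constant": m.value}
            else:
                cells[f"{i},{j}"] = _lr_to_dict(m)
        payload = {"schema": "cbc", "cells": cells, **common}
    elif isinstance(model, MatrixBasedGraphClassifier):
        payload = {"schema": "mbc", "model": _lr_to_dict(model.model_), **common}
    else:
        raise TypeError(f"cannot serialise {type(model).__name__}")
    path.write_text(json.dumps(payload))
    return path


def load_model(path):
    from sklearn.preprocessing import StandardScaler

    payload = json.loads(Path(path).read_text())
    cls = {"cbc": CellBasedGraphClassifier, "mbc": MatrixBasedGraphClassifier}[
        payload["schema"]
    ]
    model = cls(**payload["params"])
    scaler = StandardScaler()
    scaler.mean_ = np.asarray(payload["scaler_mean"], dtype=float)
    scaler.scale_ = np.asarray(payload["scaler_scale"], dtype=float)
    scaler.var_ = scaler.scale_**2
    scaler.n_features_in_ = len(scaler.mean_)
    model.scaler_ = scaler
    model.n_features_in_ = payload["n_features_in"]
    model.classes_ = np.asarray(payload["classes"])
    lr_params = dict(
        C=model.C,
        solver="lbfgs",
        max_iter=model.max_iter,
        tol=model.tol,
        random_state=model.random_state,
    )
    from .simulate import offdiag_pairs

    if payload["schema"] == "cbc":
        model.pairs_ = offdiag_pairs(model.n_channels)
        model.models_ = {}
        for key, d in payload["cells"].items():
            i, j = (int(v) for v in key.split(","))
            if "constant" in d:
                model.models_[(i, j)] = _ConstantCell(d["constant"])
            else:
                model.models_[(i, j)] = _lr_from_dict(d, lr_params)
    else:
        model.model_ = _lr_from_dict(payload["model"], lr_params)
        pairs = offdiag_pairs(model.n_channels)
        model.pairs_ = pairs
        model._membership_ = np.stack(
            [
                [index_to_graph(int(k), model.n_channels).entries[i, j]
                 for (i, j) in pairs]
                for k in model.classes_
            ]
        ).astype(float)
    return model


# ---------------------------------------------------------------------------
# run configuration


_CONFIG_FIELDS = {
    "M": 3,
    "p": 10,
    "N": 1500,
    "trials_per_graph": 100,
    "noise_mode": "uniform",
    "mode": "complete",
    "engineered": True,
    "method": "cbc",
    "reg_strength": 1.0,
    "threshold": 0.75,
    "folds": 5,
    "seed": 0,
}


@dataclasses.dataclass
class RunConfig:
    """Validated flat configuration for a full pipeline run."""

    M: int = 3
    p: int = 10
    N: int = 1500
    trials_per_graph: int = 100
    noise_mode: str = "uniform"
    mode: str = "complete"
    engineered: bool = True
    method: str = "cbc"
    reg_strength: float = 1.0
    threshold: float = 0.75
    folds: int = 5
    seed: int = 0

    def __post_init__(self):
        if self.M < 1 or self.p < 1 or self.N <= self.p:
            raise ValueError("require M >= 1, p >= 1, N > p")
        if self.noise_mode not in ("none", "uniform"):
            raise ValueError(f"unknown noise_mode {self.noise_mode!r}")
        if self.mode not in ("complete", "pw", "c-pw"):
            raise ValueError(f"unknown feature mode {self.mode!r}")
        if self.method not in ("cbc", "mbc", "gca"):
            raise ValueError(f"unknown method {self.method!r}")
        if not 0.0 <= self.threshold <= 1.0:
            raise ValueError("threshold must lie in [0, 1]")

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        data = json.loads(Path(path).read_text())
        unknown = set(data) - set(_CONFIG_FIELDS)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def fingerprint(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]
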
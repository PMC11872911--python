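"""Portable model checkpoints (npz archive: config + weights + training pool)."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from ._nn import GraphConvNet
from .classifier import WCSGNetClassifier
from .wcsn import CellNetwork


def save_checkpoint(path: str | Path, clf: WCSGNetClassifier, hvg_ids: list[str]) -> None:
    arrays: dict[str, np.ndarray] = {}
    for j, model in enumerate(clf.models_):
        for k, v in model.params.items():
            arrays[f"m{j}__param__{k}"] = v
        for k, v in model.running.items():
            arrays[f"m{j}__running__{k}"] = v
    arrays["train_E0"] = clf._train_E0
    for i, net in enumerate(clf.train_networks_):
        arrays[f"net{i}__u"] = net.u
        arrays[f"net{i}__v"] = net.v
        arrays[f"net{i}__w"] = net.weight
    meta = {
        "params": clf.get_params(),
        "classes": clf.classes_.tolist(),
        "hvg_ids": list(hvg_ids),
        "n_networks": len(clf.train_networks_),
        "n_models": len(clf.models_),
        "p": clf.n_features_in_,
    }
    arrays["meta_json"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
    np.savez_compressed(path, **arrays)


def load_checkpoint(path: str | Path) -> tuple[WCSGNetClassifier, list[str]]:
    data = np.load(path, allow_pickle=False)
    meta = json.loads(bytes(data["meta_json"]).decode())
    p = meta["p"]
    params = meta["params"]
    clf = WCSGNetClassifier(**params)
    clf.classes_ = np.asarray(meta["classes"])
    clf.n_features_in_ = p
    clf._train_E0 = data["train_E0"]
    clf.train_networks_ = [
        CellNetwork(
            cell_index=i,
            u=data[f"net{i}__u"],
            v=data[f"net{i}__v"],
            weight=data[f"net{i}__w"],
            p=p,
            weight_mode=params["weight_mode"],
        )
        for i in range(meta["n_networks"])
    ]
    clf.models_ = []
    for j in range(meta["n_models"]):
        model = GraphConvNet(
            p=p,
            n_classes=len(meta["classes"]),
            embed_dim=params["embed_dim"],
            conv_channels=tuple(params["conv_channels"]),
            mlp_hidden=tuple(params["mlp_hidden"]),
            dropout=params["dropout_rate"],
            seed=params["random_state"],
        )
        model.load_state_dict(
            {
                "params": {
                    k.split("__", 2)[2]: data[k]
                    for k in data.files
                    if k.startswith(f"m{j}__param__")
                },
                "running": {
                    k.split("__", 2)[2]: data[k]
                    for k in data.files
                    if k.startswith(f"m{j}__running__")
                },
            }
        )
        clf.models_.append(model)
    clf.loss_histories_ = []
    clf.loss_history_ = []
    return clf, meta["hvg_ids"]
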
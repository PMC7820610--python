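"""Single-file model checkpoints: config + weights + schema version (.npz)."""

from __future__ import annotations

import dataclasses
import json

import numpy as np

from .ann import ANNConfig, ANNModel
from .classifier import build_classifier
from .network import BatchNorm3D, Conv3D, DCNNConfig, Dense, SequentialModel, build_dcnn

SCHEMA_VERSION = 1


def _config_json(cfg) -> str:
    return json.dumps(dataclasses.asdict(cfg))


def save_dcnn(model: SequentialModel, path: str) -> None:
    arrays: dict[str, np.ndarray] = {}
    for i, layer in enumerate(model.layers):
        if isinstance(layer, (Conv3D, Dense)):
            arrays[f"layer{i}_w"] = layer.w.value
            arrays[f"layer{i}_b"] = layer.b.value
        elif isinstance(layer, BatchNorm3D):
            arrays[f"layer{i}_gamma"] = layer.gamma.value
            arrays[f"layer{i}_beta"] = layer.beta.value
            arrays[f"layer{i}_rmean"] = layer.running_mean
            arrays[f"layer{i}_rvar"] = layer.running_var
    np.savez(
        path,
        schema=np.array([SCHEMA_VERSION]),
        kind=np.array(["dcnn"]),
        config=np.array([_config_json(model.cfg)]),
        trained=np.array([int(model.trained)]),
        **arrays,
    )


def load_dcnn(path: str) -> SequentialModel:
    with np.load(path, allow_pickle=False) as data:
        if int(data["schema"][0]) != SCHEMA_VERSION:
            raise ValueError(f"unsupported checkpoint schema {data['schema'][0]}")
        raw = json.loads(str(data["config"][0]))
        for key in ("conv_channels", "input_dims"):
            raw[key] = tuple(raw[key])
        raw["pool_windows"] = tuple(tuple(w) if w is not None else None for w in raw["pool_windows"])
        cfg = DCNNConfig(**raw)
        model = build_classifier(cfg) if cfg.n_outputs == 2 else build_dcnn(cfg)
        for i, layer in enumerate(model.layers):
            if isinstance(layer, (Conv3D, Dense)):
                layer.w.value = data[f"layer{i}_w"]
                layer.b.value = data[f"layer{i}_b"]
            elif isinstance(layer, BatchNorm3D):
                layer.gamma.value = data[f"layer{i}_gamma"]
                layer.beta.value = data[f"layer{i}_beta"]
                layer.running_mean = data[f"layer{i}_rmean"]
                layer.running_var = data[f"layer{i}_rvar"]
        model.trained = bool(int(data["trained"][0]))
    return model


def save_ann(model: ANNModel, path: str) -> None:
    np.savez(
        path,
        schema=np.array([SCHEMA_VERSION]),
        kind=np.array(["ann"]),
        config=np.array([_config_json(model.cfg)]),
        w1=model.w1,
        w2=model.w2,
        x_mean=model.x_mean,
        x_std=model.x_std,
        t_mean=model.t_mean,
        t_std=model.t_std,
    )


def load_ann(path: str) -> ANNModel:
    with np.load(path, allow_pickle=False) as data:
        if int(data["schema"][0]) != SCHEMA_VERSION:
            raise ValueError(f"unsupported checkpoint schema {data['schema'][0]}")
        cfg = ANNConfig(**json.loads(str(data["config"][0])))
        return ANNModel(
            data["w1"], data["w2"], data["x_mean"], data["x_std"],
            data["t_mean"], data["t_std"], cfg, history={},
        )
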
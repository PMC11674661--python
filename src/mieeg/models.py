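"""The five motor-imagery decoder architectures.

Three networks consume the dense 9x7x T spatial tensor (Conv2D Net,
Conv3D Net, multi-branch Conv3D) and two consume the flat channels x
time layout (EEGNet, Shallow ConvNet).  All share one contract: build a
:class:`ModelSpec`, call :func:`fit` to obtain a :class:`TrainedModel`,
and read class probabilities from :func:`predict_proba` (rows are
probability simplices).

Architectural constants that the study fixes are fixed here too: the
Conv2D Net stacks 32/64/128 kernels of 3x3x(depth) and collapses the
whole time axis in its first layer; the Conv3D Net uses 32 kernels of
(1,1,30) then twice (2,2,40) with batch-norm + ELU between convolutions
and two 32-unit dense layers; EEGNet's first temporal kernel spans half
the sampling rate.  Everything the study leaves open (optimizer, loss,
batch size, the multi-branch kernel sizes, Shallow ConvNet
hyperparameters) is a documented, configurable default: Adam with
categorical cross-entropy at batch 32; the multi-branch kernel sizes are
a reconstruction, not a published table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .containers import CLASSES

MODEL_NAMES = ("conv2d_net", "conv3d_net", "mb_conv3d", "eegnet", "shallow_convnet")

#: architectures that consume the dense 9x7 tensor
DENSE3D_MODELS = ("conv2d_net", "conv3d_net", "mb_conv3d")


@dataclass(frozen=True)
class ModelSpec:
    """Architecture description; ``build`` instantiates the network."""

    name: str
    input_kind: str            # "dense3d" | "channels_x_time"
    input_shape: tuple         # per-sample shape the network expects
    n_classes: int
    hyperparameters: dict = field(default_factory=dict)
    layer_summary: tuple = ()  # ordered (kind, detail-dict) pairs

    def conv_layers(self) -> list[dict]:
        return [d for k, d in self.layer_summary if k.startswith("conv")]

    def build(self, seed: int = 0) -> nn.Network:
        return _BUILDERS[self.name](self, np.random.default_rng(seed))


def _check_dense_input(T: int, n_classes: int):
    if T < 30:
        raise ValueError("need at least 30 timepoints")
    if n_classes < 2:
        raise ValueError("need at least 2 classes")


# ---------------------------------------------------------------------------
# specs

def build_conv2d_net(T: int, n_classes: int = len(CLASSES), **hp) -> ModelSpec:
    """2-D convolutions over the 9x7 grid with time as the channel axis.

    The first layer's 3x3xT kernels sum the whole time axis with learned
    weights, so time is collapsed after layer one.
    """
    _check_dense_input(T, n_classes)
    h = {"kernels": (32, 64, 128), "dense": (1024, 64), "lr": 1e-3, **hp}
    k1, k2, k3 = h["kernels"]
    summary = (
        ("l2norm", {}),
        ("conv2d", {"kernels": k1, "kernel_shape": (3, 3, T), "collapses_time": True}),
        ("conv2d", {"kernels": k2, "kernel_shape": (3, 3, k1)}),
        ("conv2d", {"kernels": k3, "kernel_shape": (3, 3, k2)}),
        ("flatten", {}),
        ("dense", {"units": h["dense"][0]}),
        ("dense", {"units": h["dense"][1]}),
        ("dense_softmax", {"units": n_classes}),
    )
    return ModelSpec("conv2d_net", "dense3d", (9, 7, T), n_classes, h, summary)


def build_conv3d_net(T: int, n_classes: int = len(CLASSES), **hp) -> ModelSpec:
    """3-D convolutions: 32 kernels of (1,1,30) then twice (2,2,40),
    batch-norm + ELU between convolutions, two 32-unit dense layers."""
    _check_dense_input(T, n_classes)
    h = {"kernels": 32, "kernel_shapes": ((1, 1, 30), (2, 2, 40), (2, 2, 40)),
         "dense": (32, 32), "lr": 1e-3, **hp}
    t_needed = sum(ks[2] - 1 for ks in h["kernel_shapes"]) + 1
    if T < t_needed:
        raise ValueError(f"T={T} too short for valid temporal convolutions (need >= {t_needed})")
    summary = (
        ("l2norm", {}),
        *[("conv3d", {"kernels": h["kernels"], "kernel_shape": ks, "batch_norm": True,
                      "activation": "elu"}) for ks in h["kernel_shapes"]],
        ("flatten", {}),
        ("dense", {"units": h["dense"][0]}),
        ("dense", {"units": h["dense"][1]}),
        ("dense_softmax", {"units": n_classes}),
    )
    return ModelSpec("conv3d_net", "dense3d", (9, 7, T), n_classes, h, summary)


#: reconstructed multi-branch defaults: three temporal scales, two conv
#: layers and three dense layers per branch (the last dense matches the
#: class count; branch outputs are summed before the softmax)
_MB_DEFAULT_BRANCHES = (
    {"kernels": 16, "kernel_shapes": ((1, 1, 10), (2, 2, 20)), "dense": (32, 16)},
    {"kernels": 16, "kernel_shapes": ((1, 1, 30), (2, 2, 40)), "dense": (32, 16)},
    {"kernels": 16, "kernel_shapes": ((1, 1, 50), (2, 2, 60)), "dense": (32, 16)},
)


def build_mb_conv3d(T: int, n_classes: int = len(CLASSES), **hp) -> ModelSpec:
    """Three parallel Conv3D branches at different temporal scales; their
    class-score outputs are added and softmaxed.  Kernel sizes are a
    documented reconstruction (configurable via ``branches``)."""
    _check_dense_input(T, n_classes)
    h = {"branches": _MB_DEFAULT_BRANCHES, "lr": 1e-3, **hp}
    t_needed = max(sum(ks[2] - 1 for ks in b["kernel_shapes"]) + 1 for b in h["branches"])
    if T < t_needed:
        raise ValueError(f"T={T} too short for valid temporal convolutions (need >= {t_needed})")
    summary = tuple(
        ("branch", {
            "conv_layers": [{"kernels": b["kernels"], "kernel_shape": ks}
                            for ks in b["kernel_shapes"]],
            "dense_layers": [*b["dense"], n_classes],
        })
        for b in h["branches"]
    ) + (("sum", {}), ("softmax", {}))
    return ModelSpec("mb_conv3d", "dense3d", (9, 7, T), n_classes, h, summary)


def build_eegnet(fs: float, n_channels: int, T: int,
                 n_classes: int = len(CLASSES), **hp) -> ModelSpec:
    """Canonical EEGNet with the first temporal kernel spanning fs/2."""
    if n_classes < 2:
        raise ValueError("need at least 2 classes")
    h = {"F1": 8, "D": 2, "F2": 16, "dropout": 0.5,
         "temporal_kernel": int(round(fs / 2)), "sep_kernel": 16,
         "pool1": 4, "pool2": 8, "lr": 1e-3, **hp}
    if T < h["pool1"] * h["pool2"]:
        raise ValueError("too few timepoints for the two pooling stages")
    summary = (
        ("conv2d", {"kernels": h["F1"], "kernel_shape": (1, h["temporal_kernel"]),
                    "temporal": True, "batch_norm": True}),
        ("depthwise_conv2d", {"kernel_shape": (n_channels, 1), "depth_multiplier": h["D"],
                              "groups_per_temporal_filter": 1, "batch_norm": True,
                              "activation": "elu", "pool": h["pool1"],
                              "dropout": h["dropout"]}),
        ("separable_conv2d", {"kernel_shape": (1, h["sep_kernel"]), "filters": h["F2"],
                              "batch_norm": True, "activation": "elu",
                              "pool": h["pool2"], "dropout": h["dropout"]}),
        ("dense_softmax", {"units": n_classes}),
    )
    return ModelSpec("eegnet", "channels_x_time", (n_channels, T), n_classes, h, summary)


def build_shallow_convnet(n_channels: int, T: int,
                          n_classes: int = len(CLASSES), **hp) -> ModelSpec:
    """Shallow ConvNet: temporal conv, spatial conv, square, mean pooling,
    log, dense softmax — a learned band-power feature extractor.
    Hyperparameters are configurable; defaults follow the original
    publication (40/40 filters, 25-sample temporal kernel, 75/15 pool)."""
    if n_classes < 2:
        raise ValueError("need at least 2 classes")
    h = {"n_filters_time": 40, "n_filters_spat": 40, "filter_time_length": 25,
         "pool_time_length": 75, "pool_time_stride": 15, "dropout": 0.5,
         "lr": 1e-3, **hp}
    t_conv = T - h["filter_time_length"] + 1
    if t_conv < h["pool_time_length"]:
        raise ValueError("too few timepoints for the pooling stage")
    summary = (
        ("conv2d", {"kernels": h["n_filters_time"],
                    "kernel_shape": (1, h["filter_time_length"]), "temporal": True}),
        ("conv2d", {"kernels": h["n_filters_spat"],
                    "kernel_shape": (n_channels, 1), "spatial": True, "batch_norm": True}),
        ("square", {}),
        ("mean_pool", {"length": h["pool_time_length"], "stride": h["pool_time_stride"]}),
        ("log", {}),
        ("dense_softmax", {"units": n_classes}),
    )
    return ModelSpec("shallow_convnet", "channels_x_time", (n_channels, T),
                     n_classes, h, summary)


def build_stub(n_classes: int = len(CLASSES), input_shape: tuple = ()) -> ModelSpec:
    """A trivial class-prior classifier for pipeline bookkeeping at zero cost."""
    return ModelSpec("stub", "any", input_shape, n_classes, {}, (("prior", {}),))


# ---------------------------------------------------------------------------
# network construction

def _net_conv2d(spec: ModelSpec, rng) -> nn.Network:
    T = spec.input_shape[2]
    k1, k2, k3 = spec.hyperparameters["kernels"]
    d1, d2 = spec.hyperparameters["dense"]
    layers = [
        nn.L2Norm(),
        nn.Conv2D(T, k1, 3, 3, rng), nn.ELU(),
        nn.Conv2D(k1, k2, 3, 3, rng), nn.ELU(),
        nn.Conv2D(k2, k3, 3, 3, rng), nn.ELU(),
        nn.Flatten(),
        nn.Dense(9 * 7 * k3, d1, rng), nn.ELU(),
        nn.Dense(d1, d2, rng), nn.ELU(),
        nn.Dense(d2, spec.n_classes, rng),
    ]
    return nn.Network(nn.Sequential(layers), spec.n_classes)


def _net_conv3d(spec: ModelSpec, rng) -> nn.Network:
    T = spec.input_shape[2]
    nk = spec.hyperparameters["kernels"]
    shapes = spec.hyperparameters["kernel_shapes"]
    d1, d2 = spec.hyperparameters["dense"]
    layers: list[nn.Layer] = [nn.L2Norm(), nn.AddChannel()]
    in_ch, t = 1, T
    for (a, b, kt) in shapes:
        layers += [nn.Conv3D(in_ch, nk, a, b, kt, rng), nn.BatchNorm(nk), nn.ELU()]
        in_ch, t = nk, t - kt + 1
    layers += [
        nn.Flatten(),
        nn.Dense(9 * 7 * t * nk, d1, rng), nn.ELU(),
        nn.Dense(d1, d2, rng), nn.ELU(),
        nn.Dense(d2, spec.n_classes, rng),
    ]
    return nn.Network(nn.Sequential(layers), spec.n_classes)


def _net_mb_conv3d(spec: ModelSpec, rng) -> nn.Network:
    T = spec.input_shape[2]
    branches = []
    for b in spec.hyperparameters["branches"]:
        nk = b["kernels"]
        layers: list[nn.Layer] = []
        in_ch, t = 1, T
        for (a, bb, kt) in b["kernel_shapes"]:
            layers += [nn.Conv3D(in_ch, nk, a, bb, kt, rng), nn.BatchNorm(nk), nn.ELU()]
            in_ch, t = nk, t - kt + 1
        d1, d2 = b["dense"]
        layers += [
            nn.Flatten(),
            nn.Dense(9 * 7 * t * nk, d1, rng), nn.ELU(),
            nn.Dense(d1, d2, rng), nn.ELU(),
            nn.Dense(d2, spec.n_classes, rng),
        ]
        branches.append(nn.Sequential(layers))
    root = nn.Sequential([nn.L2Norm(), nn.AddChannel(), nn.ParallelSum(branches)])
    return nn.Network(root, spec.n_classes)


def _net_eegnet(spec: ModelSpec, rng) -> nn.Network:
    C, T = spec.input_shape
    h = spec.hyperparameters
    f1, d, f2 = h["F1"], h["D"], h["F2"]
    t_after = (T // h["pool1"]) // h["pool2"]
    layers = [
        nn.AddChannel(),
        nn.Conv2D(1, f1, 1, h["temporal_kernel"], rng, bias=False),
        nn.BatchNorm(f1),
        nn.DepthwiseSpatialConv(C, f1, d, rng),
        nn.BatchNorm(f1 * d), nn.ELU(),
        nn.AvgPoolTime(h["pool1"], h["pool1"]),
        nn.Dropout(h["dropout"], rng),
        nn.DepthwiseTemporalConv(h["sep_kernel"], f1 * d, rng),
        nn.Conv2D(f1 * d, f2, 1, 1, rng, bias=False),
        nn.BatchNorm(f2), nn.ELU(),
        nn.AvgPoolTime(h["pool2"], h["pool2"]),
        nn.Dropout(h["dropout"], rng),
        nn.Flatten(),
        nn.Dense(f2 * t_after, spec.n_classes, rng),
    ]
    return nn.Network(nn.Sequential(layers), spec.n_classes)


def _net_shallow(spec: ModelSpec, rng) -> nn.Network:
    C, T = spec.input_shape
    h = spec.hyperparameters
    t_conv = T - h["filter_time_length"] + 1
    n_pool = (t_conv - h["pool_time_length"]) // h["pool_time_stride"] + 1
    layers = [
        nn.AddChannel(),
        nn.Conv2D(1, h["n_filters_time"], 1, h["filter_time_length"], rng,
                  padding="valid"),
        nn.Conv2D(h["n_filters_time"], h["n_filters_spat"], C, 1, rng,
                  padding="valid", bias=False),
        nn.BatchNorm(h["n_filters_spat"]),
        nn.Square(),
        nn.AvgPoolTime(h["pool_time_length"], h["pool_time_stride"]),
        nn.LogAct(),
        nn.Dropout(h["dropout"], rng),
        nn.Flatten(),
        nn.Dense(h["n_filters_spat"] * n_pool, spec.n_classes, rng),
    ]
    return nn.Network(nn.Sequential(layers), spec.n_classes)


class _PriorNet:
    """Class-frequency predictor satisfying the Network interface."""

    def __init__(self, n_classes: int):
        self.n_classes = n_classes
        self.prior = np.full(n_classes, 1.0 / n_classes)
        self.history = {"loss": [], "val_loss": [], "val_accuracy": []}

    def fit(self, x, y_idx, **kw):
        counts = np.bincount(y_idx, minlength=self.n_classes).astype(float)
        self.prior = counts / counts.sum()
        self.history["loss"].append(float(-np.sum(
            self.prior * np.log(np.maximum(self.prior, 1e-12)))))
        return self

    def predict_proba(self, x, batch_size: int = 64):
        return np.tile(self.prior, (x.shape[0], 1))

    def n_parameters(self):
        return 0

    def get_weights(self):
        return [self.prior.copy()]

    def set_weights(self, w):
        self.prior = w[0].copy()


_BUILDERS = {
    "conv2d_net": _net_conv2d,
    "conv3d_net": _net_conv3d,
    "mb_conv3d": _net_mb_conv3d,
    "eegnet": _net_eegnet,
    "shallow_convnet": _net_shallow,
    "stub": lambda spec, rng: _PriorNet(spec.n_classes),
}


def build_model(name: str, *, T: int, fs: float = 160.0, n_channels: int = 64,
                n_classes: int = len(CLASSES), **hp) -> ModelSpec:
    """Registry entry point keyed by architecture name."""
    if name == "conv2d_net":
        return build_conv2d_net(T, n_classes, **hp)
    if name == "conv3d_net":
        return build_conv3d_net(T, n_classes, **hp)
    if name == "mb_conv3d":
        return build_mb_conv3d(T, n_classes, **hp)
    if name == "eegnet":
        return build_eegnet(fs, n_channels, T, n_classes, **hp)
    if name == "shallow_convnet":
        return build_shallow_convnet(n_channels, T, n_classes, **hp)
    if name == "stub":
        return build_stub(n_classes)
    raise KeyError(f"unknown model {name!r}; choose from {MODEL_NAMES}")


# ---------------------------------------------------------------------------
# train / predict contract

@dataclass
class TrainedModel:
    spec: ModelSpec
    network: object                  # nn.Network or _PriorNet
    classes: tuple[str, ...]
    history: dict

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        _check_input(self.spec, x)
        return self.network.predict_proba(x)

    def predict(self, x: np.ndarray) -> np.ndarray:
        idx = self.predict_proba(x).argmax(axis=1)
        return np.asarray(self.classes, dtype=object)[idx].astype(str)

    def accuracy(self, x: np.ndarray, labels: np.ndarray) -> float:
        return float(np.mean(self.predict(x) == np.asarray(labels).astype(str)))

    def clone(self) -> "TrainedModel":
        net = self.spec.build(seed=0)
        net.set_weights(self.network.get_weights())
        return TrainedModel(self.spec, net, self.classes, {"loss": []})


def _check_input(spec: ModelSpec, x: np.ndarray):
    if spec.input_kind == "any":
        return
    if x.shape[1:] != tuple(spec.input_shape):
        raise ValueError(
            f"{spec.name} expects per-sample shape {tuple(spec.input_shape)}, "
            f"got {x.shape[1:]}")


def encode_labels(labels: np.ndarray, classes=None):
    labels = np.asarray(labels).astype(str)
    if classes is None:
        classes = tuple(sorted(set(labels)))
    lut = {c: i for i, c in enumerate(classes)}
    unknown = [l for l in labels if l not in lut]
    if unknown:
        raise ValueError(f"labels outside the class set: {sorted(set(unknown))}")
    return np.array([lut[l] for l in labels]), tuple(classes)


def fit(spec: ModelSpec, x: np.ndarray, labels: np.ndarray,
        val: tuple[np.ndarray, np.ndarray] | None = None,
        epochs: int = 50, batch_size: int = 32, lr: float | None = None,
        patience: int | None = None, seed: int = 0,
        classes: tuple[str, ...] | None = None,
        init_weights: list | None = None) -> TrainedModel:
    """Train a network for ``spec``; returns the fitted model with history.

    ``val`` (inputs, labels) enables early stopping with the given
    patience; ``init_weights`` warm-starts fine-tuning.
    """
    _check_input(spec, x)
    y_idx, classes = encode_labels(labels, classes)
    net = spec.build(seed=seed)
    if init_weights is not None:
        net.set_weights(init_weights)
    kw = {}
    if isinstance(net, nn.Network):
        val_enc = None
        if val is not None:
            v_idx, _ = encode_labels(val[1], classes)
            val_enc = (val[0].astype(nn.F), v_idx)
        kw = dict(epochs=epochs, batch_size=batch_size,
                  lr=lr or spec.hyperparameters.get("lr", 1e-3),
                  val=val_enc, patience=patience, seed=seed)
    net.fit(x, y_idx, **kw)
    return TrainedModel(spec, net, classes, net.history)


def predict_proba(model: TrainedModel, x: np.ndarray) -> np.ndarray:
    return model.predict_proba(x)


# ---------------------------------------------------------------------------
# persistence: npz weights + JSON spec sidecar

def save_model(model: TrainedModel, prefix) -> tuple:
    """Write ``<prefix>.npz`` (weights) and ``<prefix>.json`` (spec)."""
    import json
    from pathlib import Path

    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    weights = model.network.get_weights()
    np.savez(prefix.with_suffix(".npz"), *weights)
    sidecar = {
        "name": model.spec.name,
        "input_kind": model.spec.input_kind,
        "input_shape": list(model.spec.input_shape),
        "n_classes": model.spec.n_classes,
        "hyperparameters": _jsonable_hp(model.spec.hyperparameters),
        "classes": list(model.classes),
    }
    prefix.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))
    return prefix.with_suffix(".npz"), prefix.with_suffix(".json")


def load_model(prefix) -> TrainedModel:
    """Rebuild a TrainedModel from :func:`save_model` output."""
    import json
    from pathlib import Path

    prefix = Path(prefix)
    sidecar = json.loads(prefix.with_suffix(".json").read_text())
    spec = ModelSpec(sidecar["name"], sidecar["input_kind"],
                     tuple(sidecar["input_shape"]), sidecar["n_classes"],
                     sidecar["hyperparameters"], ())
    net = spec.build(seed=0)
    with np.load(prefix.with_suffix(".npz")) as archive:
        weights = [archive[k] for k in archive.files]
    net.set_weights(weights)
    return TrainedModel(spec, net, tuple(sidecar["classes"]), {"loss": []})


def _jsonable_hp(obj):
    if isinstance(obj, dict):
        return {k: _jsonable_hp(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable_hp(v) for v in obj]
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj
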
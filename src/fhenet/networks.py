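"""Builders and drivers for the two reference network graphs.

*sphira* is the classification topology: encrypted image ingress, a
masqueraded cross-correlation emitting one cyphertext per window, fold-sum
rotations, a polynomial activation, one dense neuron per class (each with its
own activation), decryption, and two plaintext branches — the prediction
circuit (argmax -> one-hot decode) and the loss circuit (softmax ->
categorical cross-entropy fed by the one-hot encoded label).

*constellation* is the regression topology: encrypted feature-window ingress,
a 1-D cross-correlation over time, sigmoid approximations around a dense
merge, decryption, and plaintext prediction/MSE branches — sized for
environmental time-series yield forecasting.

Automatic FHE parameterisation runs at build time: the graph is costed, the
parameter groups discovered, and the encrypt/rotation nodes configured so
that no firing can exhaust a modulus chain.

Training is plain SGD on the plaintext shadow (weights stay plaintext; only
inference is encrypted), one example per firing: forward signals seeded at
the ingress nodes, the loss and its gradient computed behind the decryption
boundary, and the gradient fired back through the ``backward`` receptors.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .autofhe import autohe, assign_parameters, parameterise_ckks
from .data import ImageDataset, YieldSeriesDataset
from .errors import ConfigError, DivergenceError, StateError
from .graph import ComputationGraph, neuronal_firing
from .layers import (ArgmaxNode, CCENode, CrossCorrelationNode, DecryptNode,
                     DenseNode, EncryptNode, GenericNode, InputNode, MSENode,
                     OneHotDecodeNode, OneHotEncodeNode, ReluApproxNode,
                     RotationNode, SigmoidApproxNode, SoftmaxNode)

__all__ = [
    "NetworkConfig", "sphira_mini_config", "constellation_mini_config",
    "build_sphira", "build_constellation",
    "train", "infer", "evaluate_classification", "predict_batch", "mape",
]


@dataclass
class NetworkConfig:
    """Everything needed to rebuild a network graph deterministically."""

    kind: str = "classification"
    input_shape: tuple[int, ...] = (8, 8)
    kernel_shape: tuple[int, ...] = (3, 3)
    stride: tuple[int, ...] = (2, 2)
    n_filters: int = 1
    n_classes: int = 2
    output_dim: int = 1
    activation: str = "relu"       # "relu" or "sigmoid" approximation
    scale_power: int = 40
    special_mult: float = 1.5
    seed: int = 0
    lr: float = 0.1
    epochs: int = 25

    def __post_init__(self):
        self.input_shape = tuple(int(d) for d in self.input_shape)
        self.kernel_shape = tuple(int(d) for d in self.kernel_shape)
        if isinstance(self.stride, int):
            self.stride = (self.stride,) * len(self.input_shape)
        self.stride = tuple(int(s) for s in self.stride)

    @property
    def window_count(self) -> int:
        """Valid window placements per filter (T_x)."""
        return int(np.prod([
            (d - k) // s + 1
            for d, k, s in zip(self.input_shape, self.kernel_shape,
                               self.stride)]))

    def validate(self) -> None:
        if self.kind not in ("classification", "regression"):
            raise ConfigError(f"unknown network kind {self.kind!r}")
        if len(self.kernel_shape) != len(self.input_shape) or \
                len(self.stride) != len(self.input_shape):
            raise ConfigError("input, kernel and stride ranks disagree")
        if any(k > d for k, d in zip(self.kernel_shape, self.input_shape)):
            raise ConfigError(
                f"kernel {self.kernel_shape} does not fit into input "
                f"{self.input_shape}")
        if any(s < 1 for s in self.stride):
            raise ConfigError("strides must be >= 1")
        if self.n_filters < 1:
            raise ConfigError("need at least one filter neuron")
        if self.activation not in ("relu", "sigmoid"):
            raise ConfigError(f"unknown activation {self.activation!r}")
        if self.kind == "classification" and self.n_classes < 2:
            raise ConfigError("classification needs at least two classes")
        if self.window_count < 1:
            raise ConfigError("no valid window placements")

    def to_dict(self) -> dict:
        return {k: (list(v) if isinstance(v, tuple) else v)
                for k, v in self.__dict__.items()}

    @classmethod
    def from_dict(cls, d: dict) -> "NetworkConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)


def sphira_mini_config(**overrides) -> NetworkConfig:
    """Desk-scale classification defaults: 8x8 images, two classes."""
    cfg = dict(kind="classification", input_shape=(8, 8),
               kernel_shape=(3, 3), stride=(2, 2), n_classes=2,
               activation="relu", lr=0.1, epochs=25)
    cfg.update(overrides)
    return NetworkConfig(**cfg)


def constellation_mini_config(T_x: int = 14, n_features: int = 12,
                              **overrides) -> NetworkConfig:
    """Desk-scale regression defaults: 14-day windows of 12 features."""
    cfg = dict(kind="regression", input_shape=(T_x, n_features),
               kernel_shape=(3, n_features), stride=(2, 1),
               activation="sigmoid", lr=0.1, epochs=30)
    cfg.update(overrides)
    return NetworkConfig(**cfg)


def _seed_stream(seed: int):
    ss = np.random.SeedSequence(seed)
    while True:
        ss, child = ss.spawn(2)
        yield int(child.generate_state(1)[0] % (2 ** 31))


def _activation_node(cfg: NetworkConfig):
    if cfg.activation == "relu":
        return ReluApproxNode()
    return SigmoidApproxNode()


def _parameteriser(cfg: NetworkConfig):
    return lambda c: parameterise_ckks(c, cfg.scale_power, cfg.special_mult)


def build_sphira(cfg: NetworkConfig) -> ComputationGraph:
    """Build and auto-parameterise the classification graph."""
    cfg.validate()
    if cfg.kind != "classification":
        raise ConfigError("sphira is the classification topology")
    seeds = _seed_stream(cfg.seed)
    g = ComputationGraph()
    g.add_node("x", InputNode("flatten"))
    g.add_node("x_enc", EncryptNode())
    g.add_edge("x", "x_enc")

    fold_names: list[str] = []
    for f in range(cfg.n_filters):
        cc = f"cc{f}"
        g.add_node(cc, CrossCorrelationNode(
            cfg.input_shape, cfg.kernel_shape, cfg.stride, seed=next(seeds)))
        g.add_edge("x_enc", cc)
        for t in range(cfg.window_count):
            name = f"fold{f}_{t}"
            g.add_node(name, RotationNode("fold"))
            g.add_edge(cc, name)
            fold_names.append(name)

    g.add_node("act_cc", _activation_node(cfg))
    for name in fold_names:
        g.add_edge(name, "act_cc")

    for k in range(cfg.n_classes):
        g.add_node(f"dense_{k}", DenseNode(len(fold_names), seed=next(seeds)))
        g.add_edge("act_cc", f"dense_{k}")
        g.add_node(f"act_d{k}", _activation_node(cfg))
        g.add_edge(f"dense_{k}", f"act_d{k}")
        g.add_node(f"dec_{k}", DecryptNode())
        g.add_edge(f"act_d{k}", f"dec_{k}")

    # loss circuit (plaintext, behind the decryption boundary)
    g.add_node("softmax", SoftmaxNode())
    for k in range(cfg.n_classes):
        g.add_edge(f"dec_{k}", "softmax")
    g.add_node("cce", CCENode())
    g.add_edge("softmax", "cce")
    g.add_node("y", InputNode())
    g.add_node("y_onehot", OneHotEncodeNode(cfg.n_classes))
    g.add_edge("y", "y_onehot", receptors=("forward",))
    g.add_edge("y_onehot", "cce", receptors=("forward",))

    # prediction circuit (output only: no backpropagation from this branch)
    g.add_node("argmax", ArgmaxNode())
    for k in range(cfg.n_classes):
        g.add_edge(f"dec_{k}", "argmax", receptors=("forward",))
    g.add_node("prediction", OneHotDecodeNode())
    g.add_edge("argmax", "prediction", receptors=("forward",))

    groups = autohe(g, ["x_enc"])
    assignment = assign_parameters(g, groups, _parameteriser(cfg))
    g.meta.update(kind="classification", config=cfg, loss_node="cce",
                  x_node="x", y_node="y", prediction_node="prediction",
                  groups=groups, fhe_assignment=assignment, trained=False)
    return g


def build_constellation(cfg: NetworkConfig) -> ComputationGraph:
    """Build and auto-parameterise the regression graph."""
    cfg.validate()
    if cfg.kind != "regression":
        raise ConfigError("constellation is the regression topology")
    if cfg.kernel_shape[1:] != cfg.input_shape[1:]:
        raise ConfigError(
            "the 1-D kernel must span the full feature axis")
    seeds = _seed_stream(cfg.seed)
    g = ComputationGraph()
    g.add_node("x", InputNode("flatten"))
    g.add_node("x_enc", EncryptNode())
    g.add_edge("x", "x_enc")

    fold_names: list[str] = []
    for f in range(cfg.n_filters):
        cc = f"cc{f}"
        g.add_node(cc, CrossCorrelationNode(
            cfg.input_shape, cfg.kernel_shape, cfg.stride, seed=next(seeds)))
        g.add_edge("x_enc", cc)
        for t in range(cfg.window_count):
            name = f"fold{f}_{t}"
            g.add_node(name, RotationNode("fold"))
            g.add_edge(cc, name)
            fold_names.append(name)

    g.add_node("act_cc", SigmoidApproxNode())
    for name in fold_names:
        g.add_edge(name, "act_cc")
    g.add_node("dense", DenseNode(len(fold_names), seed=next(seeds)))
    g.add_edge("act_cc", "dense")
    g.add_node("act_out", SigmoidApproxNode())
    g.add_edge("dense", "act_out")
    g.add_node("dec", DecryptNode())
    g.add_edge("act_out", "dec")

    g.add_node("prediction", GenericNode())
    g.add_edge("dec", "prediction", receptors=("forward",))
    g.add_node("mse", MSENode())
    g.add_edge("dec", "mse")
    g.add_node("y", InputNode())
    g.add_edge("y", "mse", receptors=("forward",))

    groups = autohe(g, ["x_enc"])
    assignment = assign_parameters(g, groups, _parameteriser(cfg))
    g.meta.update(kind="regression", config=cfg, loss_node="mse",
                  x_node="x", y_node="y", prediction_node="prediction",
                  groups=groups, fhe_assignment=assignment, trained=False)
    return g


# ---------------------------------------------------------------------------
# Drivers
# ---------------------------------------------------------------------------

def _set_training(g: ComputationGraph, flag: bool) -> None:
    for rec in g.records():
        if hasattr(rec.node, "training"):
            rec.node.training = flag


def _set_encryption(g: ComputationGraph, flag: bool) -> None:
    for rec in g.records():
        if isinstance(rec.node, EncryptNode):
            rec.node.enabled = flag


def _examples(dataset):
    if isinstance(dataset, ImageDataset):
        return dataset.images, dataset.labels
    if isinstance(dataset, YieldSeriesDataset):
        return dataset.windows, dataset.targets
    raise TypeError(f"unsupported dataset type {type(dataset).__name__}")


def train(g: ComputationGraph, dataset, cfg: NetworkConfig | None = None,
          epochs: int | None = None, stop_accuracy: float | None = None
          ) -> dict:
    """Per-example SGD over the plaintext shadow of the graph.

    Returns the history: mean loss per epoch plus training accuracy
    (classification) or training MAPE (regression).  ``stop_accuracy``
    short-circuits classification training once reached.
    """
    cfg = cfg or g.meta["config"]
    kind = g.meta["kind"]
    epochs = epochs if epochs is not None else cfg.epochs
    xs, ys = _examples(dataset)
    if kind == "regression":
        # squash targets into the activation's comfortable output range
        scale = 2.0 * float(np.max(np.abs(ys)))
        g.meta["target_scale"] = scale
    rng = np.random.default_rng(cfg.seed)
    _set_training(g, True)
    _set_encryption(g, False)
    loss_node = g.meta["loss_node"]
    history: dict = {"loss": []}
    history["accuracy" if kind == "classification" else "mape"] = []

    for _epoch in range(epochs):
        order = rng.permutation(len(ys))
        losses = []
        correct = 0
        preds = []
        for i in order:
            g.clear_signals()
            target = ys[i] if kind == "classification" \
                else ys[i] / g.meta["target_scale"]
            neuronal_firing(g, [g.meta["x_node"], g.meta["y_node"]],
                            [xs[i], target], ["forward", "forward"])
            loss = g.node(loss_node).node.last_loss
            if loss is None or not math.isfinite(loss):
                raise DivergenceError(
                    f"non-finite loss at example {i} (seed={cfg.seed}, "
                    f"lr={cfg.lr}, activation={cfg.activation})")
            losses.append(loss)
            out = g.node(g.meta["prediction_node"]).meta.get("output")
            if kind == "classification":
                correct += int(out == ys[i])
            else:
                preds.append((i, float(np.asarray(out).ravel()[0])
                              * g.meta["target_scale"]))
            neuronal_firing(g, [loss_node], [1.0], ["backward"])
            for rec in g.records():
                rec.node.apply_gradients(cfg.lr)
        history["loss"].append(float(np.mean(losses)))
        if kind == "classification":
            acc = correct / len(ys)
            history["accuracy"].append(acc)
            if stop_accuracy is not None and acc >= stop_accuracy:
                break
        else:
            idx, vals = zip(*preds)
            history["mape"].append(
                mape(ys[np.asarray(idx)], np.asarray(vals)))
    _set_training(g, False)
    g.meta["trained"] = True
    return history


def infer(g: ComputationGraph, x, encrypted: bool = False,
          allow_unfitted: bool = False):
    """Predict a class (classification) or value (regression) for ``x``.

    Cyphertext and plaintext inputs follow the identical graph: with
    ``encrypted=True`` the ingress encrypt node packs the example under its
    group parameters and the decrypt nodes recover the activations at the
    plaintext boundary.
    """
    if not g.meta.get("trained") and not allow_unfitted:
        raise StateError("graph has not been trained; pass "
                         "allow_unfitted=True to run an untrained network")
    _set_training(g, False)
    _set_encryption(g, encrypted)
    g.clear_signals()
    neuronal_firing(g, [g.meta["x_node"]], [x], ["forward"])
    out = g.node(g.meta["prediction_node"]).meta["output"]
    if g.meta["kind"] == "classification":
        return int(out)
    return float(np.asarray(out).ravel()[0]) * g.meta.get("target_scale", 1.0)


def evaluate_classification(g: ComputationGraph, dataset: ImageDataset,
                            encrypted: bool = False,
                            allow_unfitted: bool = False) -> float:
    """Fraction of examples whose decoded argmax matches the label."""
    hits = sum(
        infer(g, img, encrypted=encrypted, allow_unfitted=allow_unfitted)
        == int(lab)
        for img, lab in zip(dataset.images, dataset.labels))
    return hits / len(dataset)


def predict_batch(g: ComputationGraph, dataset, encrypted: bool = False,
                  allow_unfitted: bool = False) -> np.ndarray:
    """Predictions for every example of a dataset, in order."""
    xs, _ = _examples(dataset)
    return np.asarray([
        infer(g, x, encrypted=encrypted, allow_unfitted=allow_unfitted)
        for x in xs])


def mape(y, yhat) -> float:
    """Mean absolute percentage error, 100 * mean(|y - yhat| / |y|)."""
    y = np.asarray(y, dtype=np.float64)
    yhat = np.asarray(yhat, dtype=np.float64)
    if y.shape != yhat.shape:
        raise ValueError(f"shape mismatch: {y.shape} vs {yhat.shape}")
    if np.any(y == 0):
        raise ValueError("MAPE is undefined for zero targets")
    return float(100.0 * np.mean(np.abs(y - yhat) / np.abs(y)))
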
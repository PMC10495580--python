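"""The five QC classifiers.

* ``RF`` — random forest on the raw 850-point normalized spectrum
  (200 trees, per-split feature subsample of floor(sqrt(850)) = 29 by
  default; 30 is selectable through :class:`ModelSpec`).
* ``CNN`` — six (conv -> ReLU -> max-pool) blocks followed by two fully
  connected layers, the second 64 wide, and a 2-way softmax output.
* ``ICNN`` — two conv/pool blocks, two inception modules (parallel
  kernel-1/3/5 branches plus a pooled branch) each followed by max pooling,
  then the same two fully connected layers and softmax head.
* ``CNN+RF`` / ``ICNN+RF`` — hybrids: the trained network's 64-node
  penultimate activations are forwarded as features to a random forest
  (feature subsample floor(sqrt(64)) = 8) which makes the final call.

Class 1 ("good") is the positive class everywhere.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass, field

import joblib
import numpy as np
from sklearn.ensemble import RandomForestClassifier

from . import _nn
from ._nn import Adam, Conv1d, Dense, Flatten, Inception1d, MaxPool1d, ReLU, Sequential

__all__ = [
    "ModelSpec",
    "RFModel",
    "NetworkModel",
    "HybridModel",
    "build_model",
    "build_hybrid",
    "predict_proba",
    "extract_penultimate_features",
    "save_model",
    "load_model",
    "GOOD_CLASS",
]

MODEL_KINDS = ("RF", "CNN", "ICNN", "CNN+RF", "ICNN+RF")
NETWORK_KINDS = ("CNN", "ICNN")
HYBRID_KINDS = ("CNN+RF", "ICNN+RF")

#: index of the positive ("good") class in probability outputs
GOOD_CLASS = 1


@dataclass(frozen=True)
class ModelSpec:
    """Architecture hyperparameters; defaults follow the published design."""

    kind: str = "CNN"
    input_length: int = 850
    n_classes: int = 2
    # random forest
    rf_n_estimators: int = 200
    rf_max_features: int | None = None  # default: floor(sqrt(n_features))
    # CNN
    cnn_conv_layers: int = 6
    conv_kernel: int = 5
    pool_size: int = 2
    base_channels: int = 16  # doubled per conv block: 16 -> 512 over 6 blocks
    # ICNN
    icnn_conv_layers: int = 2
    icnn_inception_modules: int = 2
    inception_branch_channels: int = 16
    # fully connected head (shared by CNN and ICNN)
    fc_layers: int = 2
    fc1_width: int = 256
    penultimate_width: int = 64

    def __post_init__(self) -> None:
        if self.kind not in MODEL_KINDS:
            raise ValueError(f"unknown model kind {self.kind!r}; choose from {MODEL_KINDS}")
        if self.input_length < 2 or self.n_classes != 2:
            raise ValueError("inconsistent spec: need input_length >= 2 and 2 classes")
        if self.kind != "RF" and self.penultimate_width != 64:
            raise ValueError("network kinds use a 64-node penultimate layer")

    def resolve_rf_max_features(self, n_features: int) -> int:
        if self.rf_max_features is not None:
            return self.rf_max_features
        return int(math.floor(math.sqrt(n_features)))


def _check_input(X: np.ndarray, input_length: int) -> np.ndarray:
    X = np.asarray(X, dtype=np.float32)
    if X.ndim == 1:
        X = X[None, :]
    if X.ndim != 2 or X.shape[1] != input_length:
        raise ValueError(
            f"expected spectra of length {input_length}, got shape {tuple(X.shape)}"
        )
    return X


class RFModel:
    """Random forest on raw spectra (or on hybrid deep features)."""

    def __init__(self, spec: ModelSpec, seed: int = 0, n_features: int | None = None):
        self.spec = spec
        self.seed = seed
        self.n_features = n_features if n_features is not None else spec.input_length
        self.forest = RandomForestClassifier(
            n_estimators=spec.rf_n_estimators,
            max_features=spec.resolve_rf_max_features(self.n_features),
            random_state=seed,
            n_jobs=1,
        )
        self.trained = False

    def fit(self, X: np.ndarray, y: np.ndarray) -> "RFModel":
        X = _check_input(X, self.n_features)
        y = np.asarray(y)
        if np.unique(y).size < 2:
            raise ValueError("training labels contain a single class")
        self.forest.fit(X, y)
        self.trained = True
        return self

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        if not self.trained:
            raise RuntimeError("model must be fitted before prediction")
        X = _check_input(X, self.n_features)
        proba = self.forest.predict_proba(X)
        # sklearn orders columns by sorted class label (0=bad, 1=good)
        return proba

    def layer_census(self) -> dict:
        return {
            "kind": self.spec.kind,
            "n_trees": self.forest.n_estimators,
            "max_features_per_split": self.forest.max_features,
        }


def _build_cnn(spec: ModelSpec, rng: np.random.Generator) -> Sequential:
    layers: list[_nn.Layer] = []
    in_c, length = 1, spec.input_length
    ch = spec.base_channels
    for _ in range(spec.cnn_conv_layers):
        layers += [Conv1d(in_c, ch, spec.conv_kernel, rng), ReLU(), MaxPool1d(spec.pool_size)]
        in_c, ch = ch, ch * 2
        length //= spec.pool_size
    layers += [
        Flatten(),
        Dense(in_c * length, spec.fc1_width, rng),
        ReLU(),
        Dense(spec.fc1_width, spec.penultimate_width, rng),
        ReLU(),
        Dense(spec.penultimate_width, spec.n_classes, rng),
    ]
    return Sequential(layers)


def _build_icnn(spec: ModelSpec, rng: np.random.Generator) -> Sequential:
    layers: list[_nn.Layer] = []
    in_c, length = 1, spec.input_length
    ch = spec.base_channels
    for _ in range(spec.icnn_conv_layers):
        layers += [Conv1d(in_c, ch, spec.conv_kernel, rng), ReLU(), MaxPool1d(spec.pool_size)]
        in_c, ch = ch, ch * 2
        length //= spec.pool_size
    for _ in range(spec.icnn_inception_modules):
        inc = Inception1d(in_c, spec.inception_branch_channels, rng)
        layers += [inc, MaxPool1d(spec.pool_size)]
        in_c = inc.out_channels
        length //= spec.pool_size
    layers += [
        Flatten(),
        Dense(in_c * length, spec.fc1_width, rng),
        ReLU(),
        Dense(spec.fc1_width, spec.penultimate_width, rng),
        ReLU(),
        Dense(spec.penultimate_width, spec.n_classes, rng),
    ]
    return Sequential(layers)


class NetworkModel:
    """CNN or ICNN with a softmax head; trained by ``training.train_network``."""

    def __init__(self, spec: ModelSpec, seed: int = 0):
        if spec.kind not in NETWORK_KINDS:
            raise ValueError(f"NetworkModel requires kind CNN or ICNN, got {spec.kind}")
        self.spec = spec
        self.seed = seed
        rng = np.random.default_rng(seed)
        self.net = _build_cnn(spec, rng) if spec.kind == "CNN" else _build_icnn(spec, rng)
        self.trained = False
        self._batch = 256

    # -- inference --------------------------------------------------------------

    def _batched(self, X: np.ndarray, fn) -> np.ndarray:
        outs = [fn(X[i : i + self._batch, None, :]) for i in range(0, X.shape[0], self._batch)]
        return np.concatenate(outs, axis=0)

    def logits(self, X: np.ndarray) -> np.ndarray:
        X = _check_input(X, self.spec.input_length)
        return self._batched(X, self.net.forward)

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        if not self.trained:
            raise RuntimeError("model must be fitted before prediction")
        return _nn.softmax(self.logits(X).astype(np.float64))

    def extract_penultimate_features(self, X: np.ndarray) -> np.ndarray:
        """Activations of the 64-node layer feeding the output layer."""
        if not self.trained:
            raise RuntimeError("model must be fitted before feature extraction")
        X = _check_input(X, self.spec.input_length)
        stop = len(self.net.layers) - 1  # everything except the output Dense
        return self._batched(X, lambda xb: self.net.forward_until(xb, stop))

    def output_layer_proba(self, features: np.ndarray) -> np.ndarray:
        """Softmax probabilities computed from penultimate features only."""
        logits = self.net.layers[-1].forward(np.asarray(features, dtype=np.float32))
        return _nn.softmax(logits.astype(np.float64))

    def class_score_input_grad(self, X: np.ndarray, class_idx: np.ndarray) -> np.ndarray:
        """Gradient of the softmax probability of ``class_idx`` w.r.t. the input."""
        X = _check_input(X, self.spec.input_length)
        class_idx = np.broadcast_to(np.asarray(class_idx), (X.shape[0],))
        grads = []
        for i in range(0, X.shape[0], self._batch):
            xb = X[i : i + self._batch, None, :]
            cb = class_idx[i : i + self._batch]
            logits = self.net.forward(xb)
            p = _nn.softmax(logits.astype(np.float64))
            n = p.shape[0]
            pc = p[np.arange(n), cb][:, None]
            dlogits = -pc * p
            dlogits[np.arange(n), cb] += pc[:, 0]
            grads.append(self.net.backward(dlogits.astype(np.float32))[:, 0, :])
        return np.concatenate(grads, axis=0).astype(np.float64)

    # -- introspection ----------------------------------------------------------

    def layer_census(self) -> dict:
        conv = sum(isinstance(l, Conv1d) for l in self.net.layers)
        inception = sum(isinstance(l, Inception1d) for l in self.net.layers)
        dense = [l for l in self.net.layers if isinstance(l, Dense)]
        return {
            "kind": self.spec.kind,
            "conv_layers": conv,
            "inception_modules": inception,
            "fc_layers": len(dense) - 1,  # excluding the output layer
            "penultimate_width": dense[-1].W.shape[0],
            "output_width": dense[-1].W.shape[1],
        }


class HybridModel:
    """A trained network feeding its 64-node features to a random forest."""

    def __init__(self, network: NetworkModel, forest: RFModel):
        self.network = network
        self.forest = forest
        self.spec = network.spec
        self.trained = forest.trained

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        feats = self.network.extract_penultimate_features(X)
        return self.forest.predict_proba(feats)

    def layer_census(self) -> dict:
        census = self.network.layer_census()
        census.update(
            kind=f"{self.network.spec.kind}+RF",
            n_trees=self.forest.forest.n_estimators,
            rf_input_features=self.forest.n_features,
            max_features_per_split=self.forest.forest.max_features,
        )
        return census


def build_model(spec: ModelSpec, seed: int = 0):
    """Construct an untrained model of the requested kind.

    Hybrid kinds cannot be built directly from scratch — they require a
    trained network first (see :func:`build_hybrid`).
    """
    if spec.kind == "RF":
        return RFModel(spec, seed=seed)
    if spec.kind in NETWORK_KINDS:
        return NetworkModel(spec, seed=seed)
    raise ValueError(
        f"{spec.kind} is a hybrid: train a {spec.kind.split('+')[0]} first and call build_hybrid"
    )


def build_hybrid(
    trained_net: NetworkModel,
    rf_spec: ModelSpec,
    train_spectra: np.ndarray,
    train_labels: np.ndarray,
    seed: int = 0,
) -> HybridModel:
    """Fit the hybrid: RF on the trained network's penultimate features."""
    if not trained_net.trained:
        raise RuntimeError("hybrid requires a trained network")
    feats = trained_net.extract_penultimate_features(train_spectra)
    forest = RFModel(rf_spec, seed=seed, n_features=feats.shape[1])
    forest.fit(feats, train_labels)
    return HybridModel(trained_net, forest)


# -- module-level conveniences ---------------------------------------------------


def predict_proba(model, spectra: np.ndarray) -> np.ndarray:
    """Class probabilities, columns ordered (bad, good); rows sum to 1."""
    return model.predict_proba(spectra)


def extract_penultimate_features(model, spectra: np.ndarray) -> np.ndarray:
    if not isinstance(model, NetworkModel):
        raise TypeError("penultimate features exist only for CNN/ICNN models")
    return model.extract_penultimate_features(spectra)


# -- serialization ---------------------------------------------------------------


def save_model(model, path) -> None:
    """Self-describing archive: spec dict plus parameter payload."""
    if isinstance(model, RFModel):
        payload = {"type": "rf", "forest": model.forest, "n_features": model.n_features}
    elif isinstance(model, NetworkModel):
        payload = {"type": "net", "state": model.net.state(), "trained": model.trained}
    elif isinstance(model, HybridModel):
        payload = {
            "type": "hybrid",
            "state": model.network.net.state(),
            "net_spec": asdict(model.network.spec),
            "net_seed": model.network.seed,
            "forest": model.forest.forest,
            "rf_n_features": model.forest.n_features,
            "rf_spec": asdict(model.forest.spec),
        }
    else:
        raise TypeError(f"cannot serialize {type(model).__name__}")
    joblib.dump({"spec": asdict(model.spec), "seed": getattr(model, "seed", 0), "payload": payload}, path)


def load_model(path):
    blob = joblib.load(path)
    spec = ModelSpec(**blob["spec"])
    payload = blob["payload"]
    if payload["type"] == "rf":
        model = RFModel(spec, seed=blob["seed"], n_features=payload["n_features"])
        model.forest = payload["forest"]
        model.trained = True
        return model
    if payload["type"] == "net":
        model = NetworkModel(spec, seed=blob["seed"])
        model.net.load_state(payload["state"])
        model.trained = payload["trained"]
        return model
    if payload["type"] == "hybrid":
        net = NetworkModel(ModelSpec(**payload["net_spec"]), seed=payload["net_seed"])
        net.net.load_state(payload["state"])
        net.trained = True
        forest = RFModel(ModelSpec(**payload["rf_spec"]), n_features=payload["rf_n_features"])
        forest.forest = payload["forest"]
        forest.trained = True
        return HybridModel(net, forest)
    raise ValueError(f"unknown payload type {payload['type']!r}")
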
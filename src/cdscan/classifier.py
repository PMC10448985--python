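"""Feed-forward nucleotide classifier trained on balanced sensor samples.

The network is deliberately small: 16 inputs, one hidden layer of 10 SELU
units by default, and two unnormalized output scores trained with softmax
cross-entropy from logits.  It is implemented directly in numpy (the
dependency footprint does not include a deep-learning framework and the model
is tiny), with Adam and early stopping on validation loss.

Five models are trained as five disjoint 20% validation folds over the
balanced sample set, so each model sees a distinct 80/20 split.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np

from .sensors import FeatureMatrix, N_FEATURES
from .sequence_io import PredictionTrack

logger = logging.getLogger(__name__)

_SELU_SCALE = 1.0507009873554805
_SELU_ALPHA = 1.6732632423543772


@dataclass
class ModelSpec:
    hidden_layers: int = 1
    neurons_per_layer: int = 10
    learning_rate: float = 1e-3
    batch_size: int = 256
    max_epochs: int = 100
    patience: int = 5
    standardize: bool = True
    n_folds: int = 5

    def __post_init__(self) -> None:
        if self.hidden_layers < 1 or self.neurons_per_layer < 1:
            raise ValueError("need at least one hidden layer and one neuron")


def _selu(z: np.ndarray) -> np.ndarray:
    return _SELU_SCALE * np.where(z > 0, z, _SELU_ALPHA * np.expm1(z))


def _selu_grad(z: np.ndarray) -> np.ndarray:
    return _SELU_SCALE * np.where(z > 0, 1.0, _SELU_ALPHA * np.exp(z))


def _log_softmax(logits: np.ndarray) -> np.ndarray:
    m = logits.max(axis=1, keepdims=True)
    z = logits - m
    return z - np.log(np.exp(z).sum(axis=1, keepdims=True))


class DenseNet:
    """Minimal fully connected SELU network with two logit outputs."""

    def __init__(self, spec: ModelSpec, rng: np.random.Generator,
                 n_in: int = N_FEATURES):
        self.spec = spec
        sizes = [n_in] + [spec.neurons_per_layer] * spec.hidden_layers + [2]
        self.weights: list[np.ndarray] = []
        self.biases: list[np.ndarray] = []
        for fan_in, fan_out in zip(sizes[:-1], sizes[1:]):
            # lecun-normal init, the standard pairing for SELU
            self.weights.append(rng.normal(0.0, 1.0 / np.sqrt(fan_in),
                                           size=(fan_in, fan_out)))
            self.biases.append(np.zeros(fan_out))

    def forward(self, x: np.ndarray) -> np.ndarray:
        """Unnormalized output scores (logits), shape (n, 2)."""
        a = x
        for w, b in zip(self.weights[:-1], self.biases[:-1]):
            a = _selu(a @ w + b)
        return a @ self.weights[-1] + self.biases[-1]

    def loss(self, x: np.ndarray, y: np.ndarray) -> float:
        logp = _log_softmax(self.forward(x))
        return float(-logp[np.arange(len(y)), y].mean())

    def _grads(self, x: np.ndarray, y: np.ndarray):
        zs, acts = [], [x]
        a = x
        for w, b in zip(self.weights[:-1], self.biases[:-1]):
            z = a @ w + b
            zs.append(z)
            a = _selu(z)
            acts.append(a)
        logits = a @ self.weights[-1] + self.biases[-1]
        probs = np.exp(_log_softmax(logits))
        delta = probs
        delta[np.arange(len(y)), y] -= 1.0
        delta /= len(y)
        gw = [None] * len(self.weights)
        gb = [None] * len(self.biases)
        for layer in range(len(self.weights) - 1, -1, -1):
            gw[layer] = acts[layer].T @ delta
            gb[layer] = delta.sum(axis=0)
            if layer > 0:
                delta = (delta @ self.weights[layer].T) * _selu_grad(zs[layer - 1])
        return gw, gb

    def fit(self, x: np.ndarray, y: np.ndarray,
            x_val: np.ndarray, y_val: np.ndarray,
            rng: np.random.Generator) -> dict:
        spec = self.spec
        params = self.weights + self.biases
        m = [np.zeros_like(p) for p in params]
        v = [np.zeros_like(p) for p in params]
        beta1, beta2, eps = 0.9, 0.999, 1e-8
        t = 0
        best_loss = np.inf
        best_state = None
        bad_epochs = 0
        history = []
        for epoch in range(spec.max_epochs):
            order = rng.permutation(len(x))
            for start in range(0, len(x), spec.batch_size):
                batch = order[start:start + spec.batch_size]
                gw, gb = self._grads(x[batch], y[batch])
                t += 1
                for i, g in enumerate(gw + gb):
                    m[i] = beta1 * m[i] + (1 - beta1) * g
                    v[i] = beta2 * v[i] + (1 - beta2) * g * g
                    mhat = m[i] / (1 - beta1 ** t)
                    vhat = v[i] / (1 - beta2 ** t)
                    params[i] -= spec.learning_rate * mhat / (np.sqrt(vhat) + eps)
            val_loss = self.loss(x_val, y_val)
            history.append(val_loss)
            if val_loss < best_loss - 1e-5:
                best_loss = val_loss
                best_state = ([w.copy() for w in self.weights],
                              [b.copy() for b in self.biases])
                bad_epochs = 0
            else:
                bad_epochs += 1
                if bad_epochs >= spec.patience:
                    break
        if best_state is not None:
            self.weights, self.biases = best_state
        val_pred = self.predict(x_val)
        return {
            "val_loss": best_loss if np.isfinite(best_loss) else history[-1],
            "val_accuracy": float((val_pred == y_val).mean()),
            "epochs": len(history),
        }

    def predict(self, x: np.ndarray) -> np.ndarray:
        """0/1 labels; exact ties break toward noncoding (0)."""
        scores = self.forward(x)
        return (scores[:, 1] > scores[:, 0]).astype(np.uint8)

    def to_dict(self) -> dict:
        return {
            "weights": [w.tolist() for w in self.weights],
            "biases": [b.tolist() for b in self.biases],
        }

    @classmethod
    def from_dict(cls, spec: ModelSpec, d: dict) -> "DenseNet":
        net = cls.__new__(cls)
        net.spec = spec
        net.weights = [np.asarray(w, dtype=np.float64) for w in d["weights"]]
        net.biases = [np.asarray(b, dtype=np.float64) for b in d["biases"]]
        return net


@dataclass
class FoldModel:
    net: DenseNet
    mean: np.ndarray  # per-feature standardization, fit on the training fold
    scale: np.ndarray
    val_loss: float
    val_accuracy: float

    def predict(self, features: np.ndarray) -> np.ndarray:
        x = (features - self.mean) / self.scale
        return self.net.predict(x)


@dataclass
class ModelEnsemble:
    spec: ModelSpec
    folds: list[FoldModel]
    seed: int

    def val_summary(self) -> tuple[float, float]:
        losses = [f.val_loss for f in self.folds]
        return float(np.mean(losses)), float(np.std(losses))

    def to_dict(self) -> dict:
        return {
            "spec": self.spec.__dict__,
            "seed": self.seed,
            "folds": [
                {
                    "net": f.net.to_dict(),
                    "mean": f.mean.tolist(),
                    "scale": f.scale.tolist(),
                    "val_loss": f.val_loss,
                    "val_accuracy": f.val_accuracy,
                }
                for f in self.folds
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelEnsemble":
        spec = ModelSpec(**d["spec"])
        folds = [
            FoldModel(
                net=DenseNet.from_dict(spec, f["net"]),
                mean=np.asarray(f["mean"]),
                scale=np.asarray(f["scale"]),
                val_loss=f["val_loss"],
                val_accuracy=f["val_accuracy"],
            )
            for f in d["folds"]
        ]
        return cls(spec=spec, folds=folds, seed=d["seed"])

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh)

    @classmethod
    def load(cls, path) -> "ModelEnsemble":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def sample_balanced(track: PredictionTrack, n1: int, n0: int,
                    seed: int) -> np.ndarray:
    """Pick n1 coding and n0 noncoding valid positions without replacement."""
    valid = np.arange(track.valid_start, track.valid_end)
    labels = track.labels[valid]
    pos1 = valid[labels == 1]
    pos0 = valid[labels == 0]
    if len(pos1) < n1:
        raise ValueError(
            f"requested {n1} coding positions but only {len(pos1)} available"
        )
    if len(pos0) < n0:
        raise ValueError(
            f"requested {n0} noncoding positions but only {len(pos0)} available"
        )
    rng = np.random.default_rng(seed)
    take1 = rng.choice(pos1, size=n1, replace=False)
    take0 = rng.choice(pos0, size=n0, replace=False)
    return np.sort(np.concatenate([take1, take0]))


def train_ensemble(features: np.ndarray, labels: np.ndarray,
                   spec: ModelSpec, seed: int) -> ModelEnsemble:
    """Train one model per disjoint 20% validation fold (5 by default)."""
    features = np.asarray(features, dtype=np.float64)
    labels = np.asarray(labels, dtype=np.int64)
    if features.ndim != 2 or features.shape[1] != N_FEATURES:
        raise ValueError(f"features must be (n, {N_FEATURES})")
    if len(np.unique(labels)) < 2:
        raise ValueError("training data contains a single class")
    master = np.random.default_rng(seed)
    perm = master.permutation(len(labels))
    fold_idx = np.array_split(perm, spec.n_folds)
    folds: list[FoldModel] = []
    for i in range(spec.n_folds):
        val = fold_idx[i]
        train = np.concatenate([fold_idx[j] for j in range(spec.n_folds)
                                if j != i])
        x_tr, y_tr = features[train], labels[train]
        x_va, y_va = features[val], labels[val]
        if spec.standardize:
            mean = x_tr.mean(axis=0)
            scale = x_tr.std(axis=0)
            scale[scale == 0] = 1.0
        else:
            mean = np.zeros(features.shape[1])
            scale = np.ones(features.shape[1])
        x_tr = (x_tr - mean) / scale
        x_va = (x_va - mean) / scale
        fold_rng = np.random.default_rng(master.integers(2 ** 31))
        net = DenseNet(spec, fold_rng)
        stats = net.fit(x_tr, y_tr, x_va, y_va, fold_rng)
        logger.info("fold %d: val_loss=%.4f val_acc=%.4f epochs=%d",
                    i, stats["val_loss"], stats["val_accuracy"],
                    stats["epochs"])
        folds.append(FoldModel(net=net, mean=mean, scale=scale,
                               val_loss=stats["val_loss"],
                               val_accuracy=stats["val_accuracy"]))
    return ModelEnsemble(spec=spec, folds=folds, seed=seed)


def predict_initial(model, features: FeatureMatrix,
                    mode: str = "majority"):
    """Initial per-nucleotide 0/1 predictions from sensor features.

    *model* may be a FoldModel (single net) or a ModelEnsemble.  With an
    ensemble, mode="per_model" returns one PredictionTrack per fold and
    mode="majority" a single consensus-vote track.
    """
    if features.values.shape[1] != N_FEATURES:
        raise ValueError(f"feature dimension must be {N_FEATURES}")
    n = features.seq_len
    half = features.window // 2
    if len(features.positions):
        valid_start = int(features.positions[0])
        valid_end = int(features.positions[-1]) + 1
    else:
        valid_start = valid_end = half

    def _track(pred: np.ndarray) -> PredictionTrack:
        labels = np.zeros(n, dtype=np.uint8)
        labels[features.positions] = pred
        return PredictionTrack(features.seq_id, labels, valid_start, valid_end)

    if isinstance(model, FoldModel):
        return _track(model.predict(features.values))
    if not isinstance(model, ModelEnsemble):
        raise TypeError("model must be a FoldModel or ModelEnsemble")
    per_model = [f.predict(features.values) for f in model.folds]
    if mode == "per_model":
        return [_track(p) for p in per_model]
    if mode == "majority":
        votes = np.sum(per_model, axis=0) if per_model else np.zeros(0)
        # strict majority; exact splits break toward noncoding
        return _track((votes * 2 > len(model.folds)).astype(np.uint8))
    raise ValueError(f"unknown prediction mode {mode!r}")
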
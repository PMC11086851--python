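"""Two-stream feedforward classifier for MI vs MCI phenotyping.

Architecture: the kinematic (angle) features and the questionnaire (PROMs)
features enter separate streams. Each stream applies batch normalisation,
then a square linear layer with as many outputs as inputs, then ReLU. The
stream outputs are concatenated and a final linear layer with a sigmoid
produces the probability of the positive class (MI, encoded 1); the label
is MI when the probability reaches the decision threshold. Feature-subset
masks select which features each stream sees; a stream with no active
features is dropped, which yields the angle-only and PROMs-only models.

Training minimises binary cross-entropy by gradient descent (full batch by
default — exact and bit-reproducible at cohort sizes of ~10²; minibatch SGD
is available via ``batch_size``). Batch normalisation sits at the input, so
its batch statistics depend only on the data, never on the parameters;
treating them as constants in the backward pass is therefore exact.
Inference uses running statistics accumulated with momentum during training.

The whole model is a few hundred parameters, so it is implemented directly
in NumPy with analytic gradients rather than through an autodiff framework.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .proms import N_PROM_FEATURES
from .repetitions import N_ANGLE_FEATURES

MODEL_FORMAT_VERSION = 1

#: class encoding: MI is the positive class
LABEL_MI = 1
LABEL_MCI = 0
LABEL_NAMES = {LABEL_MI: "MI", LABEL_MCI: "MCI"}

_STREAMS = ("angle", "proms")


class DivergenceError(RuntimeError):
    """Training loss became non-finite."""


class UntrainedModelError(RuntimeError):
    """Prediction was requested from parameters that were never trained."""


@dataclass(frozen=True)
class ModelConfig:
    """Hyperparameters and feature masks for one model fit.

    ``batch_size=0`` means full-batch gradient descent. The decision
    threshold is the probability cutoff above which the positive class (MI)
    is predicted.
    """

    angle_mask: tuple[bool, ...] = (True,) * N_ANGLE_FEATURES
    proms_mask: tuple[bool, ...] = (True,) * N_PROM_FEATURES
    learning_rate: float = 0.05
    epochs: int = 500
    batch_size: int = 0
    seed: int = 0
    decision_threshold: float = 0.5
    bn_momentum: float = 0.1
    bn_eps: float = 1e-5

    def __post_init__(self) -> None:
        if len(self.angle_mask) != N_ANGLE_FEATURES:
            raise ValueError(f"angle_mask must have length {N_ANGLE_FEATURES}")
        if len(self.proms_mask) != N_PROM_FEATURES:
            raise ValueError(f"proms_mask must have length {N_PROM_FEATURES}")
        if not (any(self.angle_mask) or any(self.proms_mask)):
            raise ValueError("at least one feature must be active across both masks")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if not (0 < self.decision_threshold < 1):
            raise ValueError("decision_threshold must lie in (0, 1)")


@dataclass
class StreamParams:
    """Batch-norm statistics/affine and square linear map of one stream."""

    gamma: np.ndarray  # (d,) BN scale
    beta: np.ndarray  # (d,) BN shift
    running_mean: np.ndarray
    running_var: np.ndarray
    weight: np.ndarray  # (d, d)
    bias: np.ndarray  # (d,)


@dataclass
class ModelParams:
    """All learned parameters of a (possibly masked) two-stream model."""

    config: ModelConfig
    streams: dict[str, StreamParams]
    w_out: np.ndarray  # (sum of active dims,)
    b_out: float
    trained: bool = False
    loss_history: list[float] = field(default_factory=list)


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=float)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def _active_inputs(config: ModelConfig, angle_X: np.ndarray | None,
                   proms_X: np.ndarray | None) -> dict[str, np.ndarray]:
    """Masked per-stream design matrices; streams with no features dropped."""
    out: dict[str, np.ndarray] = {}
    for name, X, mask in (
        ("angle", angle_X, config.angle_mask),
        ("proms", proms_X, config.proms_mask),
    ):
        if not any(mask):
            continue
        if X is None:
            raise ValueError(f"{name} features required by mask but not provided")
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != len(mask):
            raise ValueError(
                f"{name} features must have shape (n, {len(mask)}), got {X.shape}"
            )
        out[name] = X[:, np.asarray(mask, dtype=bool)]
    return out


def init_params(config: ModelConfig, rng: np.random.Generator) -> ModelParams:
    """Seeded initialisation.

    The square stream layer starts near the identity (identity plus small
    uniform noise) with a bias of one, so after batch normalisation almost
    every ReLU unit is initially active; a plain symmetric-uniform start
    leaves narrow streams prone to dead-unit collapse (the whole stream
    output stuck at zero). The final layer uses uniform ±1/√d.
    """
    streams: dict[str, StreamParams] = {}
    dims = []
    for name, mask in (("angle", config.angle_mask), ("proms", config.proms_mask)):
        d = int(np.sum(mask))
        if d == 0:
            continue
        streams[name] = StreamParams(
            gamma=np.ones(d),
            beta=np.zeros(d),
            running_mean=np.zeros(d),
            running_var=np.ones(d),
            weight=np.eye(d) + rng.uniform(-0.1, 0.1, size=(d, d)),
            bias=np.ones(d),
        )
        dims.append(d)
    d_total = int(np.sum(dims))
    bound = 1.0 / np.sqrt(d_total)
    return ModelParams(
        config=config,
        streams=streams,
        w_out=rng.uniform(-bound, bound, size=d_total),
        b_out=float(rng.uniform(-bound, bound)),
    )


def forward(
    params: ModelParams,
    angle_X: np.ndarray | None,
    proms_X: np.ndarray | None,
    training: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Probability of MI and hard labels for a batch of feature vectors.

    In training mode batch statistics normalise each stream; in inference
    mode the stored running statistics are used.
    """
    cfg = params.config
    inputs = _active_inputs(cfg, angle_X, proms_X)
    acts = []
    for name in _STREAMS:
        if name not in params.streams:
            continue
        sp = params.streams[name]
        X = inputs[name]
        if training:
            mu, var = X.mean(axis=0), X.var(axis=0)
        else:
            mu, var = sp.running_mean, sp.running_var
        x_hat = (X - mu) / np.sqrt(var + cfg.bn_eps)
        z = sp.gamma * x_hat + sp.beta
        h = z @ sp.weight + sp.bias
        acts.append(np.maximum(h, 0.0))
    cat = np.concatenate(acts, axis=1)
    logits = cat @ params.w_out + params.b_out
    probs = _sigmoid(logits)
    labels = (probs >= cfg.decision_threshold).astype(int)
    return probs, labels


def _bce(probs: np.ndarray, y: np.ndarray) -> float:
    p = np.clip(probs, 1e-12, 1.0 - 1e-12)
    return float(-np.mean(y * np.log(p) + (1.0 - y) * np.log(1.0 - p)))


def train(
    angle_X: np.ndarray | None,
    proms_X: np.ndarray | None,
    y: np.ndarray,
    config: ModelConfig,
) -> ModelParams:
    """Fit the two-stream model by gradient descent on binary cross-entropy.

    Requires at least two examples of each class. With a fixed seed the
    result is bit-reproducible. Raises :class:`DivergenceError` if the loss
    becomes non-finite.
    """
    y = np.asarray(y, dtype=float)
    classes, counts = np.unique(y, return_counts=True)
    if not set(classes).issubset({0.0, 1.0}):
        raise ValueError(f"labels must be 0 (MCI) or 1 (MI), got {classes}")
    if len(classes) < 2:
        raise ValueError("training set contains a single class; need both MI and MCI")
    if counts.min() < 2:
        raise ValueError("need at least 2 examples per class")

    cfg = config
    rng = np.random.default_rng(cfg.seed)
    params = init_params(cfg, rng)
    inputs_full = _active_inputs(cfg, angle_X, proms_X)
    n = len(y)
    active = [s for s in _STREAMS if s in params.streams]
    lr, m = cfg.learning_rate, cfg.bn_momentum

    for epoch in range(cfg.epochs):
        if cfg.batch_size and cfg.batch_size < n:
            order = rng.permutation(n)
            batches = [
                order[i : i + cfg.batch_size] for i in range(0, n, cfg.batch_size)
            ]
        else:
            batches = [np.arange(n)]

        epoch_loss = 0.0
        for idx in batches:
            yb = y[idx]
            nb = len(idx)
            # forward with batch statistics, caching intermediates
            cache: dict[str, tuple] = {}
            acts = []
            for name in active:
                sp = params.streams[name]
                X = inputs_full[name][idx]
                mu, var = X.mean(axis=0), X.var(axis=0)
                inv_std = 1.0 / np.sqrt(var + cfg.bn_eps)
                x_hat = (X - mu) * inv_std
                z = sp.gamma * x_hat + sp.beta
                h = z @ sp.weight + sp.bias
                r = np.maximum(h, 0.0)
                cache[name] = (x_hat, h, r, mu, var)
                acts.append(r)
            cat = np.concatenate(acts, axis=1)
            probs = _sigmoid(cat @ params.w_out + params.b_out)
            loss = _bce(probs, yb)
            if not np.isfinite(loss):
                raise DivergenceError(
                    f"non-finite loss at epoch {epoch} (learning_rate={lr})"
                )
            epoch_loss += loss * nb / n

            # backward: d(BCE)/d(logit) = (p - y)/n for sigmoid + BCE
            dlogit = (probs - yb) / nb
            dw_out = cat.T @ dlogit
            db_out = float(dlogit.sum())
            dcat = np.outer(dlogit, params.w_out)
            col = 0
            grads: dict[str, tuple] = {}
            for name in active:
                sp = params.streams[name]
                d = sp.gamma.size
                x_hat, h, r, mu, var = cache[name]
                dr = dcat[:, col : col + d]
                col += d
                dh = dr * (h > 0)
                dweight = (sp.gamma * x_hat + sp.beta).T @ dh
                dbias = dh.sum(axis=0)
                dz = dh @ sp.weight.T
                dgamma = (dz * x_hat).sum(axis=0)
                dbeta = dz.sum(axis=0)
                grads[name] = (dweight, dbias, dgamma, dbeta, mu, var)

            params.w_out -= lr * dw_out
            params.b_out -= lr * db_out
            for name in active:
                sp = params.streams[name]
                dweight, dbias, dgamma, dbeta, mu, var = grads[name]
                sp.weight -= lr * dweight
                sp.bias -= lr * dbias
                sp.gamma -= lr * dgamma
                sp.beta -= lr * dbeta
                sp.running_mean = (1 - m) * sp.running_mean + m * mu
                sp.running_var = (1 - m) * sp.running_var + m * var
        params.loss_history.append(epoch_loss)

    params.trained = True
    return params


def predict(
    params: ModelParams,
    angle_X: np.ndarray | None,
    proms_X: np.ndarray | None,
) -> tuple[np.ndarray, np.ndarray]:
    """Probabilities and hard MI/MCI labels for a dataset; deterministic."""
    if not params.trained:
        raise UntrainedModelError("model parameters have not been trained")
    n = None
    for X in (angle_X, proms_X):
        if X is not None:
            n = np.asarray(X).shape[0]
            break
    if n == 0:
        return np.array([]), np.array([], dtype=int)
    return forward(params, angle_X, proms_X, training=False)


def save_model(params: ModelParams, path: str | Path) -> None:
    """Serialise config, masks, weights and BN statistics to JSON."""
    doc = {
        "format_version": MODEL_FORMAT_VERSION,
        "config": {
            "angle_mask": list(params.config.angle_mask),
            "proms_mask": list(params.config.proms_mask),
            "learning_rate": params.config.learning_rate,
            "epochs": params.config.epochs,
            "batch_size": params.config.batch_size,
            "seed": params.config.seed,
            "decision_threshold": params.config.decision_threshold,
            "bn_momentum": params.config.bn_momentum,
            "bn_eps": params.config.bn_eps,
        },
        "trained": params.trained,
        "w_out": params.w_out.tolist(),
        "b_out": params.b_out,
        "loss_history": params.loss_history,
        "streams": {
            name: {
                "gamma": sp.gamma.tolist(),
                "beta": sp.beta.tolist(),
                "running_mean": sp.running_mean.tolist(),
                "running_var": sp.running_var.tolist(),
                "weight": sp.weight.tolist(),
                "bias": sp.bias.tolist(),
            }
            for name, sp in params.streams.items()
        },
    }
    Path(path).write_text(json.dumps(doc, indent=1))


def load_model(path: str | Path) -> ModelParams:
    doc = json.loads(Path(path).read_text())
    if doc.get("format_version") != MODEL_FORMAT_VERSION:
        raise ValueError(f"unsupported model format version {doc.get('format_version')}")
    c = doc["config"]
    config = ModelConfig(
        angle_mask=tuple(bool(v) for v in c["angle_mask"]),
        proms_mask=tuple(bool(v) for v in c["proms_mask"]),
        learning_rate=c["learning_rate"],
        epochs=c["epochs"],
        batch_size=c["batch_size"],
        seed=c["seed"],
        decision_threshold=c["decision_threshold"],
        bn_momentum=c["bn_momentum"],
        bn_eps=c["bn_eps"],
    )
    streams = {
        name: StreamParams(
            gamma=np.asarray(s["gamma"], dtype=float),
            beta=np.asarray(s["beta"], dtype=float),
            running_mean=np.asarray(s["running_mean"], dtype=float),
            running_var=np.asarray(s["running_var"], dtype=float),
            weight=np.asarray(s["weight"], dtype=float),
            bias=np.asarray(s["bias"], dtype=float),
        )
        for name, s in doc["streams"].items()
    }
    return ModelParams(
        config=config,
        streams=streams,
        w_out=np.asarray(doc["w_out"], dtype=float),
        b_out=float(doc["b_out"]),
        trained=bool(doc["trained"]),
        loss_history=list(doc.get("loss_history", [])),
    )
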
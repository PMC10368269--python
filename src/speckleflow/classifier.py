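"""Multi-input LSTM classifier for stenosis probability.

Architecture: each of the three factor sequences (two spatial, one
temporal) feeds its own 8-cell LSTM; the final hidden states are passed
through a hyperbolic tangent, concatenated into a 24-vector, projected
through a 32-unit dense layer with ReLU, and reduced to a single
sigmoid-activated output — the probability of stenosis.

Training minimises class-weighted binary cross-entropy plus L1 and L2
penalties on the LSTM kernel and recurrent weights (not biases), with
the Adam update rule, mini-batches of size one, at most 100 epochs and
early stopping after five epochs without validation-loss improvement
(restoring the best-epoch weights).

The network is implemented directly on NumPy arrays — forward pass,
backpropagation through time, and the Adam optimiser — and is verified
against numerical gradients in the test suite.  All randomness (weight
initialisation, epoch shuffling) derives from a single integer seed.
"""

from __future__ import annotations

import copy
import json
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .dataset import FeatureSequences, NormalizerState, save_normalizer

__all__ = [
    "ModelConfig",
    "TrainedModel",
    "build_model",
    "train",
    "predict_proba",
    "compute_class_weights",
    "parameter_count",
    "save_model",
    "load_model",
]

_GATES = 4  # input, forget, cell, output


@dataclass(frozen=True)
class ModelConfig:
    """Hyperparameters of the network and its training loop."""

    lstm_cells: int = 8
    dense_units: int = 32
    l1_penalty: float = 0.01
    l2_penalty: float = 0.01
    learning_rate: float = 0.001
    beta1: float = 0.9
    beta2: float = 0.999
    epsilon: float = 1e-8
    max_epochs: int = 100
    batch_size: int = 1
    patience: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.lstm_cells, self.dense_units, self.max_epochs,
               self.batch_size, self.patience) < 1:
            raise ValueError("counts (cells, units, epochs, batch, patience) must be >= 1")
        if self.l1_penalty < 0 or self.l2_penalty < 0:
            raise ValueError("penalties must be non-negative")
        if not self.learning_rate > 0:
            raise ValueError("learning_rate must be positive")
        if not (0 < self.beta1 < 1 and 0 < self.beta2 < 1):
            raise ValueError("Adam betas must lie in (0, 1)")


@dataclass
class TrainedModel:
    """Network parameters plus everything needed to reproduce inference."""

    params: Dict[str, np.ndarray]
    config: ModelConfig
    input_lengths: Tuple[int, int, int]
    channels: int
    normalizer: Optional[NormalizerState] = None
    history: Dict[str, List[float]] = field(default_factory=lambda: {"train_loss": [], "val_loss": []})
    stopped_epoch: int = 0


def parameter_count(channels: int, lstm_cells: int = 8, dense_units: int = 32) -> int:
    """Closed-form trainable parameter count of the three-input topology."""
    per_lstm = _GATES * lstm_cells * (channels + lstm_cells + 1)
    dense1 = 3 * lstm_cells * dense_units + dense_units
    dense2 = dense_units + 1
    return 3 * per_lstm + dense1 + dense2


def _glorot(rng: np.random.Generator, shape: Tuple[int, int]) -> np.ndarray:
    limit = np.sqrt(6.0 / (shape[0] + shape[1]))
    return rng.uniform(-limit, limit, size=shape)


def _orthogonal(rng: np.random.Generator, n: int) -> np.ndarray:
    q, r = np.linalg.qr(rng.standard_normal((n, n)))
    return q * np.sign(np.diag(r))


def build_model(
    config: ModelConfig,
    input_lengths: Tuple[int, int, int],
    channels: int,
) -> TrainedModel:
    """Initialise an untrained model deterministically from ``config.seed``.

    Kernels use Glorot-uniform, recurrent matrices are orthogonal, and
    the forget-gate bias starts at one (all other biases at zero).
    """
    if channels < 1 or min(input_lengths) < 1:
        raise ValueError("input lengths and channel count must be >= 1")
    H, D = config.lstm_cells, config.dense_units
    rng = np.random.default_rng(config.seed)
    params: Dict[str, np.ndarray] = {}
    for i in range(3):
        Wh_blocks = [_orthogonal(rng, H) for _ in range(_GATES)]
        params[f"Wx{i}"] = _glorot(rng, (channels, _GATES * H))
        params[f"Wh{i}"] = np.hstack(Wh_blocks)
        b = np.zeros(_GATES * H)
        b[H:2 * H] = 1.0  # forget-gate bias
        params[f"b{i}"] = b
    params["Wd1"] = _glorot(rng, (3 * H, D))
    params["bd1"] = np.zeros(D)
    params["Wd2"] = _glorot(rng, (D, 1))
    params["bd2"] = np.zeros(1)
    return TrainedModel(
        params=params, config=config,
        input_lengths=tuple(int(x) for x in input_lengths),
        channels=int(channels),
    )


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -60.0, 60.0)))


def _lstm_forward(X: np.ndarray, Wx: np.ndarray, Wh: np.ndarray, b: np.ndarray, H: int):
    """Run one LSTM over an (L, R) sequence; returns final h and a cache."""
    L = X.shape[0]
    Z_in = X @ Wx + b  # precomputed input contribution, (L, 4H)
    gates = np.empty((L, _GATES * H))
    cs = np.empty((L, H))
    hcs = np.empty((L, H))
    hs = np.empty((L, H))
    h = np.zeros(H)
    c = np.zeros(H)
    for t in range(L):
        z = Z_in[t] + h @ Wh
        ig = _sigmoid(z[:H])
        fg = _sigmoid(z[H:2 * H])
        gg = np.tanh(z[2 * H:3 * H])
        og = _sigmoid(z[3 * H:])
        c = fg * c + ig * gg
        hc = np.tanh(c)
        h = og * hc
        gates[t, :H], gates[t, H:2 * H] = ig, fg
        gates[t, 2 * H:3 * H], gates[t, 3 * H:] = gg, og
        cs[t], hcs[t], hs[t] = c, hc, h
    cache = (X, gates, cs, hcs, hs)
    return h, cache


def _lstm_backward(dh_last: np.ndarray, cache, Wh: np.ndarray, H: int):
    """BPTT from a gradient on the final hidden state only."""
    X, gates, cs, hcs, hs = cache
    L = X.shape[0]
    dZ = np.zeros((L, _GATES * H))
    dh = dh_last.copy()
    dc = np.zeros(H)
    for t in range(L - 1, -1, -1):
        ig, fg = gates[t, :H], gates[t, H:2 * H]
        gg, og = gates[t, 2 * H:3 * H], gates[t, 3 * H:]
        hc = hcs[t]
        c_prev = cs[t - 1] if t > 0 else np.zeros(H)
        do = dh * hc
        dc = dc + dh * og * (1.0 - hc * hc)
        di = dc * gg
        df = dc * c_prev
        dg = dc * ig
        dz = np.concatenate([
            di * ig * (1.0 - ig),
            df * fg * (1.0 - fg),
            dg * (1.0 - gg * gg),
            do * og * (1.0 - og),
        ])
        dZ[t] = dz
        dh = dz @ Wh.T
        dc = dc * fg
    H_prev = np.vstack([np.zeros((1, H)), hs[:-1]])
    dWx = X.T @ dZ
    dWh = H_prev.T @ dZ
    db = dZ.sum(axis=0)
    return dWx, dWh, db


def _forward(params: Dict[str, np.ndarray], seqs, H: int):
    """Full forward pass; returns probability and caches for backprop."""
    finals, caches = [], []
    for i in range(3):
        h, cache = _lstm_forward(
            seqs[i], params[f"Wx{i}"], params[f"Wh{i}"], params[f"b{i}"], H
        )
        finals.append(h)
        caches.append(cache)
    th = [np.tanh(h) for h in finals]
    concat = np.concatenate(th)
    pre1 = concat @ params["Wd1"] + params["bd1"]
    act1 = np.maximum(pre1, 0.0)
    logit = float((act1 @ params["Wd2"])[0] + params["bd2"][0])
    p = float(_sigmoid(np.array(logit)))
    return p, (finals, th, concat, pre1, act1, logit, caches)


def _backward(params, fwd_cache, dlogit: float, H: int) -> Dict[str, np.ndarray]:
    finals, th, concat, pre1, act1, logit, caches = fwd_cache
    grads: Dict[str, np.ndarray] = {}
    grads["Wd2"] = act1[:, None] * dlogit
    grads["bd2"] = np.array([dlogit])
    dact1 = params["Wd2"][:, 0] * dlogit
    dpre1 = dact1 * (pre1 > 0)
    grads["Wd1"] = np.outer(concat, dpre1)
    grads["bd1"] = dpre1
    dconcat = params["Wd1"] @ dpre1
    for i in range(3):
        dth = dconcat[i * H:(i + 1) * H]
        dh_last = dth * (1.0 - th[i] * th[i])
        dWx, dWh, db = _lstm_backward(dh_last, caches[i], params[f"Wh{i}"], H)
        grads[f"Wx{i}"], grads[f"Wh{i}"], grads[f"b{i}"] = dWx, dWh, db
    return grads


_REGULARIZED = tuple(f"{k}{i}" for i in range(3) for k in ("Wx", "Wh"))


def _penalty(params: Dict[str, np.ndarray], l1: float, l2: float) -> float:
    total = 0.0
    for name in _REGULARIZED:
        W = params[name]
        total += l1 * np.abs(W).sum() + l2 * (W * W).sum()
    return total


def _sample_loss(p: float, y: int, weight: float) -> float:
    eps = 1e-12
    return -weight * (y * np.log(p + eps) + (1 - y) * np.log(1 - p + eps))


def compute_class_weights(labels: Sequence[int]) -> Dict[int, float]:
    """Inverse-frequency class weights normalised to mean one.

    ``w_c = N / (2 N_c)``: the rarer class always receives the strictly
    larger weight.
    """
    labels = list(labels)
    n = len(labels)
    counts = {c: labels.count(c) for c in (0, 1)}
    if min(counts.values()) == 0:
        raise ValueError("both classes must be present to define class weights")
    return {c: n / (2.0 * counts[c]) for c in (0, 1)}


def _check_input(model: TrainedModel, f: FeatureSequences) -> Tuple[np.ndarray, ...]:
    seqs = f.sequences
    for i, (seq, L) in enumerate(zip(seqs, model.input_lengths)):
        if seq.shape != (L, model.channels):
            raise ValueError(
                f"input {i + 1} has shape {seq.shape}, model expects ({L}, {model.channels})"
            )
    return seqs


def train(
    model: TrainedModel,
    train_set: Sequence[FeatureSequences],
    val_set: Sequence[FeatureSequences],
    class_weights: Optional[Dict[int, float]] = None,
) -> TrainedModel:
    """Train in place and return the model with best-epoch weights.

    Sequences must already be normalised and length-aligned.  One Adam
    update per sample (mini-batch size one), sample order reshuffled
    every epoch from the model seed.  Reported losses (training and
    validation) are the full optimised objective — class-weighted
    cross-entropy plus the L1/L2 penalty — so the early-stopping monitor
    sees the same quantity the optimiser minimises.  Training stops
    after ``patience`` consecutive epochs without validation-loss
    improvement or at ``max_epochs``, whichever comes first, and the
    parameters from the best validation epoch are restored.
    """
    cfg = model.config
    if not train_set or not val_set:
        raise ValueError("train and validation sets must be non-empty")
    train_labels = [f.label for f in train_set]
    if class_weights is None:
        class_weights = compute_class_weights(train_labels)
    H = cfg.lstm_cells
    l1, l2 = cfg.l1_penalty, cfg.l2_penalty

    train_seqs = [(_check_input(model, f), f.label) for f in train_set]
    val_seqs = [(_check_input(model, f), f.label) for f in val_set]

    params = model.params
    adam_m = {k: np.zeros_like(v) for k, v in params.items()}
    adam_v = {k: np.zeros_like(v) for k, v in params.items()}
    step = 0
    rng = np.random.default_rng(cfg.seed + 1)  # decoupled from init stream

    best_val = np.inf
    best_params = copy.deepcopy(params)
    best_epoch = 0
    epochs_since_best = 0

    for epoch in range(1, cfg.max_epochs + 1):
        order = rng.permutation(len(train_seqs))
        epoch_loss = 0.0
        for idx in order:
            seqs, y = train_seqs[idx]
            w = class_weights[y]
            p, cache = _forward(params, seqs, H)
            epoch_loss += _sample_loss(p, y, w)
            grads = _backward(params, cache, w * (p - y), H)
            for name in _REGULARIZED:
                W = params[name]
                grads[name] = grads[name] + l1 * np.sign(W) + 2.0 * l2 * W
            step += 1
            bc1 = 1.0 - cfg.beta1 ** step
            bc2 = 1.0 - cfg.beta2 ** step
            for name, g in grads.items():
                adam_m[name] = cfg.beta1 * adam_m[name] + (1 - cfg.beta1) * g
                adam_v[name] = cfg.beta2 * adam_v[name] + (1 - cfg.beta2) * g * g
                params[name] -= cfg.learning_rate * (adam_m[name] / bc1) / (
                    np.sqrt(adam_v[name] / bc2) + cfg.epsilon
                )
        pen = _penalty(params, l1, l2)
        train_loss = epoch_loss / len(train_seqs) + pen
        val_loss = sum(
            _sample_loss(_forward(params, seqs, H)[0], y, class_weights[y])
            for seqs, y in val_seqs
        ) / len(val_seqs) + pen
        model.history["train_loss"].append(float(train_loss))
        model.history["val_loss"].append(float(val_loss))
        if val_loss < best_val:
            best_val = val_loss
            best_params = copy.deepcopy(params)
            best_epoch = epoch
            epochs_since_best = 0
        else:
            epochs_since_best += 1
            if epochs_since_best >= cfg.patience:
                break

    model.params = best_params
    model.stopped_epoch = len(model.history["val_loss"])
    model.history["best_epoch"] = best_epoch  # type: ignore[assignment]
    return model


def predict_proba(model: TrainedModel, f: FeatureSequences) -> float:
    """Probability of stenosis for one normalised feature set, in (0, 1)."""
    seqs = _check_input(model, f)
    p, _ = _forward(model.params, seqs, model.config.lstm_cells)
    return min(max(p, 1e-12), 1.0 - 1e-12)


def save_model(model: TrainedModel, directory: os.PathLike | str) -> Path:
    """Persist parameters, config, normalizer and history to a directory."""
    out = Path(directory)
    out.mkdir(parents=True, exist_ok=True)
    np.savez(out / "params.npz", **model.params)
    meta = {
        "config": model.config.__dict__,
        "input_lengths": list(model.input_lengths),
        "channels": model.channels,
        "stopped_epoch": model.stopped_epoch,
    }
    with open(out / "config.json", "w") as fh:
        json.dump(meta, fh, indent=2)
    if model.normalizer is not None:
        save_normalizer(model.normalizer, out / "normalizer.json")
    hist = model.history
    n = len(hist.get("train_loss", []))
    with open(out / "history.csv", "w") as fh:
        fh.write("epoch,train_loss,val_loss\n")
        for e in range(n):
            fh.write(f"{e + 1},{hist['train_loss'][e]},{hist['val_loss'][e]}\n")
    return out


def load_model(directory: os.PathLike | str) -> TrainedModel:
    """Load a model saved by :func:`save_model`."""
    from .dataset import load_normalizer

    d = Path(directory)
    with open(d / "config.json") as fh:
        meta = json.load(fh)
    params = dict(np.load(d / "params.npz"))
    model = TrainedModel(
        params=params,
        config=ModelConfig(**meta["config"]),
        input_lengths=tuple(meta["input_lengths"]),
        channels=int(meta["channels"]),
        stopped_epoch=int(meta["stopped_epoch"]),
    )
    norm_path = d / "normalizer.json"
    if norm_path.exists():
        model.normalizer = load_normalizer(norm_path)
    return model
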
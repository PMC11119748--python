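"""Shallow multi-task network: speaker embedding -> (intelligibility, severity).

The network is two fully connected hidden layers ([emb x 128], [128 x 64]),
each followed by ReLU, batch normalization and 20% dropout, feeding two affine
[64 x 1] heads — one per perceptual score.  Training minimizes the weighted
sum of the two per-task mean-squared errors (50% each by default) with Adam,
batch size 8, learning rate 0.001, for 20 epochs.  Inference outputs are
clamped to the clinical 0-10 scale.

Everything is plain numpy; the model is small enough that hand-written
backpropagation is both fast and exactly reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .audio import BreakSpec, Waveform, segment_audio, segment_passage
from .errors import ConfigurationError, TrainingDivergenceError, ValidationError
from .xvector import ExtractorWeights, extract_embedding

SCORE_MIN, SCORE_MAX = 0.0, 10.0
HIDDEN_DIMS = (128, 64)
_BN_EPS = 1e-5
_BN_MOMENTUM = 0.1


@dataclass(frozen=True)
class ScorePair:
    """Intelligibility and severity on the 0-10 clinical scale.

    0 is unintelligible speech with high severity; 10 is perceived unimpaired
    speech.
    """

    intelligibility: float
    severity: float

    def __post_init__(self):
        for name, v in (("intelligibility", self.intelligibility), ("severity", self.severity)):
            if not np.isfinite(v) or not (SCORE_MIN <= v <= SCORE_MAX):
                raise ValidationError(f"{name} score {v} outside [{SCORE_MIN}, {SCORE_MAX}]")

    def as_array(self) -> np.ndarray:
        return np.array([self.intelligibility, self.severity], dtype=np.float64)


@dataclass(frozen=True)
class LabeledExample:
    embedding: np.ndarray
    target: ScorePair
    provenance: dict = field(default_factory=dict)


@dataclass(frozen=True)
class TrainingConfig:
    learning_rate: float = 0.001
    batch_size: int = 8
    epochs: int = 20
    dropout: float = 0.2
    loss_weights: tuple[float, float] = (0.5, 0.5)
    seed: int = 0

    def __post_init__(self):
        if self.learning_rate <= 0 or self.batch_size <= 0 or self.epochs <= 0:
            raise ValidationError("learning_rate, batch_size and epochs must be positive")
        if not (0.0 <= self.dropout < 1.0):
            raise ValidationError(f"dropout {self.dropout} must be in [0, 1)")
        if abs(sum(self.loss_weights) - 1.0) > 1e-9:
            raise ValidationError(f"loss weights {self.loss_weights} must sum to 1")


class RegressorWeights:
    """Parameters of the shallow network; hidden layers carry batch-norm state."""

    PARAM_NAMES = (
        "W1", "b1", "g1", "beta1", "W2", "b2", "g2", "beta2",
        "w_int", "b_int", "w_sev", "b_sev",
    )

    def __init__(self, emb_dim: int, rng: np.random.Generator):
        h1, h2 = HIDDEN_DIMS
        self.emb_dim = emb_dim

        def glorot(fan_in, fan_out):
            return rng.normal(0.0, np.sqrt(2.0 / (fan_in + fan_out)), size=(fan_in, fan_out))

        self.W1 = glorot(emb_dim, h1)
        self.b1 = np.zeros(h1)
        self.g1 = np.ones(h1)
        self.beta1 = np.zeros(h1)
        self.rm1 = np.zeros(h1)
        self.rv1 = np.ones(h1)
        self.W2 = glorot(h1, h2)
        self.b2 = np.zeros(h2)
        self.g2 = np.ones(h2)
        self.beta2 = np.zeros(h2)
        self.rm2 = np.zeros(h2)
        self.rv2 = np.ones(h2)
        # Heads share their initialization: with duplicated targets the two
        # tasks then receive identical gradients and stay exactly equal.
        self.w_int = glorot(h2, 1)[:, 0]
        self.b_int = 0.0
        self.w_sev = self.w_int.copy()
        self.b_sev = 0.0

    def params(self) -> dict[str, np.ndarray | float]:
        return {name: getattr(self, name) for name in self.PARAM_NAMES}


def _check_dim(x: np.ndarray, w: RegressorWeights) -> np.ndarray:
    x = np.asarray(x, dtype=np.float64)
    if x.shape[-1] != w.emb_dim:
        raise ConfigurationError(
            f"embedding length {x.shape[-1]} does not match model input dim {w.emb_dim}"
        )
    return x


def _infer_batch(X: np.ndarray, w: RegressorWeights) -> np.ndarray:
    """Deterministic forward pass with running batch-norm stats, no dropout."""
    h = np.maximum(X @ w.W1 + w.b1, 0.0)
    h = w.g1 * (h - w.rm1) / np.sqrt(w.rv1 + _BN_EPS) + w.beta1
    h = np.maximum(h @ w.W2 + w.b2, 0.0)
    h = w.g2 * (h - w.rm2) / np.sqrt(w.rv2 + _BN_EPS) + w.beta2
    yi = h @ w.w_int + w.b_int
    ys = h @ w.w_sev + w.b_sev
    return np.stack([yi, ys], axis=1)


def forward(
    x: np.ndarray,
    w: RegressorWeights,
    mode: str = "infer",
    rng: np.random.Generator | None = None,
    dropout: float = 0.2,
) -> ScorePair:
    """Predict the score pair for one embedding.

    In ``infer`` mode dropout is disabled, batch norm uses its running
    statistics, and the outputs are clamped to [0, 10].  ``train`` mode is
    stochastic (requires ``rng``) and returns unclamped head outputs as a
    plain tuple of floats packed in a ScorePair after clamping is *not*
    applied — training uses the internal batch path instead.
    """
    x = _check_dim(x, w)
    if mode == "infer":
        out = _infer_batch(x[None, :], w)[0]
        out = np.clip(out, SCORE_MIN, SCORE_MAX)
        return ScorePair(float(out[0]), float(out[1]))
    if mode != "train":
        raise ValidationError(f"unknown mode {mode!r}")
    if rng is None:
        raise ValidationError("train-mode forward requires an rng")
    out, _ = _train_forward(x[None, :], w, rng, dropout)
    out = np.clip(out, SCORE_MIN, SCORE_MAX)
    return ScorePair(float(out[0, 0]), float(out[0, 1]))


def predict_batch(X: np.ndarray, w: RegressorWeights) -> np.ndarray:
    """Clamped infer-mode predictions for a (B, emb) matrix -> (B, 2)."""
    X = _check_dim(np.atleast_2d(X), w)
    return np.clip(_infer_batch(X, w), SCORE_MIN, SCORE_MAX)


def multitask_loss(
    pred: np.ndarray, target: np.ndarray, weights: tuple[float, float] = (0.5, 0.5)
) -> float:
    """Weighted sum of the per-task mean squared errors.

    ``pred`` and ``target`` are (B, 2) arrays with columns (INT, SEV).
    """
    pred = np.atleast_2d(np.asarray(pred, dtype=np.float64))
    target = np.atleast_2d(np.asarray(target, dtype=np.float64))
    if pred.shape != target.shape or pred.shape[0] == 0 or pred.shape[1] != 2:
        raise ValidationError(
            f"prediction batch {pred.shape} and target batch {target.shape} must be "
            "equal non-empty (B, 2) shapes"
        )
    mse = np.mean((pred - target) ** 2, axis=0)
    w_int, w_sev = weights
    return float(w_int * mse[0] + w_sev * mse[1])


def _batchnorm_forward(x, gamma, beta, running_mean, running_var):
    mu = x.mean(axis=0)
    var = x.var(axis=0)
    inv_std = 1.0 / np.sqrt(var + _BN_EPS)
    xhat = (x - mu) * inv_std
    out = gamma * xhat + beta
    running_mean *= 1.0 - _BN_MOMENTUM
    running_mean += _BN_MOMENTUM * mu
    running_var *= 1.0 - _BN_MOMENTUM
    running_var += _BN_MOMENTUM * var
    return out, (xhat, inv_std)


def _batchnorm_backward(dout, gamma, cache):
    xhat, inv_std = cache
    B = dout.shape[0]
    dgamma = np.sum(dout * xhat, axis=0)
    dbeta = np.sum(dout, axis=0)
    dxhat = dout * gamma
    dx = (inv_std / B) * (
        B * dxhat - np.sum(dxhat, axis=0) - xhat * np.sum(dxhat * xhat, axis=0)
    )
    return dx, dgamma, dbeta


def _train_forward(X, w: RegressorWeights, rng, dropout):
    keep = 1.0 - dropout
    a1 = X @ w.W1 + w.b1
    r1 = np.maximum(a1, 0.0)
    z1, bn1_cache = _batchnorm_forward(r1, w.g1, w.beta1, w.rm1, w.rv1)
    m1 = (rng.random(z1.shape) < keep) / keep if dropout > 0 else np.ones_like(z1)
    d1 = z1 * m1
    a2 = d1 @ w.W2 + w.b2
    r2 = np.maximum(a2, 0.0)
    z2, bn2_cache = _batchnorm_forward(r2, w.g2, w.beta2, w.rm2, w.rv2)
    m2 = (rng.random(z2.shape) < keep) / keep if dropout > 0 else np.ones_like(z2)
    d2 = z2 * m2
    yi = d2 @ w.w_int + w.b_int
    ys = d2 @ w.w_sev + w.b_sev
    out = np.stack([yi, ys], axis=1)
    cache = (X, a1, bn1_cache, m1, d1, a2, bn2_cache, m2, d2)
    return out, cache


def _train_backward(out, T, w: RegressorWeights, cache, loss_weights):
    X, a1, bn1_cache, m1, d1, a2, bn2_cache, m2, d2 = cache
    B = X.shape[0]
    w_int, w_sev = loss_weights
    dyi = 2.0 * w_int * (out[:, 0] - T[:, 0]) / B
    dys = 2.0 * w_sev * (out[:, 1] - T[:, 1]) / B

    grads = {}
    grads["w_int"] = d2.T @ dyi
    grads["b_int"] = float(np.sum(dyi))
    grads["w_sev"] = d2.T @ dys
    grads["b_sev"] = float(np.sum(dys))
    dd2 = np.outer(dyi, w.w_int) + np.outer(dys, w.w_sev)
    dz2 = dd2 * m2
    dr2, grads["g2"], grads["beta2"] = _batchnorm_backward(dz2, w.g2, bn2_cache)
    da2 = dr2 * (a2 > 0)
    grads["W2"] = d1.T @ da2
    grads["b2"] = np.sum(da2, axis=0)
    dd1 = da2 @ w.W2.T
    dz1 = dd1 * m1
    dr1, grads["g1"], grads["beta1"] = _batchnorm_backward(dz1, w.g1, bn1_cache)
    da1 = dr1 * (a1 > 0)
    grads["W1"] = X.T @ da1
    grads["b1"] = np.sum(da1, axis=0)
    return grads


class _Adam:
    def __init__(self, params: dict, lr: float, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = {k: np.zeros_like(np.asarray(v, dtype=np.float64)) for k, v in params.items()}
        self.v = {k: np.zeros_like(np.asarray(v, dtype=np.float64)) for k, v in params.items()}

    def step(self, weights: RegressorWeights, grads: dict) -> None:
        self.t += 1
        for name, g in grads.items():
            g = np.asarray(g, dtype=np.float64)
            self.m[name] = self.beta1 * self.m[name] + (1 - self.beta1) * g
            self.v[name] = self.beta2 * self.v[name] + (1 - self.beta2) * g**2
            mhat = self.m[name] / (1 - self.beta1**self.t)
            vhat = self.v[name] / (1 - self.beta2**self.t)
            update = self.lr * mhat / (np.sqrt(vhat) + self.eps)
            current = getattr(weights, name)
            if np.isscalar(current):
                setattr(weights, name, float(current - update))
            else:
                setattr(weights, name, current - update)


def train(
    data: list[LabeledExample], cfg: TrainingConfig = TrainingConfig()
) -> tuple[RegressorWeights, list[float]]:
    """Train the regressor; returns final weights and the per-epoch loss trace.

    Mini-batches are reshuffled every epoch with the configured seed, so two
    runs with the same data and config produce identical traces and weights.
    Batches of a single example are skipped (batch norm is undefined there).
    """
    if not data:
        raise ValidationError("training data is empty")
    if len(data) < cfg.batch_size:
        raise ValidationError(
            f"need at least batch_size={cfg.batch_size} examples, got {len(data)}"
        )
    X = np.stack([np.asarray(ex.embedding, dtype=np.float64) for ex in data])
    T = np.stack([ex.target.as_array() for ex in data])
    rng = np.random.default_rng(cfg.seed)
    weights = RegressorWeights(X.shape[1], rng)
    optimizer = _Adam(weights.params(), cfg.learning_rate)
    n = X.shape[0]
    trace: list[float] = []
    for epoch in range(cfg.epochs):
        order = rng.permutation(n)
        epoch_losses = []
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            if idx.size < 2:
                continue
            out, cache = _train_forward(X[idx], weights, rng, cfg.dropout)
            loss = multitask_loss(out, T[idx], cfg.loss_weights)
            if not np.isfinite(loss):
                raise TrainingDivergenceError(epoch)
            grads = _train_backward(out, T[idx], weights, cache, cfg.loss_weights)
            optimizer.step(weights, grads)
            epoch_losses.append(loss)
        trace.append(float(np.mean(epoch_losses)))
    return weights, trace


def speaker_disjoint_split(
    data: list[LabeledExample], test_fraction: float = 0.2, seed: int = 0
) -> tuple[list[LabeledExample], list[LabeledExample]]:
    """Split examples so no speaker (hence no augmented copy) straddles sets."""
    speakers = sorted({ex.provenance.get("speaker_id", i) for i, ex in enumerate(data)},
                      key=str)
    rng = np.random.default_rng(seed)
    rng.shuffle(speakers)
    n_test = max(1, int(round(test_fraction * len(speakers))))
    test_set = set(speakers[:n_test])
    train_part, test_part = [], []
    for i, ex in enumerate(data):
        sid = ex.provenance.get("speaker_id", i)
        (test_part if sid in test_set else train_part).append(ex)
    return train_part, test_part


def predict_recording(
    w: Waveform,
    extractor: ExtractorWeights,
    reg: RegressorWeights,
    strategy: str = "whole",
    breaks: BreakSpec | None = None,
) -> ScorePair:
    """Score one passage recording.

    ``whole`` embeds the full recording; ``segments`` segments it with the
    default (or given) break spec, scores each segment, and averages.
    """
    if strategy == "whole":
        emb = extract_embedding(w, extractor)
        return forward(emb, reg, mode="infer")
    if strategy != "segments":
        raise ValidationError(f"unknown prediction strategy {strategy!r}")
    segments = segment_passage(w, breaks)
    preds = [
        forward(extract_embedding(seg, extractor), reg, mode="infer")
        for seg in segment_audio(w, segments)
    ]
    mean = np.mean([p.as_array() for p in preds], axis=0)
    mean = np.clip(mean, SCORE_MIN, SCORE_MAX)
    return ScorePair(float(mean[0]), float(mean[1]))


def save_model(path, reg: RegressorWeights, cfg: TrainingConfig, extractor_fingerprint: str = "") -> None:
    """Bundle regressor weights, training config and extractor provenance."""
    arrays = {name: np.asarray(getattr(reg, name)) for name in reg.PARAM_NAMES}
    arrays.update({name: getattr(reg, name) for name in ("rm1", "rv1", "rm2", "rv2")})
    meta = {
        "emb_dim": reg.emb_dim,
        "config": {
            "learning_rate": cfg.learning_rate,
            "batch_size": cfg.batch_size,
            "epochs": cfg.epochs,
            "dropout": cfg.dropout,
            "loss_weights": list(cfg.loss_weights),
            "seed": cfg.seed,
        },
        "extractor_fingerprint": extractor_fingerprint,
    }
    arrays["__meta__"] = np.frombuffer(json.dumps(meta).encode("utf-8"), dtype=np.uint8)
    np.savez(path, **arrays)


def load_model(path) -> tuple[RegressorWeights, TrainingConfig, str]:
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode("utf-8"))
        reg = RegressorWeights.__new__(RegressorWeights)
        reg.emb_dim = int(meta["emb_dim"])
        for name in RegressorWeights.PARAM_NAMES + ("rm1", "rv1", "rm2", "rv2"):
            value = data[name]
            setattr(reg, name, float(value) if value.ndim == 0 else value)
    c = meta["config"]
    cfg = TrainingConfig(
        learning_rate=c["learning_rate"], batch_size=c["batch_size"], epochs=c["epochs"],
        dropout=c["dropout"], loss_weights=tuple(c["loss_weights"]), seed=c["seed"],
    )
    return reg, cfg, meta.get("extractor_fingerprint", "")
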
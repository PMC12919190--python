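"""Dual-branch ordinal severity model with a rank-consistent CORAL head.

The model scores one motor-task clip on the 0..K-1 ordinal severity scale.
A 1D CNN branch (conv -> batchnorm -> ReLU -> max-pool blocks, then global
average pooling) reads the task signal resampled to a fixed length; an MLP
branch reads the handcrafted kinematic features. Their embeddings are
concatenated and reduced to a single scalar score s; the CORAL head turns
s into K-1 cumulative logits g_k = s - b_k against strictly increasing
thresholds b_k, so the cumulative probabilities

    P(y > k) = sigmoid(s - b_k)

are non-increasing in k by construction. Expanding the cumulative
probabilities gives a class distribution over severities, whose mean
mu_hat and variance sigma_hat^2 feed the disagreement-aware loss

    L = Huber(mu_hat - t; delta) + lambda * sigma_hat^2,

where t is the rater-panel mean. The Huber term tracks the consensus
severity; the variance penalty discourages unwarranted spread, while
genuinely ambiguous clips can keep a broad predicted distribution at small
loss cost. Gradients are closed-form: with cumulative probabilities c_k,
mu = sum_k c_k and E[y^2] = sum_k (2k+1) c_k, so dL/dc_k =
Huber'(mu - t) + lambda * ((2k+1) - 2*mu).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from . import nn
from .errors import ConfigurationError, TrainingDivergenceError
from .kinematics import FEATURE_NAMES, FeatureVector, Signal, resample
from .consensus import RatingSummary

logger = logging.getLogger(__name__)


@dataclass
class ModelConfig:
    """Hyperparameters of the ordinal scorer.

    Defaults: K=5 severity classes, signals resampled to T=256 samples,
    three conv blocks of (channels, kernel, pool) = (16,7,2)/(32,5,2)/
    (64,3,2), MLP widths (32, 16), Adam at lr 1e-3, batch 32, 100 epochs.
    ``lambda_weight`` trades prediction accuracy against predicted
    variance; ``huber_delta`` is the Huber transition point in severity
    units.
    """

    num_classes: int = 5
    input_length: int = 256
    cnn_blocks: tuple[tuple[int, int, int], ...] = ((16, 7, 2), (32, 5, 2), (64, 3, 2))
    mlp_widths: tuple[int, ...] = (32, 16)
    lambda_weight: float = 0.1
    huber_delta: float = 1.0
    lr: float = 1e-3
    batch_size: int = 32
    epochs: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.num_classes < 2:
            raise ConfigurationError("need K >= 2 classes")
        if self.input_length < 8:
            raise ConfigurationError("need input length T >= 8")
        if self.lambda_weight < 0:
            raise ConfigurationError("lambda must be >= 0")
        if self.huber_delta <= 0:
            raise ConfigurationError("huber delta must be > 0")
        self.cnn_blocks = tuple(tuple(b) for b in self.cnn_blocks)
        self.mlp_widths = tuple(self.mlp_widths)


@dataclass(frozen=True)
class Prediction:
    """CORAL output for one clip.

    ``cumulative[k]`` is P(severity > k); ``class_probs`` the expanded
    distribution over 0..K-1; ``mean``/``variance`` its first two moments.
    """

    cumulative: np.ndarray
    class_probs: np.ndarray
    mean: float
    variance: float


def expand_distribution(cumulative: np.ndarray) -> Prediction:
    """Expand K-1 cumulative P(y > k) probabilities into a class distribution.

    Non-monotone inputs are repaired by a running maximum from the right
    (logged); values outside [0, 1] are a domain error.
    """
    cum = np.asarray(cumulative, dtype=float).copy()
    if cum.ndim != 1 or cum.size < 1:
        raise ValueError("cumulative must be a 1D array of K-1 probabilities")
    if ((cum < 0) | (cum > 1)).any():
        raise ValueError("cumulative probabilities must lie in [0, 1]")
    mono = np.maximum.accumulate(cum[::-1])[::-1]
    if not np.allclose(mono, cum):
        logger.warning("non-monotone cumulative probabilities; monotonized")
        cum = mono
    k1 = cum.size
    probs = np.empty(k1 + 1)
    probs[0] = 1.0 - cum[0]
    probs[1:k1] = cum[:-1] - cum[1:]
    probs[k1] = cum[-1]
    levels = np.arange(k1 + 1)
    mean = float(np.dot(levels, probs))
    variance = float(np.dot(probs, (levels - mean) ** 2))
    return Prediction(cum, probs, mean, variance)


def huber(e: float | np.ndarray, delta: float) -> float | np.ndarray:
    ae = np.abs(e)
    return np.where(ae <= delta, 0.5 * e * e, delta * (ae - 0.5 * delta))


def disagreement_loss(pred: Prediction, target: float, lambda_weight: float,
                      huber_delta: float = 1.0) -> float:
    """Huber(mu_hat, t) + lambda * sigma_hat^2 for one prediction."""
    h, v = disagreement_loss_terms(pred, target, lambda_weight, huber_delta)
    return h + v


def disagreement_loss_terms(pred: Prediction, target: float,
                            lambda_weight: float, huber_delta: float = 1.0
                            ) -> tuple[float, float]:
    """The two loss terms separately: (Huber term, lambda * variance)."""
    if lambda_weight < 0:
        raise ValueError("lambda must be >= 0")
    if huber_delta <= 0:
        raise ValueError("huber delta must be > 0")
    h = float(huber(pred.mean - target, huber_delta))
    return h, float(lambda_weight * pred.variance)


class OrdinalScorer:
    """The dual-branch CNN-MLP with ordered-threshold CORAL head."""

    def __init__(self, cfg: ModelConfig, n_features: int):
        if n_features < 1:
            raise ConfigurationError("need n_features >= 1")
        self.cfg = cfg
        self.n_features = n_features
        rng = np.random.default_rng(cfg.seed)

        layers: list[nn.Layer] = []
        in_ch = 1
        for channels, kernel, pool in cfg.cnn_blocks:
            layers += [nn.Conv1d(in_ch, channels, kernel, rng),
                       nn.BatchNorm1d(channels), nn.ReLU(), nn.MaxPool1d(pool)]
            in_ch = channels
        layers.append(nn.GlobalAvgPool())
        self.cnn = nn.Sequential(layers)

        mlp_layers: list[nn.Layer] = []
        w_in = n_features
        for width in cfg.mlp_widths:
            mlp_layers += [nn.Linear(w_in, width, rng), nn.ReLU()]
            w_in = width
        self.mlp = nn.Sequential(mlp_layers)

        self.head = nn.Linear(in_ch + w_in, 1, rng)
        # ordered thresholds b_k = theta0 + cumsum(exp(theta_k)), k >= 1;
        # init evenly spaced across the class range
        k1 = cfg.num_classes - 1
        self.theta = np.concatenate([[-(k1 - 1) / 2.0], np.zeros(k1 - 1)])
        self.theta_grad = np.zeros_like(self.theta)

        # feature standardization constants, fitted on the training split
        self.feat_center = np.zeros(n_features)
        self.feat_scale = np.ones(n_features)
        self.feat_fill = np.zeros(n_features)

    # -- parameter plumbing -------------------------------------------------
    def _handles(self) -> list[tuple[object, str]]:
        class _ThetaHolder:
            pass
        holder = _ThetaHolder()
        holder.params = {"theta": self.theta}
        holder.grads = {"theta": self.theta_grad}
        self._theta_holder = holder
        return (self.cnn.parameters() + self.mlp.parameters()
                + [(self.head, "w"), (self.head, "b"), (holder, "theta")])

    def set_training(self, training: bool) -> None:
        self.cnn.set_training(training)
        self.mlp.set_training(training)
        self.head.training = training

    def thresholds(self) -> np.ndarray:
        k1 = self.cfg.num_classes - 1
        b = np.empty(k1)
        b[0] = self.theta[0]
        if k1 > 1:
            b[1:] = self.theta[0] + np.cumsum(np.exp(self.theta[1:]))
        return b

    # -- forward / backward -------------------------------------------------
    def forward(self, signals: np.ndarray, feats: np.ndarray) -> np.ndarray:
        """(B, T) signals + (B, F) features -> (B, K-1) cumulative logits."""
        if signals.shape[1] != self.cfg.input_length:
            raise ValueError(f"signals must have length {self.cfg.input_length}")
        if feats.shape[1] != self.n_features:
            raise ValueError(f"expected {self.n_features} features")
        h_cnn = self.cnn.forward(signals[:, None, :])
        h_mlp = self.mlp.forward(feats)
        self._split = h_cnn.shape[1]
        h = np.concatenate([h_cnn, h_mlp], axis=1)
        s = self.head.forward(h)                     # (B, 1)
        return s - self.thresholds()[None, :]        # (B, K-1)

    def backward(self, dlogits: np.ndarray) -> None:
        ds = dlogits.sum(axis=1, keepdims=True)
        db = -dlogits.sum(axis=0)
        self.theta_grad[:] = 0.0
        self.theta_grad[0] = db.sum()
        if db.size > 1:
            # b_k depends on exp(theta_i) for 1 <= i <= k
            tail = np.cumsum(db[::-1])[::-1]
            self.theta_grad[1:] = np.exp(self.theta[1:]) * tail[1:]
        dh = self.head.backward(ds)
        self.cnn.backward(dh[:, :self._split])
        self.mlp.backward(dh[:, self._split:])

    # -- persistence --------------------------------------------------------
    def state_arrays(self) -> dict[str, np.ndarray]:
        out = {"theta": self.theta,
               "feat_center": self.feat_center,
               "feat_scale": self.feat_scale,
               "feat_fill": self.feat_fill}
        for i, (layer, name) in enumerate(self.cnn.parameters()):
            out[f"cnn_{i}_{name}"] = layer.params[name]
        for i, (layer, name) in enumerate(self.mlp.parameters()):
            out[f"mlp_{i}_{name}"] = layer.params[name]
        out["head_w"], out["head_b"] = self.head.params["w"], self.head.params["b"]
        for i, layer in enumerate(self.cnn.layers):
            if isinstance(layer, nn.BatchNorm1d):
                out[f"bn_{i}_mean"] = layer.running_mean
                out[f"bn_{i}_var"] = layer.running_var
        return out

    def load_state_arrays(self, state: dict[str, np.ndarray]) -> None:
        self.theta[:] = state["theta"]
        self.feat_center = state["feat_center"]
        self.feat_scale = state["feat_scale"]
        self.feat_fill = state["feat_fill"]
        for i, (layer, name) in enumerate(self.cnn.parameters()):
            layer.params[name][:] = state[f"cnn_{i}_{name}"]
        for i, (layer, name) in enumerate(self.mlp.parameters()):
            layer.params[name][:] = state[f"mlp_{i}_{name}"]
        self.head.params["w"][:] = state["head_w"]
        self.head.params["b"][:] = state["head_b"]
        for i, layer in enumerate(self.cnn.layers):
            if isinstance(layer, nn.BatchNorm1d):
                layer.running_mean[:] = state[f"bn_{i}_mean"]
                layer.running_var[:] = state[f"bn_{i}_var"]

    def save(self, path: str | Path) -> None:
        path = Path(path)
        np.savez(path, __config__=json.dumps({
            "cfg": asdict(self.cfg), "n_features": self.n_features}),
            **self.state_arrays())

    @classmethod
    def load(cls, path: str | Path) -> "OrdinalScorer":
        with np.load(Path(path).with_suffix(".npz") if not str(path).endswith(".npz")
                     else path, allow_pickle=False) as archive:
            meta = json.loads(str(archive["__config__"]))
            model = cls(ModelConfig(**meta["cfg"]), meta["n_features"])
            model.load_state_arrays({k: archive[k] for k in archive.files
                                     if k != "__config__"})
        return model


def build_model(cfg: ModelConfig, n_features: int) -> OrdinalScorer:
    """Construct an untrained ordinal scorer (seeded initialization)."""
    return OrdinalScorer(cfg, n_features)


# -- data preparation -------------------------------------------------------

def _prepare_signals(signals: Sequence[Signal], length: int) -> np.ndarray:
    """Resample to fixed length and z-score each signal individually.

    Per-signal standardization removes residual amplitude-offset scale so
    the CNN sees shape and rhythm; absolute amplitude information reaches
    the model through the feature branch.
    """
    out = np.empty((len(signals), length))
    for i, sig in enumerate(signals):
        x = resample(sig, length)
        sd = x.std()
        out[i] = (x - x.mean()) / (sd if sd > 1e-12 else 1.0)
    return out


def _feature_matrix(features: Sequence[FeatureVector]) -> np.ndarray:
    return np.stack([f.to_array() if isinstance(f, FeatureVector)
                     else np.asarray(f, dtype=float) for f in features])


def fit_feature_scaler(model: OrdinalScorer, feats: np.ndarray) -> None:
    """Median-impute NaNs and z-score features using training statistics."""
    any_finite = np.isfinite(feats).any(axis=0)
    fill = np.zeros(feats.shape[1])
    if any_finite.any():
        fill[any_finite] = np.nanmedian(feats[:, any_finite], axis=0)
    filled = np.where(np.isfinite(feats), feats, fill[None, :])
    center = filled.mean(axis=0)
    scale = filled.std(axis=0)
    scale = np.where(scale > 1e-12, scale, 1.0)
    model.feat_fill, model.feat_center, model.feat_scale = fill, center, scale


def apply_feature_scaler(model: OrdinalScorer, feats: np.ndarray) -> np.ndarray:
    filled = np.where(np.isfinite(feats), feats, model.feat_fill[None, :])
    return (filled - model.feat_center) / model.feat_scale


# -- training and inference -------------------------------------------------

def _batch_loss_and_grad(model: OrdinalScorer, logits: np.ndarray,
                         targets: np.ndarray) -> tuple[float, float, np.ndarray]:
    """Mean loss, mean Huber term, and d(mean loss)/d(logits)."""
    lam, delta = model.cfg.lambda_weight, model.cfg.huber_delta
    c = 1.0 / (1.0 + np.exp(-logits))               # (B, K-1) cumulative
    mu = c.sum(axis=1)
    m2 = (c * (2 * np.arange(c.shape[1]) + 1)[None, :]).sum(axis=1)
    var = m2 - mu ** 2
    e = mu - targets
    h = huber(e, delta)
    loss = float(np.mean(h + lam * var))
    dh = np.clip(e, -delta, delta)                   # Huber derivative
    dc = dh[:, None] + lam * ((2 * np.arange(c.shape[1]) + 1)[None, :]
                              - 2 * mu[:, None])
    dlogits = dc * c * (1 - c) / len(targets)
    return loss, float(np.mean(h)), dlogits


def train(dataset: Sequence[tuple[Signal, FeatureVector, RatingSummary]],
          cfg: ModelConfig) -> tuple[OrdinalScorer, dict]:
    """Train an ordinal scorer on (signal, features, panel-summary) samples.

    Targets are the rater-panel means. Adam with the configured learning
    rate, batch size and epoch count; deterministic given ``cfg.seed``.
    Returns the trained model and a history dict with per-epoch mean total
    loss and Huber term.
    """
    if not dataset:
        raise ValueError("empty training dataset")
    signals, feats, summaries = zip(*dataset)
    X = _prepare_signals(signals, cfg.input_length)
    F_raw = _feature_matrix(feats)
    t = np.array([s.mean if isinstance(s, RatingSummary) else float(s)
                  for s in summaries])

    model = build_model(cfg, F_raw.shape[1])
    fit_feature_scaler(model, F_raw)
    F = apply_feature_scaler(model, F_raw)

    rng = np.random.default_rng(cfg.seed + 1)
    opt = nn.Adam(model._handles(), lr=cfg.lr)
    model.set_training(True)
    history = {"loss": [], "huber": []}
    n = len(dataset)
    for epoch in range(cfg.epochs):
        order = rng.permutation(n)
        ep_loss, ep_huber, n_batches = 0.0, 0.0, 0
        for start in range(0, n, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            logits = model.forward(X[idx], F[idx])
            loss, h, dlogits = _batch_loss_and_grad(model, logits, t[idx])
            if not np.isfinite(loss):
                raise TrainingDivergenceError(
                    f"non-finite loss at epoch {epoch}")
            model.backward(dlogits)
            opt.step()
            ep_loss += loss
            ep_huber += h
            n_batches += 1
        history["loss"].append(ep_loss / n_batches)
        history["huber"].append(ep_huber / n_batches)
    model.set_training(False)
    return model, history


def predict(model: OrdinalScorer, signal: Signal,
            features: FeatureVector) -> Prediction:
    """Score a single clip: logits -> sigmoid -> cumulative -> distribution."""
    return predict_batch(model, [signal], [features])[0]


def predict_batch(model: OrdinalScorer, signals: Sequence[Signal],
                  features: Sequence[FeatureVector]) -> list[Prediction]:
    X = _prepare_signals(signals, model.cfg.input_length)
    F = apply_feature_scaler(model, _feature_matrix(features))
    model.set_training(False)
    logits = model.forward(X, F)
    cum = 1.0 / (1.0 + np.exp(-logits))
    return [expand_distribution(row) for row in cum]
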
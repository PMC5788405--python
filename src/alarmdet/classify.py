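"""Frame-level alarm / non-alarm classifiers and threshold selection.

Two model families share one contract (:class:`FramePosteriors`):

* a generative detector with one diagonal-covariance Gaussian per class
  (a single component proved sufficient for these low-dimensional,
  class-specific features);
* a discriminative single-hidden-layer network (32 logistic hidden units,
  1 logistic output) whose hidden layer is pretrained as a
  Gaussian-Bernoulli restricted Boltzmann machine with one-step contrastive
  divergence, then fine-tuned by backpropagation with momentum and weight
  decay on class-balanced, mean-variance normalised data.

Decision thresholds are chosen at the equal-error-rate point of the training
scores (miss rate = false-alarm rate).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .spectral import FeatureSequence

log = logging.getLogger(__name__)

__all__ = [
    "GmmDetector",
    "NnDetector",
    "NnHyperparams",
    "FramePosteriors",
    "EerResult",
    "train_gmm_detector",
    "train_nn_detector",
    "frame_posteriors",
    "decision_scores",
    "select_eer_threshold",
]

VAR_FLOOR = 1e-6
_LOG_FLOOR = 1e-300


@dataclass
class GmmDetector:
    """Single diagonal Gaussian per class (alarm / non-alarm)."""

    mean_alarm: np.ndarray
    var_alarm: np.ndarray
    mean_nonalarm: np.ndarray
    var_nonalarm: np.ndarray
    feature_kind: str = ""
    class_id: str = ""

    @property
    def dim(self) -> int:
        return len(self.mean_alarm)

    def loglik(self, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        return (
            _diag_gauss_loglik(X, self.mean_alarm, self.var_alarm),
            _diag_gauss_loglik(X, self.mean_nonalarm, self.var_nonalarm),
        )


@dataclass
class NnHyperparams:
    """Training hyperparameters for the RBM-pretrained network."""

    hidden_units: int = 32
    batch_size: int = 10
    rbm_learning_rate: float = 0.001
    rbm_epochs: int = 80
    rbm_momentum: float = 0.9
    rbm_weight_decay: float = 2e-7
    learning_rate: float = 0.001
    epochs: int = 50
    momentum: float = 0.9
    weight_decay: float = 1.2e-4


@dataclass
class NnDetector:
    """One-hidden-layer logistic network with stored normalisation statistics."""

    W1: np.ndarray  # (dim, hidden)
    b1: np.ndarray
    w2: np.ndarray  # (hidden,)
    b2: float
    norm_mean: np.ndarray
    norm_std: np.ndarray
    feature_kind: str = ""
    class_id: str = ""
    training_log: dict = field(default_factory=dict, repr=False)

    @property
    def dim(self) -> int:
        return self.W1.shape[0]

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        Xn = (X - self.norm_mean) / self.norm_std
        h = _sigmoid(Xn @ self.W1 + self.b1)
        return _sigmoid(h @ self.w2 + self.b2)


@dataclass
class FramePosteriors:
    """Per-frame log-posteriors; exp(log_alarm) + exp(log_nonalarm) == 1."""

    log_alarm: np.ndarray
    log_nonalarm: np.ndarray

    def __post_init__(self) -> None:
        if self.log_alarm.shape != self.log_nonalarm.shape:
            raise ValueError("posterior arrays must have equal shape")

    @property
    def n_frames(self) -> int:
        return len(self.log_alarm)

    @property
    def contrast(self) -> np.ndarray:
        """P_A - P_NA, the frame-level decision score."""
        return self.log_alarm - self.log_nonalarm


@dataclass(frozen=True)
class EerResult:
    threshold: float
    miss_rate: float
    false_alarm_rate: float

    @property
    def eer(self) -> float:
        return 0.5 * (self.miss_rate + self.false_alarm_rate)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -500, 500)))


def _diag_gauss_loglik(X: np.ndarray, mean: np.ndarray, var: np.ndarray) -> np.ndarray:
    diff = X - mean
    return -0.5 * (np.sum(np.log(2.0 * np.pi * var)) + np.sum(diff**2 / var, axis=1))


def _as_matrix(features: FeatureSequence | np.ndarray) -> np.ndarray:
    if isinstance(features, FeatureSequence):
        return features.vectors
    return np.asarray(features, dtype=float)


def train_gmm_detector(
    features: FeatureSequence | np.ndarray,
    frame_labels: np.ndarray,
    feature_kind: str = "",
    class_id: str = "",
) -> GmmDetector:
    """Closed-form maximum-likelihood fit: per-class sample mean and variance."""
    X = _as_matrix(features)
    y = np.asarray(frame_labels).astype(bool)
    if y.sum() < 2 or (~y).sum() < 2:
        raise ValueError("insufficient class data: need >= 2 frames per class")
    Xa, Xn = X[y], X[~y]
    return GmmDetector(
        mean_alarm=Xa.mean(axis=0),
        var_alarm=np.maximum(Xa.var(axis=0), VAR_FLOOR),
        mean_nonalarm=Xn.mean(axis=0),
        var_nonalarm=np.maximum(Xn.var(axis=0), VAR_FLOOR),
        feature_kind=feature_kind or getattr(features, "feature_kind", ""),
        class_id=class_id,
    )


def _balance_classes(
    X: np.ndarray, y: np.ndarray, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Random down-sampling of the majority class to the minority count."""
    pos = np.nonzero(y)[0]
    neg = np.nonzero(~y)[0]
    n = min(len(pos), len(neg))
    pos = rng.choice(pos, n, replace=False) if len(pos) > n else pos
    neg = rng.choice(neg, n, replace=False) if len(neg) > n else neg
    idx = np.concatenate([pos, neg])
    idx.sort()
    return X[idx], y[idx]


def _rbm_pretrain(
    X: np.ndarray, hp: NnHyperparams, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """CD-1 training of a Gaussian-Bernoulli RBM on standardised data.

    Visible units are linear with unit variance (the data is standardised),
    hidden units are logistic.  Returns the hidden-layer weights and biases.
    """
    d = X.shape[1]
    W = rng.uniform(-0.01, 0.01, size=(d, hp.hidden_units))
    b_h = np.zeros(hp.hidden_units)
    b_v = np.zeros(d)
    vel_W = np.zeros_like(W)
    vel_bh = np.zeros_like(b_h)
    vel_bv = np.zeros_like(b_v)
    n = len(X)
    for _ in range(hp.rbm_epochs):
        order = rng.permutation(n)
        for start in range(0, n, hp.batch_size):
            v0 = X[order[start : start + hp.batch_size]]
            m = len(v0)
            h0 = _sigmoid(v0 @ W + b_h)
            h_sample = (rng.random(h0.shape) < h0).astype(float)
            v1 = h_sample @ W.T + b_v  # Gaussian visible: mean-field reconstruction
            h1 = _sigmoid(v1 @ W + b_h)
            gW = (v0.T @ h0 - v1.T @ h1) / m - hp.rbm_weight_decay * W
            gbh = (h0 - h1).mean(axis=0)
            gbv = (v0 - v1).mean(axis=0)
            vel_W = hp.rbm_momentum * vel_W + hp.rbm_learning_rate * gW
            vel_bh = hp.rbm_momentum * vel_bh + hp.rbm_learning_rate * gbh
            vel_bv = hp.rbm_momentum * vel_bv + hp.rbm_learning_rate * gbv
            W += vel_W
            b_h += vel_bh
            b_v += vel_bv
    return W, b_h


def train_nn_detector(
    features: FeatureSequence | np.ndarray,
    frame_labels: np.ndarray,
    hp: NnHyperparams | None = None,
    rng_seed: int = 0,
    feature_kind: str = "",
    class_id: str = "",
) -> NnDetector:
    """Balance -> normalise -> RBM pretrain -> supervised backpropagation."""
    hp = hp or NnHyperparams()
    X = _as_matrix(features)
    y = np.asarray(frame_labels).astype(bool)
    if y.sum() < 1 or (~y).sum() < 1:
        raise ValueError("both classes must be present")
    rng = np.random.default_rng(rng_seed)
    Xb, yb = _balance_classes(X, y, rng)
    mean = Xb.mean(axis=0)
    std = np.maximum(Xb.std(axis=0), 1e-6)
    Xn = (Xb - mean) / std
    t = yb.astype(float)

    W1, b1 = _rbm_pretrain(Xn, hp, rng)
    w2 = rng.uniform(-0.01, 0.01, size=hp.hidden_units)
    b2 = 0.0
    vW1 = np.zeros_like(W1)
    vb1 = np.zeros_like(b1)
    vw2 = np.zeros_like(w2)
    vb2 = 0.0
    n = len(Xn)
    losses = []
    for _ in range(hp.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, hp.batch_size):
            idx = order[start : start + hp.batch_size]
            x, tt = Xn[idx], t[idx]
            m = len(x)
            h = _sigmoid(x @ W1 + b1)
            p = _sigmoid(h @ w2 + b2)
            pc = np.clip(p, 1e-12, 1.0 - 1e-12)
            epoch_loss += float(-np.sum(tt * np.log(pc) + (1 - tt) * np.log(1 - pc)))
            dz2 = p - tt  # cross-entropy + logistic output
            gw2 = h.T @ dz2 / m + hp.weight_decay * w2
            gb2 = dz2.mean()
            dh = np.outer(dz2, w2) * h * (1.0 - h)
            gW1 = x.T @ dh / m + hp.weight_decay * W1
            gb1 = dh.mean(axis=0)
            vw2 = hp.momentum * vw2 - hp.learning_rate * gw2
            vb2 = hp.momentum * vb2 - hp.learning_rate * gb2
            vW1 = hp.momentum * vW1 - hp.learning_rate * gW1
            vb1 = hp.momentum * vb1 - hp.learning_rate * gb1
            w2 += vw2
            b2 += vb2
            W1 += vW1
            b1 += vb1
        if not np.isfinite(epoch_loss):
            raise RuntimeError("training diverged; reduce learning rate")
        losses.append(epoch_loss / n)
    log.info("NN trained: %d balanced frames, final loss %.4f", n, losses[-1])
    return NnDetector(
        W1=W1,
        b1=b1,
        w2=w2,
        b2=b2,
        norm_mean=mean,
        norm_std=std,
        feature_kind=feature_kind or getattr(features, "feature_kind", ""),
        class_id=class_id,
        training_log={"losses": losses, "n_balanced": n},
    )


def frame_posteriors(
    detector: GmmDetector | NnDetector,
    features: FeatureSequence | np.ndarray,
    posterior_floor: float = 1e-6,
) -> FramePosteriors:
    """Normalised per-frame log-posteriors under equal class priors.

    Posteriors are clipped to ``[posterior_floor, 1 - posterior_floor]``,
    which bounds the per-frame logit so that no single frame can dominate the
    temporal aggregation downstream.
    """
    X = _as_matrix(features)
    if X.shape[1] != detector.dim:
        raise ValueError(f"feature/model dimension mismatch: {X.shape[1]} vs {detector.dim}")
    if isinstance(detector, GmmDetector):
        la, ln = detector.loglik(X)
        p = np.exp(la - np.logaddexp(la, ln))  # equal priors cancel
    else:
        p = detector.predict_proba(X)
    p = np.clip(p, posterior_floor, 1.0 - posterior_floor)
    return FramePosteriors(log_alarm=np.log(p), log_nonalarm=np.log1p(-p))


def decision_scores(
    detector: GmmDetector | NnDetector, features: FeatureSequence | np.ndarray
) -> np.ndarray:
    """Per-frame score swept for the EER threshold.

    Log-likelihood ratio for the Gaussian detector, network output for the NN.
    """
    X = _as_matrix(features)
    if isinstance(detector, GmmDetector):
        la, ln = detector.loglik(X)
        return la - ln
    return detector.predict_proba(X)


def select_eer_threshold(scores: np.ndarray, frame_labels: np.ndarray) -> EerResult:
    """Threshold minimising |MR - FAR| over midpoints of sorted distinct scores.

    The decision rule is ``score >= threshold -> alarm``.  Ties pick the lower
    threshold.
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(frame_labels).astype(bool)
    if y.all() or not y.any():
        raise ValueError("cannot compute EER: both classes required")
    uniq = np.unique(scores)
    if len(uniq) == 1:
        cands = np.array([uniq[0]])
    else:
        cands = 0.5 * (uniq[:-1] + uniq[1:])
    pos = np.sort(scores[y])
    neg = np.sort(scores[~y])
    # misses: alarms with score < threshold; false alarms: non-alarms >= threshold
    n_miss = np.searchsorted(pos, cands, side="left")
    n_fa = len(neg) - np.searchsorted(neg, cands, side="left")
    mr = n_miss / len(pos)
    far = n_fa / len(neg)
    best = int(np.argmin(np.abs(mr - far)))  # argmin returns the first (lowest) tie
    return EerResult(threshold=float(cands[best]), miss_rate=float(mr[best]), false_alarm_rate=float(far[best]))
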
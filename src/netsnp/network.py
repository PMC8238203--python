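"""Feed-forward pattern network trained by scaled conjugate gradient (SCG).

The classifier is a fully connected feed-forward network (default two
hidden layers of 50 and 10 tanh units, softmax output) trained full-batch
by Moller's scaled conjugate gradient: conjugate search directions with
curvature estimated from a forward difference of the gradient (step
``wt_sigma``/|direction|) and a Levenberg-Marquardt style regulator
``lambda`` adapted from the comparison parameter, so no line search is
needed.  The performance function is a regularised cross-entropy,

    perf = (1 - reg) * mean CE  +  reg * mean(w^2),

with biases excluded from the penalty.  Training stops at ``max_epochs``
epochs, when the gradient norm falls under ``min_grad``, or after
``max_fails`` consecutive epochs of rising validation performance; the
weights from the best validation epoch are returned and are immutable
thereafter -- applying the network never changes it.

The network emits a classifier value (CV) per individual, P(case) - 0.5,
lying in [-0.5, +0.5]: -0.5 labels a confident control call and +0.5 a
confident case call.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .store import GenotypeStore

logger = logging.getLogger("netsnp")


@dataclass
class NetConfig:
    """Architecture and SCG training hyper-parameters."""

    hidden_layers: tuple[int, ...] = (50, 10)
    max_epochs: int = 1000
    min_grad: float = 1e-6
    max_fails: int = 10
    wt_sigma: float = 5e-5      # step scale for the second-derivative estimate
    lambda0: float = 5e-7       # initial Hessian-indefiniteness regulator
    reg: float = 0.1            # performance ratio: (1-reg)*CE + reg*mean(w^2)
    seed: int = 0

    def __post_init__(self):
        if not self.hidden_layers:
            raise ValueError("at least one hidden layer is required")
        if not (0 <= self.reg < 1):
            raise ValueError("reg must lie in [0, 1)")
        for name in ("max_epochs", "min_grad", "max_fails", "wt_sigma", "lambda0"):
            if not getattr(self, name) >= 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass
class FeatureScaling:
    """Affine map of each genotype-code feature onto [-1, 1].

    Fitted from training-set minima/maxima; constant features map to 0;
    out-of-range values at application time are clipped (and logged).
    """

    lo: np.ndarray
    hi: np.ndarray

    @classmethod
    def fit(cls, x: np.ndarray) -> "FeatureScaling":
        return cls(lo=x.min(axis=0), hi=x.max(axis=0))

    def apply(self, x: np.ndarray) -> np.ndarray:
        span = self.hi - self.lo
        with np.errstate(invalid="ignore", divide="ignore"):
            scaled = np.where(span > 0, 2.0 * (x - self.lo) / np.where(span > 0, span, 1.0) - 1.0, 0.0)
        n_clip = int(((scaled < -1) | (scaled > 1)).sum())
        if n_clip:
            logger.debug("clipped %d feature cells outside the training range", n_clip)
        return np.clip(scaled, -1.0, 1.0)


def build_feature_matrix(store: GenotypeStore, ids: Sequence[int],
                         feature_loci: Sequence[int],
                         labels: Optional[np.ndarray] = None,
                         scaling: Optional[FeatureScaling] = None):
    """Scaled feature matrix (and labels) for the given samples and loci.

    Cell values start as genotype codes {0,1,2} with missing mapped to 0,
    then each feature is affinely mapped to [-1,1] using training minima
    and maxima (``scaling`` fitted here when not supplied).
    """
    ids = np.asarray(ids, dtype=int)
    if ids.size == 0:
        raise ValueError("empty id list")
    codes = store.feature_codes(ids, feature_loci)
    if scaling is None:
        scaling = FeatureScaling.fit(codes)
    x = scaling.apply(codes)
    if labels is None:
        return x, scaling
    return x, np.asarray(labels), scaling


# ----------------------------------------------------------------------
# Parameter flattening


def _init_params(layer_sizes, rng):
    """Scaled-uniform initialisation: U(-s, s) with s^2 = 6/(fan_in+fan_out)."""
    params = []
    for n_in, n_out in zip(layer_sizes[:-1], layer_sizes[1:]):
        s = np.sqrt(6.0 / (n_in + n_out))
        params.append((rng.uniform(-s, s, size=(n_in, n_out)), np.zeros(n_out)))
    return params


def _flatten(params):
    return np.concatenate([a.ravel() for w, b in params for a in (w, b)])


def _unflatten(flat, layer_sizes):
    params, k = [], 0
    for n_in, n_out in zip(layer_sizes[:-1], layer_sizes[1:]):
        w = flat[k:k + n_in * n_out].reshape(n_in, n_out); k += n_in * n_out
        b = flat[k:k + n_out]; k += n_out
        params.append((w, b))
    return params


def _weight_mask(layer_sizes):
    """Boolean mask over the flat vector marking weights (True) vs biases."""
    parts = []
    for n_in, n_out in zip(layer_sizes[:-1], layer_sizes[1:]):
        parts.append(np.ones(n_in * n_out, dtype=bool))
        parts.append(np.zeros(n_out, dtype=bool))
    return np.concatenate(parts)


def _forward(flat, layer_sizes, x):
    params = _unflatten(flat, layer_sizes)
    acts = [x]
    h = x
    for w, b in params[:-1]:
        h = np.tanh(h @ w + b)
        acts.append(h)
    w, b = params[-1]
    z = h @ w + b
    z -= z.max(axis=1, keepdims=True)
    ez = np.exp(z)
    y = ez / ez.sum(axis=1, keepdims=True)
    acts.append(y)
    return acts


def loss_and_gradient(flat: np.ndarray, layer_sizes: Sequence[int],
                      x: np.ndarray, t: np.ndarray, reg: float):
    """Regularised cross-entropy performance and its exact gradient.

    ``t`` is a one-hot target matrix.  CE is averaged over samples; the
    penalty is the mean squared weight (biases excluded).
    """
    n = x.shape[0]
    acts = _forward(flat, layer_sizes, x)
    y = acts[-1]
    if not np.isfinite(y).all():
        raise FloatingPointError("non-finite activations during forward pass")
    eps = np.finfo(float).tiny
    ce = -np.sum(t * np.log(y + eps)) / n
    mask = _weight_mask(layer_sizes)
    n_w = int(mask.sum())
    msw = float(flat[mask] @ flat[mask]) / n_w
    perf = (1.0 - reg) * ce + reg * msw

    params = _unflatten(flat, layer_sizes)
    grads = [None] * len(params)
    delta = (y - t) * ((1.0 - reg) / n)          # softmax + CE
    for li in range(len(params) - 1, -1, -1):
        a_prev = acts[li]
        grads[li] = (a_prev.T @ delta, delta.sum(axis=0))
        if li > 0:
            w, _ = params[li]
            delta = (delta @ w.T) * (1.0 - acts[li] ** 2)
    g = _flatten(grads)
    g[mask] += (2.0 * reg / n_w) * flat[mask]
    return perf, g


# ----------------------------------------------------------------------


@dataclass
class TrainedNet:
    """Immutable trained network with its feature list and scaling."""

    layer_sizes: tuple[int, ...]
    flat_weights: np.ndarray
    feature_loci: tuple[int, ...]
    scaling: FeatureScaling
    reg: float
    history: list  # (epoch, train perf, validation perf, grad norm)
    stop_reason: str

    def __post_init__(self):
        self.flat_weights = np.asarray(self.flat_weights, dtype=float)
        self.flat_weights.setflags(write=False)

    @property
    def n_classes(self) -> int:
        return self.layer_sizes[-1]

    def probabilities(self, x: np.ndarray) -> np.ndarray:
        if x.shape[1] != self.layer_sizes[0]:
            raise ValueError(
                f"feature count mismatch: net expects {self.layer_sizes[0]}, got {x.shape[1]}")
        return _forward(self.flat_weights, self.layer_sizes, x)[-1]

    def predict_cv(self, x: np.ndarray) -> np.ndarray:
        """Classifier value per row: P(case) - 0.5, in [-0.5, +0.5]."""
        if self.n_classes != 2:
            raise ValueError("CV is defined for the 2-class case/control head")
        return self.probabilities(x)[:, 1] - 0.5

    def predict_proba_case(self, x: np.ndarray) -> np.ndarray:
        """[0,1]-normalised CV (P(case)), the scale used for ROC analysis."""
        return self.probabilities(x)[:, 1]

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({
                "layer_sizes": [int(v) for v in self.layer_sizes],
                "flat_weights": self.flat_weights.tolist(),
                "feature_loci": [int(v) for v in self.feature_loci],
                "scaling_lo": self.scaling.lo.tolist(),
                "scaling_hi": self.scaling.hi.tolist(),
                "reg": self.reg,
                "history": [[None if v is None else float(v) for v in h]
                            for h in self.history],
                "stop_reason": self.stop_reason,
            }, fh)

    @classmethod
    def from_json(cls, path) -> "TrainedNet":
        with open(path) as fh:
            d = json.load(fh)
        return cls(tuple(d["layer_sizes"]), np.array(d["flat_weights"]),
                   tuple(d["feature_loci"]),
                   FeatureScaling(np.array(d["scaling_lo"]), np.array(d["scaling_hi"])),
                   d["reg"], [tuple(h) for h in d["history"]], d["stop_reason"])


_LAMBDA_MIN, _LAMBDA_MAX = 1e-15, 1e15


def train_patternnet(x_train: np.ndarray, y_train: np.ndarray,
                     x_val: Optional[np.ndarray], y_val: Optional[np.ndarray],
                     config: NetConfig,
                     feature_loci: Sequence[int] = (),
                     scaling: Optional[FeatureScaling] = None,
                     n_classes: Optional[int] = None) -> TrainedNet:
    """Train by scaled conjugate gradient with validation early stopping.

    ``y_*`` are integer class labels (0 = control, 1 = case for the binary
    head; K-class labels for e.g. the cohort-identity experiment).
    """
    y_train = np.asarray(y_train, dtype=int)
    classes = np.unique(y_train)
    if classes.size < 2:
        raise ValueError("training labels must contain at least 2 classes")
    k = int(n_classes or classes.max() + 1)
    layer_sizes = (x_train.shape[1], *config.hidden_layers, k)
    use_val = config.max_fails > 0
    if use_val and (x_val is None or len(x_val) == 0):
        raise ValueError("validation set required while max_fails is active")

    t_train = np.eye(k)[y_train]
    t_val = np.eye(k)[np.asarray(y_val, dtype=int)] if x_val is not None and len(x_val) else None
    rng = np.random.default_rng(config.seed)
    w = _flatten(_init_params(layer_sizes, rng))
    n_params = w.size

    def perf_grad(v):
        return loss_and_gradient(v, layer_sizes, x_train, t_train, config.reg)

    def val_perf(v):
        p, _ = loss_and_gradient(v, layer_sizes, x_val, t_val, config.reg)
        return p

    perf, grad = perf_grad(w)
    r = -grad
    p = r.copy()
    success = True
    lam, lam_bar = config.lambda0, 0.0
    best_w, best_perf = w.copy(), perf
    best_val = val_perf(w) if t_val is not None else np.inf
    best_val_w = w.copy()
    fails = 0
    history = [(0, perf, best_val if t_val is not None else None,
                float(np.linalg.norm(grad)))]
    stop_reason = "max_epochs"
    delta_k = 1.0

    for epoch in range(1, config.max_epochs + 1):
        p_norm2 = float(p @ p)
        p_norm = np.sqrt(p_norm2)
        if not np.isfinite(p_norm) or p_norm == 0:
            p = r.copy()
            p_norm2 = float(p @ p)
            p_norm = np.sqrt(p_norm2)
            if p_norm == 0:
                stop_reason = "min_grad"
                break
        if success:
            sigma_k = config.wt_sigma / p_norm
            _, grad_plus = perf_grad(w + sigma_k * p)
            s = (grad_plus - grad) / sigma_k
            delta_k = float(p @ s)
        delta_k_reg = delta_k + (lam - lam_bar) * p_norm2
        if delta_k_reg <= 0:
            lam_bar = 2.0 * (lam - delta_k_reg / p_norm2)
            delta_k_reg = -delta_k_reg + lam * p_norm2
            lam = lam_bar
        mu = float(p @ r)
        alpha = mu / delta_k_reg
        perf_new, grad_new = perf_grad(w + alpha * p)
        comparison = 2.0 * delta_k_reg * (perf - perf_new) / (mu * mu)
        if comparison >= 0:
            w = w + alpha * p
            perf, grad = perf_new, grad_new
            r_new = -grad
            lam_bar = 0.0
            success = True
            if epoch % n_params == 0:
                p = r_new.copy()           # periodic restart to steepest descent
            else:
                beta = (float(r_new @ r_new) - float(r_new @ r)) / mu
                p = r_new + beta * p
            r = r_new
            if comparison >= 0.75:
                lam = max(lam / 4.0, _LAMBDA_MIN)
        else:
            lam_bar = lam
            success = False
        if comparison < 0.25:
            lam = min(lam + delta_k_reg * (1.0 - comparison) / p_norm2, _LAMBDA_MAX)

        gnorm = float(np.linalg.norm(grad))
        vperf = None
        if t_val is not None:
            vperf = val_perf(w)
            if vperf < best_val:
                best_val = vperf
                best_val_w = w.copy()
                fails = 0
            else:
                fails += 1
        history.append((epoch, perf, vperf, gnorm))
        if perf < best_perf:
            best_perf, best_w = perf, w.copy()
        if gnorm < config.min_grad:
            stop_reason = "min_grad"
            break
        if use_val and fails >= config.max_fails:
            stop_reason = "max_fails"
            break

    final = best_val_w if (use_val and t_val is not None) else best_w
    return TrainedNet(layer_sizes=layer_sizes, flat_weights=final,
                      feature_loci=tuple(feature_loci),
                      scaling=scaling if scaling is not None
                      else FeatureScaling(np.zeros(x_train.shape[1]) - 1,
                                          np.zeros(x_train.shape[1]) + 1),
                      reg=config.reg, history=history, stop_reason=stop_reason)
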
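"""Maximum-likelihood committor models trained on shooting outcomes.

Each one-way trial fired from a configuration with fresh thermal velocities
is a Bernoulli experiment: it commits to state A or state B.  Modelling the
committor through a real log-predictor q(x|w),

    p_B(x) = 1 / (1 + exp(-q(x|w))),

the negative log-likelihood of k recorded trials is

    l(w | theta) = sum_i log(1 + exp(s_i * q(x_i | w))),

with s_i = +1 if trial i entered A first and s_i = -1 if it entered B first.
Minimizing l is a maximum-likelihood committor estimate; with a linear q it
reduces to logistic regression, and the same loss written for aggregated
counts (n_A, n_B) per configuration is the binomial log-likelihood up to the
fixed combinatorial coefficient.

The network is a pyramid: hidden widths decay geometrically from the input
width to a final width, each block followed by tanh and a dropout whose rate
decays with the same ratio, and the last layer is a single linear neuron
producing q.  Training uses full-batch Adam; all randomness is generator-
seeded so runs are reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Protocol, Sequence

import numpy as np
from scipy.integrate import cumulative_trapezoid

from .dynamics import PhasePoint
from .potentials import Potential

__all__ = [
    "AnalyticCommittor1D",
    "CommittorModel",
    "ConstantCommittor",
    "LinearCommittor",
    "NeuralCommittor",
    "PyramidArchitecture",
    "ShootingRecord",
    "TrainingSet",
    "build_pyramid",
    "gradient_attribution",
    "nll_from_counts",
    "shooting_nll",
    "sigmoid_link",
    "softmax_link",
    "transfer_retrain_last_layer",
]


# ---------------------------------------------------------------- links/loss

def sigmoid_link(q: np.ndarray | float) -> np.ndarray | float:
    """p_B = 1/(1+e^-q), overflow-safe for any finite q."""
    q = np.asarray(q, float)
    out = np.empty_like(q)
    pos = q >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-q[pos]))
    eq = np.exp(q[~pos])
    out[~pos] = eq / (1.0 + eq)
    return out if out.ndim else float(out)


def softmax_link(q_vec: np.ndarray) -> np.ndarray:
    """Normalized state probabilities for the N-state generalization."""
    q = np.asarray(q_vec, float)
    z = np.exp(q - q.max(axis=-1, keepdims=True))
    return z / z.sum(axis=-1, keepdims=True)


def _softplus(z: np.ndarray) -> np.ndarray:
    return np.logaddexp(0.0, z)


def shooting_nll(q: np.ndarray, s: np.ndarray) -> float:
    """l = sum log(1 + e^{s q}) over per-trial records."""
    q = np.asarray(q, float)
    s = np.asarray(s, float)
    if q.size == 0:
        raise ValueError("empty training data")
    return float(np.sum(_softplus(s * q)))


def nll_from_counts(q: np.ndarray, n_A: np.ndarray, n_B: np.ndarray) -> float:
    """Binomial form: -sum [n_A log(1-p_B) + n_B log p_B], coefficient dropped.

    Identical to ``shooting_nll`` expanded over individual trials since
    -log(1-p_B) = softplus(q) and -log p_B = softplus(-q).
    """
    q = np.asarray(q, float)
    if q.size == 0:
        raise ValueError("empty training data")
    return float(np.sum(np.asarray(n_A, float) * _softplus(q)
                        + np.asarray(n_B, float) * _softplus(-q)))


# ---------------------------------------------------------------- records

@dataclass(frozen=True)
class ShootingRecord:
    """One Bernoulli datum: features of the shooting point and the outcome.

    outcome is +1 if the trial entered A first, -1 if it entered B first.
    Aggregated data may instead carry counts = (n_A, n_B); exactly one of
    outcome/counts is set.
    """

    features: np.ndarray
    outcome: int | None = None
    counts: tuple[int, int] | None = None
    step_index: int = 0
    chain_id: str = "0"

    def __post_init__(self):
        object.__setattr__(self, "features", np.atleast_1d(np.asarray(self.features, float)))
        if (self.outcome is None) == (self.counts is None):
            raise ValueError("exactly one of outcome/counts must be given")
        if self.outcome is not None and self.outcome not in (-1, 1):
            raise ValueError("outcome must be +1 or -1")
        if self.counts is not None and (self.counts[0] < 0 or self.counts[1] < 0):
            raise ValueError("counts must be non-negative")


class TrainingSet:
    """Append-only log of shooting records with constant feature width."""

    def __init__(self, records: Sequence[ShootingRecord] = ()):
        self._records: list[ShootingRecord] = []
        for r in records:
            self.append(r)

    def append(self, record: ShootingRecord) -> None:
        if self._records and record.features.shape != self._records[0].features.shape:
            raise ValueError("feature dimensionality must be constant")
        self._records.append(record)

    def extend(self, records: Sequence[ShootingRecord]) -> None:
        for r in records:
            self.append(r)

    def __len__(self) -> int:
        return len(self._records)

    def __iter__(self):
        return iter(self._records)

    def __getitem__(self, i):
        return self._records[i]

    @property
    def n_features(self) -> int:
        if not self._records:
            raise ValueError("empty training set")
        return self._records[0].features.shape[0]

    def to_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        """Expand to per-trial arrays (X, s); counted records are unrolled."""
        if not self._records:
            raise ValueError("empty training set")
        xs, ss = [], []
        for r in self._records:
            if r.outcome is not None:
                xs.append(r.features)
                ss.append(r.outcome)
            else:
                nA, nB = r.counts
                for _ in range(nA):
                    xs.append(r.features)
                    ss.append(1)
                for _ in range(nB):
                    xs.append(r.features)
                    ss.append(-1)
        return np.stack(xs), np.array(ss, float)


# ---------------------------------------------------------------- model API

class CommittorModel(Protocol):
    def q(self, X: np.ndarray) -> np.ndarray: ...


def predict_pB(model: "CommittorModel", X: np.ndarray) -> np.ndarray:
    return sigmoid_link(model.q(X))


def model_nll(model: "CommittorModel", X: np.ndarray, s: np.ndarray) -> float:
    return shooting_nll(model.q(X), s)


@dataclass(frozen=True)
class ConstantCommittor:
    """q(x) = q0 everywhere; q0 = 0 is the maximal-ignorance model."""

    q0: float = 0.0

    def q(self, X: np.ndarray) -> np.ndarray:
        return np.full(np.asarray(X).shape[0], self.q0)


@dataclass(frozen=True)
class LinearCommittor:
    """q(x) = w . x + b — the logistic-regression special case."""

    weights: np.ndarray
    bias: float = 0.0

    def q(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(X, float) @ np.asarray(self.weights, float) + self.bias


class AnalyticCommittor1D:
    """Frozen oracle: exact overdamped committor of a 1D potential.

    q = logit(p_B) with p_B from the quadrature solution on (a, b), evaluated
    by dense-grid interpolation (n_grid trapezoid points; error far below the
    sampling noise of any shooting estimate).  The model reads the first
    feature column as the coordinate x.
    """

    def __init__(self, potential: Potential, kT: float, a: float, b: float,
                 n_grid: int = 4001, p_clip: float = 1e-12):
        xs = np.linspace(a, b, n_grid)
        w = np.exp(potential.energy(xs[:, None]) / kT)
        cum = cumulative_trapezoid(w, xs, initial=0.0)
        self._xs, self._p = xs, cum / cum[-1]
        self.a, self.b, self.p_clip = a, b, p_clip

    def p(self, x: np.ndarray) -> np.ndarray:
        return np.interp(np.asarray(x, float), self._xs, self._p, left=0.0, right=1.0)

    def q(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, float)
        x = X[:, 0] if X.ndim == 2 else X
        p = np.clip(self.p(x), self.p_clip, 1.0 - self.p_clip)
        return np.log(p / (1.0 - p))


# ---------------------------------------------------------------- pyramid net

@dataclass(frozen=True)
class PyramidArchitecture:
    widths: tuple[int, ...]
    dropouts: tuple[float, ...]


def build_pyramid(input_width: int, n_blocks: int, final_width: int,
                  dropout0: float = 0.1) -> PyramidArchitecture:
    """Geometric width schedule input_width -> final_width over n_blocks.

    The decay factor is f = (final/input)^(1/(n_blocks-1)); block i has width
    round(input * f^i) and dropout dropout0 * f^i.  A single block or equal
    widths give the degenerate constant pyramid.
    """
    if not (input_width >= final_width >= 1) or n_blocks < 1:
        raise ValueError("require input_width >= final_width >= 1 and n_blocks >= 1")
    if n_blocks == 1 or input_width == final_width:
        f = 1.0
    else:
        f = (final_width / input_width) ** (1.0 / (n_blocks - 1))
    widths = tuple(max(1, round(input_width * f**i)) for i in range(n_blocks))
    dropouts = tuple(dropout0 * f**i for i in range(n_blocks))
    return PyramidArchitecture(widths, dropouts)


class _Adam:
    def __init__(self, shapes, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros(s) for s in shapes]
        self.v = [np.zeros(s) for s in shapes]
        self.t = 0

    def step(self, params, grads, lr=None):
        lr = self.lr if lr is None else lr
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for p, g, m, v in zip(params, grads, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p -= lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


class NeuralCommittor:
    """Pyramidal feed-forward log-predictor q(x|w) trained by Adam.

    Layers: n_features -> widths[0] -> ... -> widths[-1] -> 1, tanh between
    hidden layers, inverted dropout after each hidden block during training,
    final single linear neuron.  ``residual`` adds identity skips between
    equal-width consecutive blocks.
    """

    def __init__(self, n_features: int, architecture: PyramidArchitecture,
                 seed: int = 0, residual: bool = False):
        self.n_features = n_features
        self.architecture = architecture
        self.residual = residual
        rng = np.random.default_rng(seed)
        dims = [n_features, *architecture.widths, 1]
        self.W = [rng.standard_normal((dims[i], dims[i + 1])) * np.sqrt(1.0 / dims[i])
                  for i in range(len(dims) - 1)]
        self.b = [np.zeros(d) for d in dims[1:]]
        self._trainable = [True] * len(self.W)
        self._adam: _Adam | None = None

    # -- forward / backward -------------------------------------------------
    def _forward(self, X, rng=None):
        """Returns (q, cache); dropout active iff rng is given."""
        drops = self.architecture.dropouts
        a = np.asarray(X, float)
        cache = [(a, None, None)]  # (block output, dropout mask, tanh(z))
        n_hidden = len(self.W) - 1
        for i in range(n_hidden):
            z = a @ self.W[i] + self.b[i]
            t = np.tanh(z)
            h = t + a if (self.residual and i > 0 and t.shape == a.shape) else t
            mask = None
            if rng is not None and drops[i] > 0:
                mask = (rng.random(h.shape) >= drops[i]) / (1.0 - drops[i])
                h = h * mask
            cache.append((h, mask, t))
            a = h
        q = (a @ self.W[-1] + self.b[-1])[:, 0]
        return q, cache

    def q(self, X: np.ndarray) -> np.ndarray:
        return self._forward(np.atleast_2d(np.asarray(X, float)))[0]

    def nll(self, X: np.ndarray, s: np.ndarray) -> float:
        return shooting_nll(self.q(X), s)

    def _backprop(self, X, s, rng=None):
        """Gradients of the shooting NLL w.r.t. all weights (and inputs)."""
        q, cache = self._forward(X, rng=rng)
        s = np.asarray(s, float)
        dq = s * sigmoid_link(s * q)  # d/dq log(1+e^{s q})
        gW = [None] * len(self.W)
        gb = [None] * len(self.b)
        a_last = cache[-1][0]
        gW[-1] = a_last.T @ dq[:, None]
        gb[-1] = np.array([dq.sum()])
        delta = dq[:, None] @ self.W[-1].T  # grad wrt activation of last hidden
        for i in range(len(self.W) - 2, -1, -1):
            _, mask, t = cache[i + 1]
            if mask is not None:
                delta = delta * mask
            dz = delta * (1.0 - t * t)  # tanh'
            a_prev = cache[i][0]
            gW[i] = a_prev.T @ dz
            gb[i] = dz.sum(axis=0)
            delta_prev = dz @ self.W[i].T
            if self.residual and i > 0 and a_prev.shape == delta.shape:
                delta_prev = delta_prev + delta
            delta = delta_prev
        loss = float(np.sum(_softplus(s * q)))
        return loss, gW, gb, delta  # delta is now d loss / d inputs

    def input_gradient(self, X: np.ndarray) -> np.ndarray:
        """Analytic dq/dx at each row of X (no dropout)."""
        X = np.atleast_2d(np.asarray(X, float))
        q, cache = self._forward(X)
        delta = np.ones((X.shape[0], 1)) @ self.W[-1].T
        for i in range(len(self.W) - 2, -1, -1):
            t = cache[i + 1][2]
            dz = delta * (1.0 - t * t)
            delta_prev = dz @ self.W[i].T
            if self.residual and i > 0 and cache[i][0].shape == delta.shape:
                delta_prev = delta_prev + delta
            delta = delta_prev
        return delta

    # -- training -----------------------------------------------------------
    def _params_grads(self, gW, gb):
        params = [p for i, (w, bb) in enumerate(zip(self.W, self.b)) if self._trainable[i]
                  for p in (w, bb)]
        grads = [g for i, (w, bb) in enumerate(zip(gW, gb)) if self._trainable[i]
                 for g in (w, bb)]
        return params, grads

    def train_epoch(self, X, s, learning_rate: float = 1e-3,
                    rng: np.random.Generator | None = None,
                    dropout: bool = True) -> float:
        """One full-batch Adam pass; returns the (pre-update) loss."""
        if learning_rate < 0:
            raise ValueError("learning_rate must be non-negative")
        X = np.atleast_2d(np.asarray(X, float))
        drop_rng = rng if (dropout and any(d > 0 for d in self.architecture.dropouts)) else None
        loss, gW, gb, _ = self._backprop(X, s, rng=drop_rng)
        if not np.isfinite(loss):
            raise FloatingPointError("non-finite training loss")
        if learning_rate > 0:
            params, grads = self._params_grads(gW, gb)
            if self._adam is None or len(self._adam.m) != len(params):
                self._adam = _Adam([p.shape for p in params])
            self._adam.step(params, grads, lr=learning_rate)
        return loss

    def fit(self, X, s, epochs: int = 200, learning_rate: float = 1e-3,
            seed: int | np.random.Generator = 0, dropout: bool = True) -> np.ndarray:
        """Run ``epochs`` full-batch Adam epochs; returns the loss trace."""
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        return np.array([self.train_epoch(X, s, learning_rate, rng, dropout)
                         for _ in range(epochs)])

    # -- transfer -----------------------------------------------------------
    def freeze_all_but_last(self) -> None:
        self._trainable = [False] * (len(self.W) - 1) + [True]
        self._adam = None

    def unfreeze(self) -> None:
        self._trainable = [True] * len(self.W)
        self._adam = None

    def copy(self) -> "NeuralCommittor":
        import copy as _copy

        clone = NeuralCommittor(self.n_features, self.architecture, residual=self.residual)
        clone.W = [w.copy() for w in self.W]
        clone.b = [bb.copy() for bb in self.b]
        clone._trainable = list(self._trainable)
        clone._adam = _copy.deepcopy(self._adam)
        return clone


def transfer_retrain_last_layer(
    model: NeuralCommittor,
    X: np.ndarray,
    s: np.ndarray,
    learning_rate: float = 2.5e-5,
    patience: int = 200,
    test_fraction: float = 0.2,
    max_epochs: int = 20_000,
    seed: int = 0,
) -> NeuralCommittor:
    """Adapt a trained committor to a new system by retraining only the final
    linear neuron (the log predictor); all other weights stay fixed.

    The last layer is re-randomized, training monitors the loss on a held-out
    ``test_fraction`` split, stops after ``patience`` epochs without
    improvement, and the best-test-loss parameters are returned.
    """
    X = np.atleast_2d(np.asarray(X, float))
    if X.shape[1] != model.n_features:
        raise ValueError("feature width mismatch")
    rng = np.random.default_rng(seed)
    new = model.copy()
    new.W[-1] = rng.standard_normal(new.W[-1].shape) * np.sqrt(1.0 / new.W[-1].shape[0])
    new.b[-1] = np.zeros_like(new.b[-1])
    new.freeze_all_but_last()

    n = X.shape[0]
    perm = rng.permutation(n)
    n_test = max(1, int(round(test_fraction * n)))
    test, train = perm[:n_test], perm[n_test:]
    if train.size == 0:
        raise ValueError("not enough data for a train/test split")
    s = np.asarray(s, float)

    best = (np.inf, new.W[-1].copy(), new.b[-1].copy())
    stale = 0
    for _ in range(max_epochs):
        new.train_epoch(X[train], s[train], learning_rate, rng, dropout=False)
        test_loss = new.nll(X[test], s[test])
        if test_loss < best[0] - 1e-12:
            best = (test_loss, new.W[-1].copy(), new.b[-1].copy())
            stale = 0
        else:
            stale += 1
            if stale > patience:
                break
    new.W[-1], new.b[-1] = best[1], best[2]
    return new


# ---------------------------------------------------------------- attribution

def gradient_attribution(
    model: CommittorModel,
    point: PhasePoint,
    feature_map,
    eps: float = 1e-5,
) -> np.ndarray:
    """Per-coordinate |dq/dx_j| / m_j of the composed map q(features(x)).

    Central finite differences through the full composition; masses rescale
    the magnitudes so heavy degrees of freedom are de-emphasized, mirroring
    per-atom contribution maps.
    """
    x0 = point.positions
    grad = np.empty(x0.shape[0])
    for j in range(x0.shape[0]):
        xp, xm = x0.copy(), x0.copy()
        xp[j] += eps
        xm[j] -= eps
        qp = float(model.q(np.atleast_2d(feature_map(xp[None, :])))[0])
        qm = float(model.q(np.atleast_2d(feature_map(xm[None, :])))[0])
        grad[j] = (qp - qm) / (2.0 * eps)
    if not np.all(np.isfinite(grad)):
        raise FloatingPointError("non-finite committor gradient")
    return np.abs(grad) / point.masses
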
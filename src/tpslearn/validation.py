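"""On-the-fly self-consistency checks of the learned committor.

For time-reversible Markovian dynamics the probability that a two-way shot
from x produces a transition path is P(TP|x) = 2 p_B(x)(1 - p_B(x)).  Before
each shot the model's committor prediction at the trial shooting point is
logged; summing the reactive probabilities over a sliding window of the k
most recent shots gives the expected transition count

    n_TP_exp = sum_i 2 (1 - p_B(x_i, i)) p_B(x_i, i),

to be compared with the generated count n_TP_gen.  The efficiency factor

    alpha_eff = min(1, (1 - n_TP_gen / n_TP_exp)^2)

is zero for perfect prediction and scales the retraining learning rate; no
training happens while the scaled rate sits below a floor, which prevents
overfitting a model that already predicts well.

Offline validation is done by brute-force shooting: the sampled committor is
the fraction of fresh one-way trials entering B first, binned against the
model's prediction on configurations the model never trained on.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .dynamics import EngineParams, PhasePoint, StateDefinition, propagate_batch_committed
from .potentials import Potential

__all__ = [
    "CommittorEstimate",
    "CrossvalBins",
    "ValidationLedger",
    "crossval_bins",
    "efficiency_factor",
    "expected_tp_count",
    "reactive_probability",
    "sample_committor",
    "training_gate",
]


def reactive_probability(p: float | np.ndarray) -> float | np.ndarray:
    """P(TP|x) = 2 p (1-p): peaks at 1/2 on the transition-state surface."""
    p = np.asarray(p, float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("committor values must lie in [0, 1]")
    out = 2.0 * p * (1.0 - p)
    return out if out.ndim else float(out)


@dataclass
class ValidationLedger:
    """Per-shot log used for the expected-vs-generated comparison.

    Each entry stores the step index, the model's committor prediction at
    the trial shooting point before the outcome was observed, and whether
    the shot generated a transition path (0 or 1 — one two-way shot yields
    at most one TP).
    """

    window: int = 100
    steps: list[int] = field(default_factory=list)
    p_pred: list[float] = field(default_factory=list)
    generated: list[int] = field(default_factory=list)
    alpha_history: list[tuple[int, float, float]] = field(default_factory=list)

    def record(self, step: int, p_pred: float, generated: int) -> None:
        if generated not in (0, 1):
            raise ValueError("generated must be 0 or 1")
        self.steps.append(step)
        self.p_pred.append(float(p_pred))
        self.generated.append(generated)

    def record_alpha(self, step: int, alpha: float, lr: float) -> None:
        self.alpha_history.append((step, float(alpha), float(lr)))

    def __len__(self) -> int:
        return len(self.steps)

    def expected_tp_count(self, window: int | None = None) -> float:
        return expected_tp_count(self, self.window if window is None else window)

    def generated_tp_count(self, window: int | None = None) -> int:
        k = self.window if window is None else window
        return int(np.sum(self.generated[-k:]))

    def cumulative_curves(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Cumulative generated, expected and |difference| over all shots."""
        gen = np.cumsum(self.generated)
        exp = np.cumsum(reactive_probability(np.asarray(self.p_pred)))
        return gen, exp, np.abs(gen - exp)


def expected_tp_count(ledger: ValidationLedger, window: int) -> float:
    """Sum of reactive probabilities over the window's pre-shot predictions."""
    if len(ledger) == 0:
        raise ValueError("empty ledger")
    p = np.asarray(ledger.p_pred[-window:], float)
    return float(np.sum(reactive_probability(p)))


def efficiency_factor(n_gen: float, n_exp: float) -> float:
    """alpha_eff = min(1, (1 - n_gen/n_exp)^2); 0 iff counts agree exactly.

    A zero expectation with any generated paths is maximal mismatch (1).
    """
    if n_exp < 0 or n_gen < 0:
        raise ValueError("counts must be non-negative")
    if n_exp == 0:
        return 1.0
    return float(min(1.0, (1.0 - n_gen / n_exp) ** 2))


def training_gate(alpha_eff: float, base_lr: float, floor: float = 1e-4) -> tuple[bool, float]:
    """Scale the learning rate by alpha_eff; train only if lr >= floor."""
    if base_lr <= 0:
        raise ValueError("base_lr must be positive")
    lr = alpha_eff * base_lr
    return lr >= floor, lr


@dataclass(frozen=True)
class CommittorEstimate:
    p_hat: float
    n_B: int
    n: int

    @property
    def stderr(self) -> float:
        return float(np.sqrt(self.p_hat * (1.0 - self.p_hat) / self.n))


def sample_committor(
    point: PhasePoint | np.ndarray,
    engine: EngineParams,
    potential: Potential,
    states: Sequence[StateDefinition],
    n_shots: int,
    rng: np.random.Generator,
    masses: np.ndarray | None = None,
) -> CommittorEstimate:
    """Brute-force committor: fraction of fresh one-way trials entering the
    second state (B) first, each with redrawn Maxwell–Boltzmann velocities.

    Uncommitted trials are excluded from the fraction; if every trial fails
    to commit an error is raised.
    """
    if n_shots < 1:
        raise ValueError("n_shots must be >= 1")
    if len(states) != 2:
        raise ValueError("committor estimation is defined between two states")
    pos = point.positions if isinstance(point, PhasePoint) else np.atleast_1d(np.asarray(point, float))
    if isinstance(point, PhasePoint) and masses is None:
        masses = point.masses
    starts = np.tile(pos[None, :], (n_shots, 1))
    labels, committed = propagate_batch_committed(
        engine, potential, starts, states, rng, masses=masses)
    n_ok = int(committed.sum())
    if n_ok == 0:
        raise RuntimeError("all trial trajectories failed to commit")
    n_B = int(np.sum(labels[committed] == 1))
    return CommittorEstimate(n_B / n_ok, n_B, n_ok)


@dataclass(frozen=True)
class CrossvalBins:
    centers: np.ndarray
    means: np.ndarray  # NaN where a bin is empty
    stds: np.ndarray
    counts: np.ndarray

    @property
    def max_deviation(self) -> float:
        """Largest |bin mean - bin center| over populated bins."""
        ok = self.counts > 0
        return float(np.max(np.abs(self.means[ok] - self.centers[ok])))


def crossval_bins(predicted: np.ndarray, sampled: np.ndarray,
                  bin_edges: np.ndarray) -> CrossvalBins:
    """Mean/s.d. of sampled committors in bins of the predicted committor.

    The inputs must come from configurations held out of training; empty
    bins are reported as NaN with zero count, never as zero.
    """
    predicted = np.asarray(predicted, float)
    sampled = np.asarray(sampled, float)
    if predicted.shape != sampled.shape:
        raise ValueError("predicted and sampled must have equal length")
    edges = np.asarray(bin_edges, float)
    idx = np.digitize(predicted, edges) - 1
    nb = len(edges) - 1
    means = np.full(nb, np.nan)
    stds = np.full(nb, np.nan)
    counts = np.zeros(nb, int)
    for b in range(nb):
        sel = idx == b
        counts[b] = sel.sum()
        if counts[b]:
            means[b] = sampled[sel].mean()
            stds[b] = sampled[sel].std(ddof=0)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return CrossvalBins(centers, means, stds, counts)
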
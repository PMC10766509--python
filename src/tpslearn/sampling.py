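"""Transition path sampling with committor-guided two-way shooting.

A TPS Markov chain holds one transition path at a time.  Each move selects a
shooting point on the current path from the Lorentzian distribution

    p_sel(X | chi) ∝ 1 / (q(x)^2 + gamma^2),

centred on the learned transition-state ensemble q = 0 (gamma trades
exploitation for exploration), redraws Maxwell–Boltzmann velocities, and
propagates one trial forward and one backward in time (momenta inverted at
the shooting point; for overdamped dynamics the backward trial is an
independent forward realization, valid by time reversibility).  If the two
trials commit to different states they join into a candidate path, accepted
with the Metropolis probability

    p_acc = min(1, p_sel(X_SP | chi') / p_sel(X_SP | chi)),

evaluated with the committor model frozen at move time.  Every committed
trial — success or failure — contributes one shooting record, so the learner
sees all virtual experiments.

``run_guided_sampling`` orchestrates the full loop: several round-robin
chains share one committor model, a validation ledger compares generated
with expected transition counts over a sliding window, and the resulting
efficiency factor gates and scales model retraining on the cumulative
records.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np

from .committor import (CommittorModel, NeuralCommittor, ShootingRecord,
                        TrainingSet, sigmoid_link)
from .dynamics import (EngineParams, PhasePoint, StateDefinition, Trajectory,
                       UncommittedError, draw_maxwell_boltzmann,
                       make_initial_path_segments, propagate_committed)
from .potentials import Potential
from .validation import ValidationLedger, efficiency_factor, training_gate

__all__ = [
    "ChainState",
    "GuidedRun",
    "Path",
    "SelectionPolicy",
    "ShotResult",
    "acceptance_probability",
    "join_two_way",
    "run_guided_sampling",
    "selection_distribution",
    "soften_states",
    "tps_step",
    "two_way_shoot",
]

FeatureMap = Callable[[np.ndarray], np.ndarray]


@dataclass
class Path:
    """A transition path: frames plus the labels of its two endpoints."""

    positions: np.ndarray  # (n_frames, d)
    endpoint_labels: tuple[str, str]
    velocities: np.ndarray | None = None
    weight: int = 1

    def __post_init__(self):
        if self.endpoint_labels[0] == self.endpoint_labels[1]:
            raise ValueError("a transition path must connect distinct states")
        if self.weight < 1:
            raise ValueError("weight must be >= 1")

    def __len__(self) -> int:
        return self.positions.shape[0]

    def is_valid_tp(self, states: Sequence[StateDefinition]) -> bool:
        """Endpoints in their distinct states, interior frames in none."""
        by_label = {s.label: s for s in states}
        first, last = self.endpoint_labels
        if not (by_label[first].contains(self.positions[0])
                and by_label[last].contains(self.positions[-1])):
            return False
        interior = self.positions[1:-1]
        if interior.size:
            for s in states:
                if s.contains_batch(interior).any():
                    return False
        return True


@dataclass(frozen=True)
class SelectionPolicy:
    """Lorentzian shooting-point selection; larger gamma explores more."""

    gamma: float = 1.0

    def __post_init__(self):
        if not np.isfinite(self.gamma) or self.gamma <= 0:
            raise ValueError("gamma must be positive and finite")


@dataclass
class ChainState:
    current_path: Path
    rng: np.random.Generator
    mc_step: int = 0
    chain_id: str = "0"


@dataclass
class ShotResult:
    candidate: Path | None
    records: list[ShootingRecord]
    sp_index: int
    p_pred: float  # model committor at the trial shooting point, pre-outcome
    void: bool = False  # uncommitted trial; shot discarded entirely


def selection_distribution(q_values: np.ndarray, gamma: float) -> np.ndarray:
    """Normalized frame-selection probabilities ∝ 1/(q^2 + gamma^2)."""
    w = 1.0 / (np.asarray(q_values, float) ** 2 + gamma**2)
    return w / w.sum()


def acceptance_probability(
    old: Path,
    new: Path,
    sp_point: np.ndarray,
    model: CommittorModel,
    policy: SelectionPolicy,
    feature_map: FeatureMap,
) -> float:
    """Metropolis ratio of shooting-point selection probabilities.

    Both densities use the same frozen model; since q(X_SP) is common to
    numerator and denominator the ratio reduces to the ratio of the paths'
    Lorentzian normalizations.
    """
    sp = np.asarray(sp_point, float)

    def _contains(path: Path) -> bool:
        return bool(np.any(np.all(np.isclose(path.positions, sp[None, :]), axis=1)))

    if not (_contains(old) and _contains(new)):
        raise ValueError("shooting point must be a frame of both paths")
    g2 = policy.gamma**2
    sum_old = np.sum(1.0 / (model.q(feature_map(old.positions)) ** 2 + g2))
    sum_new = np.sum(1.0 / (model.q(feature_map(new.positions)) ** 2 + g2))
    return float(min(1.0, sum_old / sum_new))


def join_two_way(backward: Trajectory, label_b: str,
                 forward: Trajectory, label_f: str) -> Path:
    """Reverse the backward trial and splice it to the forward one."""
    rev = backward.reversed()
    pos = np.concatenate([rev.positions, forward.positions[1:]])
    vel = None
    if rev.velocities is not None and forward.velocities is not None:
        vel = np.concatenate([rev.velocities, forward.velocities[1:]])
    return Path(pos, (label_b, label_f), vel)


def two_way_shoot(
    chain: ChainState,
    model: CommittorModel,
    policy: SelectionPolicy,
    engine: EngineParams,
    potential: Potential,
    states: Sequence[StateDefinition],
    feature_map: FeatureMap,
    masses: np.ndarray | None = None,
) -> ShotResult:
    """One two-way shooting move from the chain's current path."""
    rng = chain.rng
    path = chain.current_path
    q_path = model.q(feature_map(path.positions))
    p_sel = selection_distribution(q_path, policy.gamma)
    sp_index = int(rng.choice(len(path), p=p_sel))
    sp = PhasePoint(path.positions[sp_index], masses=masses)
    p_pred = float(sigmoid_link(q_path[sp_index]))

    if engine.kind == "underdamped":
        fwd_pt = draw_maxwell_boltzmann(sp, engine.kT, rng)
        bwd_pt = replace(fwd_pt, velocities=-fwd_pt.velocities)
    else:
        fwd_pt = bwd_pt = sp
    try:
        bwd, lb = propagate_committed(engine, potential, bwd_pt, states, rng)
        fwd, lf = propagate_committed(engine, potential, fwd_pt, states, rng)
    except UncommittedError:
        return ShotResult(None, [], sp_index, p_pred, void=True)

    label_a = states[0].label  # outcome convention: +1 = entered first state
    x_sp = feature_map(path.positions[sp_index][None, :])[0]
    records = [
        ShootingRecord(x_sp, outcome=+1 if lab == label_a else -1,
                       step_index=chain.mc_step, chain_id=chain.chain_id)
        for lab in (lb, lf)
    ]
    candidate = join_two_way(bwd, lb, fwd, lf) if lb != lf else None
    return ShotResult(candidate, records, sp_index, p_pred)


def tps_step(
    chain: ChainState,
    model: CommittorModel,
    policy: SelectionPolicy,
    engine: EngineParams,
    potential: Potential,
    states: Sequence[StateDefinition],
    feature_map: FeatureMap,
    masses: np.ndarray | None = None,
) -> tuple[ShotResult, bool]:
    """One Markov-chain move: shoot, Metropolis-accept, update the chain.

    On rejection (including failed or void shots) the current path's weight
    is incremented — the old path is repeated in the ensemble.
    """
    shot = two_way_shoot(chain, model, policy, engine, potential, states,
                         feature_map, masses)
    accepted = False
    if shot.candidate is not None:
        p_acc = acceptance_probability(chain.current_path, shot.candidate,
                                       chain.current_path.positions[shot.sp_index],
                                       model, policy, feature_map)
        if chain.rng.random() < p_acc:
            chain.current_path = shot.candidate
            accepted = True
    if not accepted:
        chain.current_path.weight += 1
    chain.mc_step += 1
    return shot, accepted


@dataclass
class GuidedRun:
    """Outcome of a guided-sampling run."""

    paths: list[Path]
    training_set: TrainingSet
    ledger: ValidationLedger
    model: CommittorModel
    n_accepted: int
    n_steps: int
    n_void: int = 0

    @property
    def acceptance_rate(self) -> float:
        return self.n_accepted / max(1, self.n_steps)


def run_guided_sampling(
    potential: Potential,
    engine: EngineParams,
    states: Sequence[StateDefinition],
    feature_map: FeatureMap,
    model: CommittorModel,
    n_steps: int,
    policy: SelectionPolicy = SelectionPolicy(),
    n_chains: int = 1,
    seed: int = 0,
    saddle_guesses: Sequence[np.ndarray] | None = None,
    initial_paths: Sequence[Path] | None = None,
    masses: np.ndarray | None = None,
    train_interval: int = 3,
    epochs_per_update: int = 1,
    base_lr: float = 1e-3,
    lr_floor: float = 1e-4,
    k_window: int = 100,
    train: bool = True,
    dropout: bool = True,
) -> GuidedRun:
    """Round-robin multi-chain TPS guided by one shared committor model.

    Every ``train_interval`` total MC steps the ledger's efficiency factor
    alpha_eff = min(1, (1 - n_gen/n_exp)^2) over the last ``k_window`` steps
    decides whether to retrain: the learning rate is alpha_eff * base_lr and
    training only happens when it reaches ``lr_floor``.  ``train=False``
    freezes the model (plain guided TPS).
    """
    if n_chains < 1 or n_steps < 1:
        raise ValueError("n_chains and n_steps must be >= 1")
    master = np.random.default_rng(seed)
    chain_seeds = master.integers(0, 2**31 - 1, size=n_chains)
    chains: list[ChainState] = []
    for c in range(n_chains):
        rng = np.random.default_rng(chain_seeds[c])
        if initial_paths is not None:
            path = initial_paths[c]
        else:
            if saddle_guesses is None:
                raise ValueError("provide saddle_guesses or initial_paths")
            guess = saddle_guesses[c % len(saddle_guesses)]
            bwd, lb, fwd, lf = make_initial_path_segments(
                engine, potential, states, rng, guess, masses=masses)
            path = join_two_way(bwd, lb, fwd, lf)
        if not path.is_valid_tp(states):
            raise RuntimeError(f"chain {c}: initial path is not a valid TP")
        chains.append(ChainState(path, rng, chain_id=str(c)))

    training_set = TrainingSet()
    ledger = ValidationLedger(window=k_window)
    ensemble: list[Path] = [c.current_path for c in chains]
    n_accepted = n_void = 0
    trainable = train and isinstance(model, NeuralCommittor)
    train_rng = np.random.default_rng(master.integers(0, 2**31 - 1))

    for step in range(n_steps):
        chain = chains[step % n_chains]
        shot, accepted = tps_step(chain, model, policy, engine, potential,
                                  states, feature_map, masses)
        if shot.void:
            n_void += 1
            continue
        training_set.extend(shot.records)
        generated = 1 if shot.candidate is not None else 0
        ledger.record(step, shot.p_pred, generated)
        if accepted:
            n_accepted += 1
            ensemble.append(chain.current_path)

        if trainable and (step + 1) % train_interval == 0 and len(training_set):
            n_exp = ledger.expected_tp_count()
            n_gen = ledger.generated_tp_count()
            alpha = efficiency_factor(n_gen, n_exp)
            should, lr = training_gate(alpha, base_lr, lr_floor)
            ledger.record_alpha(step, alpha, lr if should else 0.0)
            if should:
                X, s = training_set.to_arrays()
                model.fit(X, s, epochs=epochs_per_update, learning_rate=lr,
                          seed=train_rng, dropout=dropout)

    return GuidedRun(ensemble, training_set, ledger, model,
                     n_accepted, n_steps, n_void)


def soften_states(
    states: Sequence[StateDefinition],
    model: CommittorModel,
    feature_map: FeatureMap,
    lo: float,
    hi: float,
    probe_points: np.ndarray,
) -> list[StateDefinition]:
    """Widen the two states to committor iso-levels p_B <= lo / p_B >= hi.

    Softened boundaries give shorter transition paths.  Refused when the
    model is uninformative on the probe points (no point on either side of
    the levels), e.g. an untrained q = 0 model.
    """
    if not (0.0 < lo < hi < 1.0):
        raise ValueError("require 0 < lo < hi < 1")
    if len(states) != 2:
        raise ValueError("softening is defined for the two-state case")
    p_probe = sigmoid_link(model.q(feature_map(np.asarray(probe_points, float))))
    if not (np.any(p_probe <= lo) and np.any(p_probe >= hi)):
        raise ValueError("model is uninformative at the requested levels; refusing to soften")

    def make(label: str, side: str) -> StateDefinition:
        if side == "A":
            single = lambda p: float(sigmoid_link(model.q(feature_map(p[None, :]))[0])) <= lo
            batch = lambda P: sigmoid_link(model.q(feature_map(P))) <= lo
        else:
            single = lambda p: float(sigmoid_link(model.q(feature_map(p[None, :]))[0])) >= hi
            batch = lambda P: sigmoid_link(model.q(feature_map(P))) >= hi
        return StateDefinition(label, single, batch, committor_bounds=(lo, hi))

    a, b = states
    return [make(a.label, "A"), make(b.label, "B")]
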
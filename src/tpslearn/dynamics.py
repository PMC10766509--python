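"""Langevin propagation of toy systems until commitment to a metastable state.

Two engines are provided. The overdamped engine is an Euler–Maruyama
discretization of

    dx = -grad U(x) / (m * friction) dt + sqrt(2 kT dt / (m * friction)) xi,

the underdamped engine is velocity Verlet with per-step velocity
randomization (an Ornstein–Uhlenbeck kick with decay exp(-friction * dt)
before each Verlet step).  Trajectories are propagated until the first frame
inside one of the metastable states; the engine is deliberately ignorant of
everything downstream — it is the black box the sampler shoots from.

An exact quadrature committor for 1D overdamped dynamics,

    p_B(x) = int_a^x exp(U/kT) dy / int_a^b exp(U/kT) dy,

serves as the validation oracle throughout the package.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
from scipy.integrate import quad

from .potentials import Potential

__all__ = [
    "EngineParams",
    "PhasePoint",
    "StateDefinition",
    "Trajectory",
    "UncommittedError",
    "analytic_committor_1d",
    "draw_maxwell_boltzmann",
    "half_line_state",
    "make_initial_path_segments",
    "propagate_batch_committed",
    "propagate_committed",
]

_NOISE_CHUNK = 1024  # steps of Gaussian noise drawn per RNG call


class UncommittedError(RuntimeError):
    """Raised when max_steps elapse without reaching any state.

    Carries the partial trajectory so the caller can log or inspect it; the
    sampler counts such shots as rejected and records no training datum.
    """

    def __init__(self, message: str, trajectory: "Trajectory | None" = None):
        super().__init__(message)
        self.trajectory = trajectory


@dataclass(frozen=True)
class EngineParams:
    """Integration parameters, in reduced units (kT houses beta = 1/kT)."""

    kind: str = "overdamped"  # or "underdamped"
    timestep: float = 0.005
    friction: float = 1.0
    kT: float = 1.0
    max_steps: int = 1_000_000
    stride: int = 1

    def __post_init__(self):
        if self.kind not in ("overdamped", "underdamped"):
            raise ValueError(f"unknown engine kind {self.kind!r}")
        if self.timestep <= 0 or self.friction <= 0 or self.kT <= 0:
            raise ValueError("timestep, friction and kT must be positive")
        if self.max_steps <= 0 or self.stride <= 0:
            raise ValueError("max_steps and stride must be positive")


@dataclass(frozen=True)
class PhasePoint:
    """A configuration X: positions, optional velocities, per-dof masses."""

    positions: np.ndarray
    velocities: np.ndarray | None = None
    masses: np.ndarray | None = None

    def __post_init__(self):
        object.__setattr__(self, "positions", np.atleast_1d(np.asarray(self.positions, float)))
        if self.velocities is not None:
            object.__setattr__(self, "velocities", np.atleast_1d(np.asarray(self.velocities, float)))
        m = np.ones_like(self.positions) if self.masses is None else np.atleast_1d(np.asarray(self.masses, float))
        if np.any(m <= 0):
            raise ValueError("masses must be positive")
        object.__setattr__(self, "masses", m)

    @property
    def dim(self) -> int:
        return self.positions.shape[0]


@dataclass(frozen=True)
class StateDefinition:
    """A metastable state: a predicate on configurations.

    ``indicator`` acts on a single position vector; ``batch_indicator`` on an
    ``(n, d)`` array and must agree with it row-wise.
    """

    label: str
    indicator: Callable[[np.ndarray], bool]
    batch_indicator: Callable[[np.ndarray], np.ndarray] | None = None
    committor_bounds: tuple[float, float] | None = None

    def contains(self, positions: np.ndarray) -> bool:
        return bool(self.indicator(np.asarray(positions, float)))

    def contains_batch(self, positions: np.ndarray) -> np.ndarray:
        positions = np.asarray(positions, float)
        if self.batch_indicator is not None:
            return np.asarray(self.batch_indicator(positions), bool)
        return np.array([self.indicator(p) for p in positions], bool)


def half_line_state(label: str, threshold: float, side: str = "le", coord: int = 0) -> StateDefinition:
    """State defined by one coordinate crossing a threshold (1D/2D toys)."""
    if side == "le":
        return StateDefinition(label, lambda p: p[coord] <= threshold,
                               lambda P: P[:, coord] <= threshold)
    if side == "ge":
        return StateDefinition(label, lambda p: p[coord] >= threshold,
                               lambda P: P[:, coord] >= threshold)
    raise ValueError("side must be 'le' or 'ge'")


def check_states_disjoint(states: Sequence[StateDefinition], probe: np.ndarray) -> None:
    """Assert no probe point belongs to two states (invariant guard)."""
    probe = np.asarray(probe, float)
    hits = np.stack([s.contains_batch(probe) for s in states])
    if np.any(hits.sum(axis=0) > 1):
        raise ValueError("state definitions overlap on probe points")


@dataclass
class Trajectory:
    """Time-ordered frames of one propagated trial."""

    positions: np.ndarray  # (n_frames, d)
    velocities: np.ndarray | None
    timestep: float
    stride: int = 1

    def __len__(self) -> int:
        return self.positions.shape[0]

    @property
    def times(self) -> np.ndarray:
        return np.arange(len(self)) * self.timestep * self.stride

    def reversed(self) -> "Trajectory":
        vel = None if self.velocities is None else -self.velocities[::-1]
        return Trajectory(self.positions[::-1].copy(), vel, self.timestep, self.stride)


def draw_maxwell_boltzmann(point: PhasePoint, kT: float, rng: np.random.Generator) -> PhasePoint:
    """Redraw velocities i.i.d. Gaussian with variance kT/m per component."""
    if kT < 0:
        raise ValueError("kT must be non-negative")
    sigma = np.sqrt(kT / point.masses)
    v = rng.standard_normal(point.dim) * sigma
    return replace(point, velocities=v)


def _which_state(positions: np.ndarray, states: Sequence[StateDefinition]) -> str | None:
    for s in states:
        if s.contains(positions):
            return s.label
    return None


def propagate_committed(
    engine: EngineParams,
    potential: Potential,
    start: PhasePoint,
    states: Sequence[StateDefinition],
    rng: np.random.Generator,
) -> tuple[Trajectory, str]:
    """Propagate from ``start`` until the first frame inside any state.

    Returns the trajectory (frames at ``engine.stride``; the committing frame
    is always recorded) and the terminal state label.  A start already inside
    a state returns immediately with a single-frame trajectory.
    """
    label = _which_state(start.positions, states)
    if label is not None:
        return Trajectory(start.positions[None, :].copy(),
                          None if start.velocities is None else start.velocities[None, :].copy(),
                          engine.timestep, engine.stride), label

    underdamped = engine.kind == "underdamped"
    x = start.positions.copy()
    m = start.masses
    dt = engine.timestep
    if underdamped:
        if start.velocities is None:
            raise ValueError("underdamped propagation requires velocities")
        v = start.velocities.copy()
        c1 = np.exp(-engine.friction * dt)
        sig_v = np.sqrt((1.0 - c1 * c1) * engine.kT / m)
    else:
        mob = dt / (m * engine.friction)
        sig_x = np.sqrt(2.0 * engine.kT * dt / (m * engine.friction))
        v = None

    frames_x, frames_v = [x.copy()], [None if v is None else v.copy()]
    noise = rng.standard_normal((_NOISE_CHUNK, x.shape[0]))
    ptr = 0
    for step in range(1, engine.max_steps + 1):
        if ptr >= _NOISE_CHUNK:
            noise = rng.standard_normal((_NOISE_CHUNK, x.shape[0]))
            ptr = 0
        xi = noise[ptr]
        ptr += 1
        if underdamped:
            v = c1 * v + sig_v * xi
            f = -potential.gradient(x)
            v = v + 0.5 * dt * f / m
            x = x + dt * v
            v = v + 0.5 * dt * (-potential.gradient(x)) / m
        else:
            x = x - mob * potential.gradient(x) + sig_x * xi
        label = _which_state(x, states)
        if step % engine.stride == 0 or label is not None:
            frames_x.append(x.copy())
            frames_v.append(None if v is None else v.copy())
        if label is not None:
            vel = None if v is None else np.stack([fv for fv in frames_v])
            return Trajectory(np.stack(frames_x), vel, dt, engine.stride), label

    traj = Trajectory(np.stack(frames_x),
                      None if v is None else np.stack([fv for fv in frames_v]),
                      dt, engine.stride)
    raise UncommittedError(f"no commitment within {engine.max_steps} steps", traj)


def propagate_batch_committed(
    engine: EngineParams,
    potential: Potential,
    starts: np.ndarray,
    states: Sequence[StateDefinition],
    rng: np.random.Generator,
    velocities: np.ndarray | None = None,
    masses: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Propagate many independent walkers at once; no frames are stored.

    Returns ``(labels, committed)`` where ``labels[i]`` is the index into
    ``states`` of the terminal state of walker ``i`` (-1 if uncommitted) and
    ``committed`` is the boolean mask of committed walkers.  Used for
    brute-force committor estimation, where only the terminal label matters.
    """
    X = np.array(starts, float, copy=True)
    n, d = X.shape
    m = np.ones(d) if masses is None else np.asarray(masses, float)
    dt = engine.timestep
    underdamped = engine.kind == "underdamped"
    if underdamped:
        if velocities is None:
            velocities = rng.standard_normal((n, d)) * np.sqrt(engine.kT / m)
        V = np.array(velocities, float, copy=True)
        c1 = np.exp(-engine.friction * dt)
        sig_v = np.sqrt((1.0 - c1 * c1) * engine.kT / m)
    else:
        mob = dt / (m * engine.friction)
        sig_x = np.sqrt(2.0 * engine.kT * dt / (m * engine.friction))

    labels = np.full(n, -1, dtype=int)
    active = np.ones(n, dtype=bool)
    for si, s in enumerate(states):
        inside = s.contains_batch(X) & active
        labels[inside] = si
        active &= ~inside

    for _ in range(engine.max_steps):
        if not active.any():
            break
        idx = np.flatnonzero(active)
        xi = rng.standard_normal((idx.size, d))
        if underdamped:
            V[idx] = c1 * V[idx] + sig_v * xi
            V[idx] += 0.5 * dt * (-potential.gradient(X[idx])) / m
            X[idx] += dt * V[idx]
            V[idx] += 0.5 * dt * (-potential.gradient(X[idx])) / m
        else:
            X[idx] += -mob * potential.gradient(X[idx]) + sig_x * xi
        for si, s in enumerate(states):
            hit = s.contains_batch(X[idx])
            if hit.any():
                hit_idx = idx[hit]
                labels[hit_idx] = si
                active[hit_idx] = False
                idx = idx[~hit]
    return labels, labels >= 0


def analytic_committor_1d(
    potential: Potential,
    kT: float,
    a: float,
    b: float,
    x: float | np.ndarray,
    quad_tol: float = 1e-10,
) -> float | np.ndarray:
    """Exact committor for 1D overdamped dynamics between boundaries a < b.

    Values outside (a, b) are clipped to 0/1.  Quadrature is adaptive with
    absolute/relative tolerance ``quad_tol``; for the toy barriers used here
    the result is accurate to well below 1e-8.
    """
    if a >= b:
        raise ValueError("require a < b")

    def w_scalar(y):
        return float(np.exp(potential.energy(np.array([[y]]))[0] / kT))

    denom, _ = quad(w_scalar, a, b, epsabs=quad_tol, epsrel=quad_tol, limit=200)

    def one(xv: float) -> float:
        if xv <= a:
            return 0.0
        if xv >= b:
            return 1.0
        num, _ = quad(w_scalar, a, xv, epsabs=quad_tol, epsrel=quad_tol, limit=200)
        return num / denom

    if np.ndim(x) == 0:
        return one(float(x))
    return np.array([one(float(xv)) for xv in np.asarray(x, float)])


def direct_tp_lengths(
    engine: EngineParams,
    potential: Potential,
    states: Sequence[StateDefinition],
    rng: np.random.Generator,
    n_paths: int,
    start: np.ndarray,
    n_walkers: int = 64,
    max_chunks: int = 2000,
    chunk: int = 2048,
) -> np.ndarray:
    """Transition path lengths from unbiased equilibrium runs.

    Propagates independent overdamped walkers and excises every segment
    running from the last frame inside one state to the first frame inside
    the other (both endpoint frames included) — the reference transition
    path ensemble against which TPS sampling is validated.  Returns the
    first ``n_paths`` segment lengths, in frames.
    """
    if engine.kind != "overdamped":
        raise ValueError("direct excision implemented for overdamped dynamics")
    d = np.atleast_1d(np.asarray(start, float)).shape[0]
    X = np.tile(np.atleast_1d(np.asarray(start, float))[None, :], (n_walkers, 1))
    dt = engine.timestep
    mob = dt / engine.friction
    sig = np.sqrt(2.0 * engine.kT * dt / engine.friction)
    # per-walker: label of last visited state (-1 before any), frame index of
    # the most recent frame inside that state, and a global frame counter
    last_label = np.full(n_walkers, -1, int)
    last_inside = np.zeros(n_walkers, int)
    lengths: list[int] = []
    frame = 0
    for _ in range(max_chunks):
        noise = rng.standard_normal((chunk, n_walkers, d))
        for k in range(chunk):
            frame += 1
            X += -mob * potential.gradient(X) + sig * noise[k]
            for si, s in enumerate(states):
                inside = s.contains_batch(X)
                if not inside.any():
                    continue
                entered = inside & (last_label != si)
                crossed = entered & (last_label >= 0)
                for w in np.flatnonzero(crossed):
                    lengths.append(frame - last_inside[w] + 1)
                last_label[inside] = si
                last_inside[inside] = frame
            if len(lengths) >= n_paths:
                return np.array(lengths[:n_paths])
    raise RuntimeError(f"collected only {len(lengths)}/{n_paths} transitions")


def make_initial_path_segments(
    engine: EngineParams,
    potential: Potential,
    states: Sequence[StateDefinition],
    rng: np.random.Generator,
    saddle_guess: np.ndarray,
    masses: np.ndarray | None = None,
    max_attempts: int = 100,
) -> tuple[Trajectory, str, Trajectory, str]:
    """Shoot two-way from a saddle guess until the two trials commit to
    different states; returns (backward, its label, forward, its label).

    The caller (path_sampling) joins the reversed backward segment with the
    forward one into an initial transition path.
    """
    if len(states) < 2:
        raise ValueError("need at least two states")
    guess = np.atleast_1d(np.asarray(saddle_guess, float))
    for s in states:
        if s.contains(guess):
            raise ValueError("saddle guess lies inside a state")
    pt = PhasePoint(guess, masses=masses)
    for _ in range(max_attempts):
        if engine.kind == "underdamped":
            fwd_pt = draw_maxwell_boltzmann(pt, engine.kT, rng)
            bwd_pt = replace(fwd_pt, velocities=-fwd_pt.velocities)
        else:
            fwd_pt = bwd_pt = pt
        try:
            bwd, lb = propagate_committed(engine, potential, bwd_pt, states, rng)
            fwd, lf = propagate_committed(engine, potential, fwd_pt, states, rng)
        except UncommittedError:
            continue
        if lb != lf:
            return bwd, lb, fwd, lf
    raise RuntimeError(f"no transition path found in {max_attempts} two-way attempts")
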
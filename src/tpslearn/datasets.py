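"""Synthetic fixtures emulating the statistical structure of real inputs.

These generators stand in for molecular datasets: ideal-gas point clouds for
symmetry-function normalization checks, logistic-planted shooting records
whose outcomes are Bernoulli draws from a known committor, polyline bundles
with planted cluster structure, and offline shooting tables in the
delimited-text layout used for training and distillation.  Every generator
is seeded and returns a manifest of its parameters alongside the data.
"""

from __future__ import annotations

import numpy as np

from .committor import ShootingRecord, TrainingSet, sigmoid_link

__all__ = [
    "logistic_records",
    "planted_polylines",
    "point_cloud",
    "shooting_table",
]


def point_cloud(density: float, box: float, rng: np.random.Generator | int = 0,
                dim: int = 3) -> tuple[np.ndarray, dict]:
    """Uniform (ideal-gas) cloud at number density ``density`` in a cube of
    side ``box`` centred at the origin; Poisson-distributed count."""
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    if density < 0 or box <= 0:
        raise ValueError("density must be >= 0 and box > 0")
    n = int(rng.poisson(density * box**dim))
    cloud = rng.uniform(-box / 2, box / 2, size=(n, dim))
    return cloud, {"kind": "point-cloud", "density": density, "box": box,
                   "dim": dim, "n_points": n}


def logistic_records(n: int, weights: np.ndarray, bias: float,
                     rng: np.random.Generator | int = 0,
                     x_scale: float = 1.0) -> tuple[np.ndarray, np.ndarray, dict]:
    """Shooting records with a planted linear log-predictor.

    Features x ~ N(0, x_scale^2) i.i.d.; each outcome is a Bernoulli draw
    with P(s = -1 | x) = sigmoid(w.x + b) — i.e. the planted committor p_B.
    Returns (X, s, manifest).
    """
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    w = np.atleast_1d(np.asarray(weights, float))
    X = rng.normal(scale=x_scale, size=(n, w.shape[0]))
    p_B = sigmoid_link(X @ w + bias)
    s = np.where(rng.random(n) < p_B, -1.0, 1.0)
    manifest = {"kind": "logistic-records", "n": n, "weights": w.tolist(),
                "bias": bias, "x_scale": x_scale}
    return X, s, manifest


def planted_polylines(n_per_bundle: int, rng: np.random.Generator | int = 0,
                      n_frames: int = 40, separation: float = 2.0,
                      noise: float = 0.15) -> tuple[list[np.ndarray], np.ndarray, dict]:
    """Two bundles of noisy arcs from (-1, 0) to (1, 0), detouring through
    y = +separation/2 or y = -separation/2 — planted 2-cluster structure.

    Returns (polylines, true_labels, manifest).
    """
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    t = np.linspace(0.0, 1.0, n_frames)
    xs = -1.0 + 2.0 * t
    arc = np.sin(np.pi * t)
    polys, labels = [], []
    for sign in (1.0, -1.0):
        for _ in range(n_per_bundle):
            y = sign * (separation / 2.0) * arc + rng.normal(scale=noise, size=n_frames)
            x = xs + rng.normal(scale=noise / 2.0, size=n_frames)
            polys.append(np.column_stack([x, y]))
            labels.append(1 if sign > 0 else 2)
    manifest = {"kind": "planted-polylines", "n_per_bundle": n_per_bundle,
                "n_frames": n_frames, "separation": separation, "noise": noise}
    return polys, np.array(labels), manifest


def shooting_table(n: int, weights: np.ndarray, bias: float,
                   rng: np.random.Generator | int = 0) -> tuple[TrainingSet, dict]:
    """Offline shooting dataset as a TrainingSet (chain/step metadata filled),
    emulating pre-existing two-way shooting archives."""
    X, s, manifest = logistic_records(n, weights, bias, rng)
    ts = TrainingSet(
        ShootingRecord(X[i], outcome=int(s[i]), step_index=i // 2,
                       chain_id=str(i % 2))
        for i in range(n)
    )
    manifest["kind"] = "offline-shooting-table"
    return ts, manifest
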
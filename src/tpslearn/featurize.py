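"""Symmetry-invariant descriptors of local point environments.

Behler-style radial (G2) and radial-angular (G5) symmetry functions with a
Fermi distance cutoff describe the arrangement of neighbour points around a
central point, invariant under rotation, translation and permutation of the
neighbours.  Raw sums are divided by the expected count of neighbours (or
neighbour pairs) for an ideal isotropic gas at number density rho_N, so that
a structureless environment maps to values near 1 and inputs land roughly in
[0, 1] for training.

The radial probing volume has the closed form

    V2 ~= 8 pi r_s^2 sqrt(2/eta)        (small eta, r_cut > r_s)

and the pair variant, including the angular factor,

    V5 = 2^(1-zeta) V2 (2 zeta - 1)!! / zeta!,
    <N_pairs> ~= <N_atoms>^2 / 2            (non-negative by construction).

``g2_probe_volume_quadrature`` evaluates the defining radial integral
numerically so the accuracy of the closed form can be quantified for any
parameter set instead of being taken on faith.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.integrate import quad

__all__ = [
    "FeatureVector",
    "SymmetryFunctionParams",
    "augment_with_parameters",
    "fermi_cutoff",
    "g2",
    "g2_normalizer",
    "g2_probe_volume_quadrature",
    "g5",
    "g5_normalizer",
    "rational_switch",
    "scale_features",
    "unscale_features",
]


@dataclass(frozen=True)
class SymmetryFunctionParams:
    """Parameters of one G2 or G5 channel.

    r_s: shell radius; eta: shell width; zeta (even) and lam (+-1) shape the
    angular term (G5 only); alpha_c, r_cut define the Fermi cutoff; rho_N is
    the reference number density for the isotropic normalization.
    """

    kind: str  # "G2" or "G5"
    r_s: float
    eta: float
    alpha_c: float
    r_cut: float
    rho_N: float
    zeta: int = 2
    lam: int = 1
    target_species: str = "all"

    def __post_init__(self):
        if self.kind not in ("G2", "G5"):
            raise ValueError("kind must be 'G2' or 'G5'")
        if self.eta <= 0 or self.alpha_c <= 0 or self.r_cut <= 0 or self.r_s < 0:
            raise ValueError("eta, alpha_c, r_cut must be positive; r_s non-negative")
        if self.rho_N < 0:
            raise ValueError("rho_N must be non-negative")
        if self.kind == "G5":
            if self.zeta % 2 != 0 or self.zeta < 2:
                raise ValueError("zeta must be a positive even integer")
            if self.zeta > 16:
                raise ValueError("zeta > 16 not supported")
            if self.lam not in (-1, 1):
                raise ValueError("lam must be +1 or -1")


@dataclass(frozen=True)
class FeatureVector:
    """Named feature values plus a record of the scaling applied to them."""

    values: np.ndarray
    names: tuple[str, ...]
    scaling: dict = field(default_factory=dict)

    def __post_init__(self):
        object.__setattr__(self, "values", np.asarray(self.values, float))
        if self.values.shape != (len(self.names),):
            raise ValueError("values and names misaligned")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature values must be finite")


def fermi_cutoff(r: np.ndarray | float, alpha_c: float, r_cut: float) -> np.ndarray | float:
    """Smooth distance cutoff: [1 + exp(alpha_c (r - r_cut - 1/sqrt(alpha_c)))]^-1
    for r <= r_cut, exactly 0 beyond r_cut.

    The midpoint shift of -1/sqrt(alpha_c) places the sigmoid's half-height
    beyond r_cut, so the function steps from 1/(1+e^{-sqrt(alpha_c)}) to 0 at
    the cutoff; this is intentional and quantified by the quadrature oracle.
    """
    r = np.asarray(r, float)
    z = alpha_c * (r - r_cut - 1.0 / np.sqrt(alpha_c))
    out = np.where(r <= r_cut, 1.0 / (1.0 + np.exp(np.minimum(z, 500.0))), 0.0)
    return out if out.ndim else float(out)


def _distances(center: np.ndarray, cloud: np.ndarray) -> np.ndarray:
    d = np.asarray(cloud, float) - np.asarray(center, float)[None, :]
    return np.sqrt(np.sum(d * d, axis=1))


def g2(center: np.ndarray, cloud: np.ndarray, params: SymmetryFunctionParams,
       normalized: bool = True) -> float:
    """Radial symmetry function: shell-weighted neighbour count around center."""
    if params.kind != "G2":
        raise ValueError("params.kind must be 'G2'")
    cloud = np.asarray(cloud, float)
    if cloud.size == 0:
        return 0.0
    r = _distances(center, cloud)
    val = float(np.sum(np.exp(-params.eta * (r - params.r_s) ** 2)
                       * fermi_cutoff(r, params.alpha_c, params.r_cut)))
    if normalized:
        val /= g2_normalizer(params)
    return val


def g5(center: np.ndarray, cloud: np.ndarray, params: SymmetryFunctionParams,
       normalized: bool = True) -> float:
    """Radial-angular symmetry function over distinct neighbour pairs."""
    if params.kind != "G5":
        raise ValueError("params.kind must be 'G5'")
    cloud = np.asarray(cloud, float)
    if cloud.shape[0] < 2:
        return 0.0
    center = np.asarray(center, float)
    d = cloud - center[None, :]
    r = np.sqrt(np.sum(d * d, axis=1))
    fc = fermi_cutoff(r, params.alpha_c, params.r_cut)
    rad = np.exp(-params.eta * (r - params.r_s) ** 2)
    # cos of the angle at the center between each pair (j, k)
    with np.errstate(invalid="ignore", divide="ignore"):
        unit = np.where(r[:, None] > 0, d / r[:, None], 0.0)
    cosang = np.clip(unit @ unit.T, -1.0, 1.0)
    ang = (1.0 + params.lam * cosang) ** params.zeta
    w = rad * fc
    pair = ang * np.outer(w, w)
    iu = np.triu_indices(cloud.shape[0], k=1)
    val = float(np.sum(pair[iu]))
    if normalized:
        val /= g5_normalizer(params)
    return val


def _g2_probe_volume(params: SymmetryFunctionParams) -> float:
    return 8.0 * np.pi * params.r_s**2 * np.sqrt(2.0 / params.eta)


def g2_normalizer(params: SymmetryFunctionParams) -> float:
    """Expected isotropic neighbour count rho_N * V2, V2 ~= 8 pi r_s^2 sqrt(2/eta)."""
    if params.r_cut <= params.r_s:
        warnings.warn("closed-form probe volume assumes r_cut > r_s", stacklevel=2)
    val = params.rho_N * _g2_probe_volume(params)
    if val == 0.0:
        warnings.warn("degenerate normalizer (rho_N or r_s is zero)", stacklevel=2)
    return val


def _double_factorial_odd(n: int) -> int:
    out = 1
    while n > 1:
        out *= n
        n -= 2
    return out


def g5_normalizer(params: SymmetryFunctionParams) -> float:
    """Expected isotropic pair count (rho_N * V5)^2 / 2 with
    V5 = 2^(1-zeta) V2 (2 zeta - 1)!! / zeta!."""
    v5 = g5_probe_volume(params)
    n_atoms = params.rho_N * v5
    return n_atoms**2 / 2.0


def g5_probe_volume(params: SymmetryFunctionParams) -> float:
    from math import factorial

    v2 = _g2_probe_volume(params)
    return 2.0 ** (1 - params.zeta) * v2 * _double_factorial_odd(2 * params.zeta - 1) / factorial(params.zeta)


def g2_probe_volume_quadrature(params: SymmetryFunctionParams, tol: float = 1e-10) -> float:
    """Numerically exact probe volume 4 pi int r^2 e^{-eta (r-r_s)^2} f_c(r) dr.

    Dividing by the closed form quantifies the normalization error of the
    small-eta approximation for a given parameter set.
    """
    def integrand(r):
        return r * r * np.exp(-params.eta * (r - params.r_s) ** 2) \
            * float(fermi_cutoff(r, params.alpha_c, params.r_cut))

    val, _ = quad(integrand, 0.0, params.r_cut, epsabs=tol, epsrel=tol, limit=500)
    return 4.0 * np.pi * val


def rational_switch(r: np.ndarray | float, R0: float) -> np.ndarray | float:
    """Sigmoidal distance switch f(r) = (1-(r/R0)^6)/(1-(r/R0)^12).

    Algebraically identical to 1/(1+(r/R0)^6), which removes the 0/0 point at
    r = R0 (limit value 1/2) and is used for evaluation.
    """
    if R0 <= 0:
        raise ValueError("R0 must be positive")
    u = (np.asarray(r, float) / R0) ** 6
    out = 1.0 / (1.0 + u)
    return out if out.ndim else float(out)


def augment_with_parameters(features: FeatureVector, extra: dict[str, float]) -> FeatureVector:
    """Append named scalars (temperature, particle size sigma, ...) as features."""
    clash = set(features.names) & set(extra)
    if clash:
        raise ValueError(f"feature names already present: {sorted(clash)}")
    names = features.names + tuple(extra)
    values = np.concatenate([features.values, np.array(list(extra.values()), float)])
    scaling = dict(features.scaling)
    scaling.setdefault("augmented", []).extend(extra)
    return FeatureVector(values, names, scaling)


def scale_features(matrix: np.ndarray, method: str = "minmax",
                   normalizers: np.ndarray | None = None) -> tuple[np.ndarray, dict]:
    """Scale a (n_samples, n_features) matrix into roughly [0, 1].

    minmax maps the observed column min to 0 and max to 1 (constant columns
    map to 0, with a warning); isotropic divides by supplied normalizers (the
    symmetry-function route).  Returns the scaled matrix and an invertible
    scaling record.
    """
    X = np.asarray(matrix, float)
    if method == "minmax":
        if X.shape[0] < 2:
            raise ValueError("minmax scaling needs at least 2 rows")
        lo, hi = X.min(axis=0), X.max(axis=0)
        span = hi - lo
        const = span == 0
        if np.any(const):
            warnings.warn("constant feature column(s) mapped to 0", stacklevel=2)
        safe = np.where(const, 1.0, span)
        scaled = np.where(const, 0.0, (X - lo) / safe)
        return scaled, {"method": "minmax", "min": lo, "max": hi}
    if method == "isotropic":
        if normalizers is None:
            raise ValueError("isotropic scaling requires normalizers")
        normalizers = np.asarray(normalizers, float)
        return X / normalizers, {"method": "isotropic", "normalizers": normalizers}
    raise ValueError(f"unknown scaling method {method!r}")


def unscale_features(scaled: np.ndarray, record: dict) -> np.ndarray:
    """Invert ``scale_features`` (constant minmax columns return their min)."""
    X = np.asarray(scaled, float)
    if record["method"] == "minmax":
        lo, hi = record["min"], record["max"]
        span = hi - lo
        return np.where(span == 0, lo, X * np.where(span == 0, 1.0, span) + lo)
    if record["method"] == "isotropic":
        return X * record["normalizers"]
    raise ValueError("unknown scaling record")
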
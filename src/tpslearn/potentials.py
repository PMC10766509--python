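"""Analytic toy potentials with exact gradients.

These are the replaceable "black box" dynamics backends used to exercise the
learning loop end to end: a 1D quartic double well whose committor is known
in closed quadrature, and a 2D double well whose two transition channels are
separated by a central Gaussian bump (for multi-pathway clustering).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Potential", "QuarticDoubleWell", "TwoChannelDoubleWell"]


class Potential:
    """Base class: energy and gradient on arrays of shape ``(..., dim)``."""

    dim: int = 1
    name: str = "potential"

    def energy(self, x: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def gradient(self, x: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    @property
    def parameters(self) -> dict:
        return dict(self.__dict__)


@dataclass(frozen=True)
class QuarticDoubleWell(Potential):
    """U(x) = h (1 - (x/x0)^2)^2 — minima at ±x0, barrier height h at x = 0."""

    h: float = 4.0
    x0: float = 1.0
    dim: int = field(default=1, init=False)
    name: str = field(default="quartic_double_well", init=False)

    def energy(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        u = 1.0 - (x[..., 0] / self.x0) ** 2
        return self.h * u * u

    def gradient(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        g = np.empty_like(x)
        u = 1.0 - (x[..., 0] / self.x0) ** 2
        g[..., 0] = -4.0 * self.h * x[..., 0] * u / self.x0**2
        return g

    def energy_1d(self, x: float | np.ndarray) -> np.ndarray:
        """Scalar-coordinate energy, convenient for quadrature."""
        u = 1.0 - (np.asarray(x, dtype=float) / self.x0) ** 2
        return self.h * u * u


@dataclass(frozen=True)
class TwoChannelDoubleWell(Potential):
    """Two wells at (±1, 0) with a Gaussian bump blocking the direct channel.

    U(x, y) = h (x^2 - 1)^2 + k y^2 + g exp(-a x^2 - b y^2)

    Transition paths must detour through y > 0 or y < 0; the two channels are
    symmetric, giving a bimodal transition path ensemble.
    """

    h: float = 2.0
    k: float = 1.0
    g: float = 6.0
    a: float = 4.0
    b: float = 1.0
    dim: int = field(default=2, init=False)
    name: str = field(default="two_channel_double_well", init=False)

    def energy(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        xx, yy = x[..., 0], x[..., 1]
        bump = self.g * np.exp(-self.a * xx**2 - self.b * yy**2)
        return self.h * (xx**2 - 1.0) ** 2 + self.k * yy**2 + bump

    def gradient(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        xx, yy = x[..., 0], x[..., 1]
        bump = self.g * np.exp(-self.a * xx**2 - self.b * yy**2)
        g = np.empty_like(x)
        g[..., 0] = 4.0 * self.h * xx * (xx**2 - 1.0) - 2.0 * self.a * xx * bump
        g[..., 1] = 2.0 * self.k * yy - 2.0 * self.b * yy * bump
        return g
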
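"""Permutation-based input importance for a trained committor model.

The reference shooting loss l_ref on the unperturbed training set is
compared with the average loss over copies of the set in which one input
column has been randomly permuted across records (the batch dimension):

    delta_l_i = < l(w, theta~_i) > - l_ref.

An input the model truly uses yields a large positive delta_l; an input the
model's output does not depend on yields exactly zero, since shuffling it
leaves every prediction unchanged.  The raw (unnormalized) differences and
their ranking are what downstream symbolic regression consumes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .committor import CommittorModel, shooting_nll

__all__ = ["ImportanceResult", "permutation_importance", "restricted_importance"]


@dataclass(frozen=True)
class ImportanceResult:
    names: tuple[str, ...]
    delta_l: np.ndarray
    stderr: np.ndarray
    l_ref: float

    @property
    def ranking(self) -> np.ndarray:
        """Input indices ordered by decreasing delta_l."""
        return np.argsort(-self.delta_l, kind="stable")

    def top(self, k: int) -> list[str]:
        return [self.names[i] for i in self.ranking[:k]]


def permutation_importance(
    model: CommittorModel,
    X: np.ndarray,
    s: np.ndarray,
    n_perms: int = 100,
    rng: np.random.Generator | int = 0,
    names: tuple[str, ...] | None = None,
) -> ImportanceResult:
    """delta_l_i over ``n_perms`` column shuffles per input, with MC s.e."""
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    X = np.atleast_2d(np.asarray(X, float))
    s = np.asarray(s, float)
    if X.shape[0] < 2:
        raise ValueError("permutation importance needs at least 2 records")
    if n_perms < 1:
        raise ValueError("n_perms must be >= 1")
    n, d = X.shape
    names = names or tuple(f"x{i}" for i in range(d))
    l_ref = shooting_nll(model.q(X), s)
    delta = np.empty(d)
    se = np.empty(d)
    for i in range(d):
        losses = np.empty(n_perms)
        for p in range(n_perms):
            Xp = X.copy()
            Xp[:, i] = X[rng.permutation(n), i]
            losses[p] = shooting_nll(model.q(Xp), s)
        # subtract before averaging: a model that ignores input i then sees
        # bitwise-identical losses and delta_l is exactly zero
        delta[i] = np.mean(losses - l_ref)
        se[i] = losses.std(ddof=1) / np.sqrt(n_perms) if n_perms > 1 else np.nan
    return ImportanceResult(names, delta, se, l_ref)


def restricted_importance(
    model: CommittorModel,
    X: np.ndarray,
    s: np.ndarray,
    region_mask: np.ndarray,
    n_perms: int = 100,
    rng: np.random.Generator | int = 0,
    names: tuple[str, ...] | None = None,
) -> ImportanceResult:
    """Importance restricted to a subset of records (e.g. near one state).

    ``region_mask`` is a boolean row filter; shuffling then happens within
    the filtered subset only.
    """
    mask = np.asarray(region_mask, bool)
    X = np.atleast_2d(np.asarray(X, float))
    if mask.shape[0] != X.shape[0]:
        raise ValueError("region_mask must align with records")
    if mask.sum() < 2:
        raise ValueError("region filter keeps fewer than 2 records")
    return permutation_importance(model, X[mask], np.asarray(s)[mask],
                                  n_perms=n_perms, rng=rng, names=names)
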
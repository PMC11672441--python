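"""Shared fuzzy-membership primitive and configuration.

All three inference engines score candidates with the classic fuzzy c-means
membership function: given a point's distances ``d_1..d_c`` to ``c`` cluster
centroids and a fuzzifier ``m > 1``, the membership to cluster ``i`` is

    u_i = 1 / sum_j (d_i / d_j)^(2/(m-1))

Memberships are non-negative and sum to one over clusters. When the point
coincides with one or more centroids (distance below the floor ``epsilon``)
the unit membership is split equally among the coincident clusters — the
standard degenerate-case convention that keeps the formula total.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["FuzzyConfig", "fuzzy_membership", "membership_matrix"]


@dataclass(frozen=True)
class FuzzyConfig:
    """Parameters shared by the fuzzy engines.

    m        -- fuzzifier exponent (> 1); m -> 1 approaches hard assignment.
    epsilon  -- distance floor below which a point is treated as coincident
                with a centroid.
    max_iter -- iteration cap for the clustering engines.
    tol      -- objective-change convergence threshold for clustering.
    seed     -- RNG seed for seeded operations (centroid initialisation).
    """

    m: float = 2.0
    epsilon: float = 1e-12
    max_iter: int = 300
    tol: float = 1e-9
    seed: int | None = None

    def __post_init__(self) -> None:
        if not self.m > 1:
            raise ValueError(f"fuzzifier m must be > 1, got {self.m}")
        if not self.epsilon > 0:
            raise ValueError(f"epsilon must be > 0, got {self.epsilon}")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")


def fuzzy_membership(
    distances, m: float = 2.0, zero_tol: float = 1e-12
) -> np.ndarray:
    """Membership of one point to ``c`` clusters from its centroid distances.

    Parameters
    ----------
    distances : sequence of c non-negative finite reals
    m : fuzzifier exponent, must be > 1
    zero_tol : distances at or below this are treated as exact coincidence

    Returns
    -------
    ndarray of shape (c,), entries in [0, 1] summing to 1.
    """
    if not m > 1:
        raise ValueError(f"fuzzifier m must be > 1, got {m}")
    d = np.asarray(distances, dtype=float)
    if d.ndim != 1 or d.size < 1:
        raise ValueError("distances must be a non-empty 1-D sequence")
    if not np.all(np.isfinite(d)) or np.any(d < 0):
        raise ValueError("distances must be finite and non-negative")
    zero = d <= zero_tol
    if zero.any():
        return zero / zero.sum()
    p = 2.0 / (m - 1.0)
    inv = d ** (-p)
    return inv / inv.sum()


def membership_matrix(
    distances: np.ndarray, m: float = 2.0, zero_tol: float = 1e-12
) -> np.ndarray:
    """Row-wise :func:`fuzzy_membership` for a (points x clusters) distance matrix."""
    if not m > 1:
        raise ValueError(f"fuzzifier m must be > 1, got {m}")
    d = np.asarray(distances, dtype=float)
    if d.ndim != 2:
        raise ValueError("distance matrix must be 2-D")
    zero = d <= zero_tol
    p = 2.0 / (m - 1.0)
    with np.errstate(divide="ignore", over="ignore"):
        inv = np.where(zero, 0.0, d) ** (-p)
    inv[zero] = 0.0
    u = np.empty_like(d)
    any_zero = zero.any(axis=1)
    if any_zero.any():
        nz = zero[any_zero].sum(axis=1, keepdims=True)
        u[any_zero] = zero[any_zero] / nz
    rest = ~any_zero
    if rest.any():
        u[rest] = inv[rest] / inv[rest].sum(axis=1, keepdims=True)
    return u
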
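"""Piecewise polynomial mean trajectory of the serum drug level.

The longitudinal submodel for subject i at time t (months post-transplant) is

    Y_ij = b0 + b1*t*I(0 < t <= k) + b2*t^2*I(0 < t <= k)
              + b3*t*I(t > k) + u_i + eps_ij,     eps_ij ~ N(0, sigma^2),

with knot k (default 10 months): a quadratic early phase followed by a linear
late phase, plus a shared per-subject random intercept u_i.  The basis is
literally segment-wise — the mean is *not* constrained continuous at the knot
unless the optional continuity reparameterization is switched on.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np

from .data import LongitudinalRecord

DEFAULT_KNOT = 10.0


@dataclass
class LongFixedEffects:
    """Fixed effects and residual SD of the longitudinal submodel.

    Units: beta1 and beta3 are per month, beta2 per month squared, beta0 and
    sigma in model-scale biomarker units.
    """

    beta0: float
    beta1: float
    beta2: float
    beta3: float
    knot: float = DEFAULT_KNOT
    sigma: float = 0.1

    def __post_init__(self) -> None:
        # sigma == 0 is allowed for noise-free simulation; likelihood
        # evaluation requires sigma > 0
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if self.knot <= 0:
            raise ValueError("knot must be > 0")

    def with_continuity(self) -> "LongFixedEffects":
        """Return a copy with beta3 set so both segments meet at the knot."""
        return replace(self, beta3=self.beta1 + self.beta2 * self.knot)


def time_basis(t, knot: float = DEFAULT_KNOT):
    """Segment basis (b1, b2, b3) at time t.

    b1 = t on (0, knot], b2 = t^2 on (0, knot], b3 = t on (knot, inf); the
    knot itself belongs to the first segment.  Accepts scalars or arrays;
    raises on non-positive times.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t <= 0):
        raise ValueError("time must be > 0")
    early = t <= knot
    b1 = np.where(early, t, 0.0)
    b2 = np.where(early, t * t, 0.0)
    b3 = np.where(early, 0.0, t)
    if t.ndim == 0:
        return float(b1), float(b2), float(b3)
    return b1, b2, b3


def design_matrix(t, knot: float = DEFAULT_KNOT, continuity: bool = False) -> np.ndarray:
    """Design matrix of the fixed effects: columns [1, b1, b2, b3].

    With ``continuity`` the post-knot slope is derived (beta3 = beta1 +
    beta2*knot) and the matrix has columns [1, b1 + b3, b2 + knot*b3] for the
    free parameters (beta0, beta1, beta2).
    """
    b1, b2, b3 = time_basis(np.atleast_1d(np.asarray(t, dtype=float)), knot)
    ones = np.ones_like(b1)
    if continuity:
        return np.column_stack([ones, b1 + b3, b2 + knot * b3])
    return np.column_stack([ones, b1, b2, b3])


def mean_trajectory(t, fx: LongFixedEffects, u: float = 0.0):
    """Expected biomarker value at time t given the random intercept u."""
    b1, b2, b3 = time_basis(t, fx.knot)
    out = fx.beta0 + fx.beta1 * np.asarray(b1) + fx.beta2 * np.asarray(b2) \
        + fx.beta3 * np.asarray(b3) + u
    return float(out) if np.ndim(out) == 0 else out


def _times_values(measurements) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(measurements, tuple) and len(measurements) == 2 and \
            not isinstance(measurements[0], LongitudinalRecord):
        t, y = measurements
        return np.asarray(t, dtype=float), np.asarray(y, dtype=float)
    t = np.array([m.time for m in measurements], dtype=float)
    y = np.array([m.y for m in measurements], dtype=float)
    return t, y


def long_loglik_given_u(
    measurements: Sequence[LongitudinalRecord] | tuple[np.ndarray, np.ndarray],
    fx: LongFixedEffects,
    u: float,
) -> float:
    """Gaussian log-likelihood of the measurements conditional on u.

    Accepts a sequence of LongitudinalRecord or a ``(times, values)`` pair of
    arrays.  An empty sequence contributes 0.
    """
    t, y = _times_values(measurements)
    if fx.sigma <= 0:
        raise ValueError("likelihood evaluation requires sigma > 0")
    if t.size == 0:
        return 0.0
    resid = y - mean_trajectory(t, fx, u)
    n = t.size
    return float(
        -0.5 * n * np.log(2.0 * np.pi * fx.sigma**2)
        - 0.5 * np.sum(resid**2) / fx.sigma**2
    )
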
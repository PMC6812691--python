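"""Circular statistics: von Mises fitting and the Jammalamadaka-Sarma
circular correlation, used to test whether wind direction is associated with
rafting direction.

Angles are radians in [0, 2pi).  The JS correlation is the circular analogue
of the Pearson product-moment coefficient,

    r = sum sin(a_i - abar) sin(b_i - bbar)
        / sqrt( sum sin^2(a_i - abar) * sum sin^2(b_i - bbar) ),

with abar, bbar the circular means.  Its large-sample test statistic is
z = sqrt(n * l20 * l02 / l22) * r with l_jk the mixed sine moments; z is
asymptotically standard normal under independence.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq
from scipy.special import i0e, i1e
from scipy.stats import norm

__all__ = [
    "MAX_KAPPA",
    "CircCorrResult",
    "CircularError",
    "wrap_angle",
    "circular_mean",
    "resultant_length",
    "fit_vonmises",
    "circular_correlation_js",
]

#: Concentration cap for degenerate (all-equal) samples.
MAX_KAPPA = 1e6


class CircularError(ValueError):
    """Undefined circular quantity (zero resultant, degenerate margin...)."""


@dataclass(frozen=True)
class CircCorrResult:
    r: float
    z: float
    p: float
    n: int
    p_permutation: float | None = None


def wrap_angle(theta):
    """Reduce angles (radians) to [0, 2pi)."""
    return np.mod(theta, 2.0 * np.pi)


def _validated(angles) -> np.ndarray:
    a = np.asarray(angles, dtype=float)
    if a.size == 0:
        raise CircularError("empty angle sample")
    if not np.isfinite(a).all():
        raise CircularError("non-finite angle in sample")
    return wrap_angle(a)


def resultant_length(angles) -> float:
    """Mean resultant length R-bar in [0, 1]."""
    a = _validated(angles)
    return float(np.hypot(np.mean(np.sin(a)), np.mean(np.cos(a))))


def circular_mean(angles) -> float:
    """Circular mean direction in [0, 2pi); undefined at zero resultant."""
    a = _validated(angles)
    s, c = np.mean(np.sin(a)), np.mean(np.cos(a))
    if math.hypot(s, c) < 1e-12:
        raise CircularError("circular mean undefined: zero resultant length")
    return float(wrap_angle(math.atan2(s, c)))


def _A(kappa: float) -> float:
    """A(kappa) = I1(kappa)/I0(kappa), computed with exponentially scaled
    Bessel functions for stability at large kappa."""
    return i1e(kappa) / i0e(kappa)


def fit_vonmises(angles) -> tuple[float, float]:
    """Maximum-likelihood von Mises fit: (mean direction mu, concentration kappa).

    kappa solves A(kappa) = R-bar by bracketed root finding; for R-bar at or
    beyond the A(MAX_KAPPA) saturation point kappa is capped at ``MAX_KAPPA``.
    """
    a = _validated(angles)
    if a.size < 2:
        raise CircularError("need at least 2 angles to fit a von Mises distribution")
    mu = circular_mean(a)
    rbar = resultant_length(a)
    if rbar <= 0.0:
        return mu, 0.0
    if rbar >= _A(MAX_KAPPA):
        return mu, MAX_KAPPA
    kappa = brentq(lambda k: _A(k) - rbar, 1e-12, MAX_KAPPA, xtol=1e-10, rtol=1e-12)
    return mu, float(kappa)


def circular_correlation_js(
    alpha,
    beta,
    permutation_reps: int = 0,
    seed: int = 0,
) -> CircCorrResult:
    """Jammalamadaka-Sarma circular correlation between paired angle samples.

    Two-sided p-value from the normal asymptotic of z; optionally also a
    seeded permutation p-value (``permutation_reps`` shuffles of ``beta``)
    for small samples.
    """
    a = _validated(alpha)
    b = _validated(beta)
    if a.shape != b.shape:
        raise CircularError(f"paired samples must match in length: {a.size} vs {b.size}")
    n = a.size
    if n < 3:
        raise CircularError(f"need at least 3 pairs, got {n}")

    sa = np.sin(a - circular_mean(a))
    sb = np.sin(b - circular_mean(b))
    den = math.sqrt(float(np.sum(sa**2)) * float(np.sum(sb**2)))
    if den < 1e-12:
        raise CircularError("degenerate margin: all sine deviations are zero")
    r = float(np.sum(sa * sb) / den)

    l20 = float(np.mean(sa**2))
    l02 = float(np.mean(sb**2))
    l22 = float(np.mean(sa**2 * sb**2))
    if l22 < 1e-300:
        raise CircularError("degenerate fourth moment")
    z = math.sqrt(n * l20 * l02 / l22) * r
    p = 2.0 * norm.sf(abs(z))

    p_perm = None
    if permutation_reps > 0:
        rng = np.random.default_rng(seed)
        mb = circular_mean(b)
        exceed = 0
        ssa = float(np.sum(sa**2))
        for _ in range(permutation_reps):
            sbp = np.sin(rng.permutation(b) - mb)
            denp = math.sqrt(ssa * float(np.sum(sbp**2)))
            rp = float(np.sum(sa * sbp) / denp)
            if abs(rp) >= abs(r) - 1e-15:
                exceed += 1
        p_perm = (exceed + 1) / (permutation_reps + 1)

    return CircCorrResult(r=r, z=z, p=float(p), n=int(n), p_permutation=p_perm)
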
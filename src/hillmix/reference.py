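"""Literature reference surfaces for binary mixtures.

These are the classical comparison models: generalised concentration
addition (GCA), the Chou-Talalay median-effect surfaces (mutually exclusive
and non-exclusive), the implicit Loewe/concentration-addition equation, and
the linear truncation of the Minto/Fidler polynomial expansion of the mixed
slope and maximum.  Each operates on scaled doses m_i = d_i / EC50_i and,
in its stated parameter regime, coincides with the null-interaction Hill
surface of :mod:`hillmix.models`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .models import HillCurve, hill_effect

__all__ = [
    "PotencyFraction",
    "u_gca",
    "u_chou",
    "ca_effect",
    "minto_linear_gamma",
    "minto_linear_umax",
]

_SLOPE_TOL = 1e-12


@dataclass(frozen=True)
class PotencyFraction:
    """theta_p = m_a / (m_a + m_b), the scaled-dose fraction of drug A."""

    theta_p: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.theta_p <= 1.0:
            raise ValueError("theta_p must lie in [0, 1]")

    @classmethod
    def from_scaled_doses(cls, m_a: float, m_b: float) -> "PotencyFraction":
        if m_a < 0 or m_b < 0 or m_a + m_b == 0:
            raise ValueError("need nonnegative scaled doses, not both zero")
        return cls(m_a / (m_a + m_b))


def _scaled(curves: tuple[HillCurve, HillCurve], doses) -> tuple[np.ndarray, np.ndarray]:
    d = np.atleast_2d(np.asarray(doses, dtype=float))
    if d.shape[-1] != 2:
        raise ValueError("binary reference models need 2-component doses")
    if np.any(d < 0):
        raise ValueError("doses must be nonnegative")
    a, b = curves
    return d[..., 0] / a.ec50, d[..., 1] / b.ec50


def u_gca(curves: tuple[HillCurve, HillCurve], doses):
    """Generalised concentration addition surface (slope-1 drugs).

    u = (a_max m_a + b_max m_b) / (1 + a_max m_a + b_max m_b); admits
    partial agonists but requires unit Hill slopes and zero baseline.
    """
    for c in curves:
        if abs(c.slope - 1.0) > _SLOPE_TOL:
            raise ValueError(f"GCA requires slope 1, got {c.slope} for {c.name}")
        if c.e0 != 0:
            raise ValueError("GCA requires zero baseline (e0 = 0)")
    m_a, m_b = _scaled(curves, doses)
    s = curves[0].emax * m_a + curves[1].emax * m_b
    out = s / (1.0 + s)
    d = np.asarray(doses, dtype=float)
    return out if d.ndim > 1 else float(out[0])


def u_chou(
    curves: tuple[HillCurve, HillCurve],
    doses,
    gamma: float,
    umax: float,
    exclusive: bool = True,
):
    """Chou-Talalay median-effect surface with shared slope and maximum.

    Exclusive:      u = umax (m_a + m_b)^gamma / (1 + (m_a + m_b)^gamma)
    Non-exclusive:  the bracket gains the product term m_a m_b.
    """
    m_a, m_b = _scaled(curves, doses)
    bracket = m_a + m_b if exclusive else m_a + m_b + m_a * m_b
    with np.errstate(divide="ignore"):
        p = np.where(bracket > 0, bracket**gamma, 0.0)
    out = umax * p / (1.0 + p)
    d = np.asarray(doses, dtype=float)
    return out if d.ndim > 1 else float(out[0])


def ca_effect(
    curves: tuple[HillCurve, HillCurve],
    doses,
    tol: float = 1e-12,
):
    """Loewe concentration-addition effect from the implicit isobole equation.

    Solves 1 = m_a / (u/(a_max - u))^(1/gamma_a) + m_b / (u/(b_max - u))^(1/gamma_b)
    for u by bracketed root finding; a zero dose short-circuits to the other
    compound's Hill effect (the implicit equation degenerates there).
    Requires zero baselines and positive slopes.
    """
    a, b = curves
    for c in curves:
        if c.e0 != 0:
            raise ValueError("ca_effect requires zero baseline (e0 = 0)")
        if c.slope <= 0:
            raise ValueError("ca_effect requires positive slopes")
    d = np.atleast_2d(np.asarray(doses, dtype=float))
    m_a, m_b = _scaled(curves, d)

    cap = min(a.emax, b.emax)
    out = np.empty(d.shape[0])
    for i in range(d.shape[0]):
        da, db = d[i]
        if da == 0 and db == 0:
            out[i] = 0.0
            continue
        if db == 0:
            out[i] = hill_effect(a, da)
            continue
        if da == 0:
            out[i] = hill_effect(b, db)
            continue

        ma, mb = m_a[i], m_b[i]

        def lhs(u):
            ta = ma / (u / (a.emax - u)) ** (1.0 / a.slope)
            tb = mb / (u / (b.emax - u)) ** (1.0 / b.slope)
            return ta + tb - 1.0

        lo, hi = 1e-12, cap - 1e-12
        flo, fhi = lhs(lo), lhs(hi)
        if not (flo > 0 > fhi):
            raise RuntimeError(
                f"no CA root bracketed in (0, {cap}) at dose {d[i].tolist()}"
            )
        u = brentq(lhs, lo, hi, xtol=1e-15, rtol=8.9e-16)
        if abs(lhs(u)) > 1e-10:
            raise RuntimeError("CA root did not converge to |lhs - 1| <= 1e-10")
        out[i] = u
    dd = np.asarray(doses, dtype=float)
    return out if dd.ndim > 1 else float(out[0])


def _theta(theta) -> float:
    t = theta.theta_p if isinstance(theta, PotencyFraction) else float(theta)
    if not 0.0 <= t <= 1.0:
        raise ValueError("theta must lie in [0, 1]")
    return t


def minto_linear_gamma(slopes: tuple[float, float], theta) -> float:
    """Linear-in-theta mixed slope: gamma(theta) = alpha theta + beta (1 - theta).

    With theta = m_a/(m_a + m_b) this equals the scaled-dose-weighted slope
    mixing of the null-interaction Hill surface.
    """
    t = _theta(theta)
    return slopes[0] * t + slopes[1] * (1.0 - t)


def minto_linear_umax(maxima: tuple[float, float], theta) -> float:
    """Linear-in-theta mixed maximum, analogous to :func:`minto_linear_gamma`."""
    t = _theta(theta)
    return maxima[0] * t + maxima[1] * (1.0 - t)
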
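"""Hill curves and Hill-type mixture response surfaces.

The single-compound dose-response law is the 4-parameter Hill equation

    E(d) = E0 + (Emax - E0) / (1 + (EC50 / d)^alpha),

the solution of a Riccati-type (generalised logistic) ODE in log-dose.  For
an n-compound mixture the same principle — that the joint response is again
a Hill-type function in log-dose along rays of fixed mixture ratio — leads
to a semilinear Riccati PDE,

    sum_i du/dx_i = gamma(x) (u - u_min)(u_max(x) - u) / (u_max(x) - u_min),

whose solutions used here are built from *scaled doses* m_i = d_i / EC50_i:

* the **null-interaction surface** ``u_null`` mixes the pure-compound slopes
  and maxima with weights m_i and responds to the plain dose sum,
    u = u_min + (u_max - u_min) / (1 + (sum_i m_i)^(-gamma));

* the **full-interaction surface** ``u_ricc`` augments every ingredient of
  that formula with perturbations of the individual Hill parameters
  (additive shifts of Emax and slope, a multiplicative shift of EC50) and
  with k-tuple interaction terms entering through k-th roots of products of
  k scaled doses, ``delta * (prod_{i in S} m_i)^(1/|S|)``.

Both surfaces satisfy the PDE exactly for *any* parameter values, because
the diagonal derivative operator acts as the identity on every k-th-root
exponential term; :func:`pde_residual` verifies this numerically.  With all
perturbation and interaction parameters at their inactive values the full
surface reduces identically to the null surface.

The total number of free parameters for n compounds is
``3n + 3(2^n - n - 1) = 3(2^n - 1)``: 9 for binary, 21 for ternary, 45 for
quaternary mixtures (:func:`parameter_count`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "HillCurve",
    "PerturbationSet",
    "InteractionSet",
    "MixtureModel",
    "BracketError",
    "hill_effect",
    "scaled_doses",
    "u_null",
    "u_ricc",
    "pde_residual",
    "parameter_count",
    "interaction_subsets",
]

# Bracket floor before exponentiation; guards log of a vanishing dose sum.
_TINY = 1e-300


class BracketError(ValueError):
    """The interaction-augmented dose bracket became negative.

    Raised when a too-negative position-interaction coefficient ``d_m``
    makes ``sum_i m_i + sum_S d_m_S (prod m)^{1/|S|}`` negative at a
    requested dose, where the surface is undefined.
    """


@dataclass(frozen=True)
class HillCurve:
    """One compound's 4-parameter Hill dose-response curve.

    Parameters
    ----------
    name
        Compound label.
    e0
        Baseline effect fraction (response at zero dose).
    emax
        Maximum effect fraction; ``0 <= e0 <= emax <= 1``.
    ec50
        Median-effect dose (same units as the doses fed in), > 0.
    slope
        Hill coefficient; nonzero, positive for effects increasing
        with dose.
    """

    name: str
    e0: float
    emax: float
    ec50: float
    slope: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.e0 <= self.emax <= 1.0:
            raise ValueError(
                f"{self.name}: need 0 <= e0 <= emax <= 1, got e0={self.e0}, "
                f"emax={self.emax}"
            )
        if not self.ec50 > 0:
            raise ValueError(f"{self.name}: ec50 must be > 0")
        if self.slope == 0:
            raise ValueError(f"{self.name}: slope must be nonzero")

    def effect(self, dose):
        return hill_effect(self, dose)


def hill_effect(curve: HillCurve, dose):
    """Hill equation effect at ``dose`` (scalar or array), doses >= 0."""
    d = np.asarray(dose, dtype=float)
    if np.any(d < 0):
        raise ValueError("dose must be nonnegative")
    m = d / curve.ec50
    with np.errstate(divide="ignore", over="ignore"):
        frac = np.where(m > 0, 1.0 / (1.0 + np.maximum(m, _TINY) ** -curve.slope), 0.0)
    out = curve.e0 + (curve.emax - curve.e0) * frac
    return out if out.ndim else float(out)


def parameter_count(n: int) -> int:
    """Total perturbation + interaction parameters for an n-compound surface.

    3 perturbations per compound plus 3 parameters for every subset of
    2..n compounds: ``3n + 3(2^n - n - 1) = 3(2^n - 1)``.
    """
    if n < 2:
        raise ValueError("parameter_count requires n >= 2")
    return 3 * (2**n - 1)


def interaction_subsets(n: int) -> list[tuple[int, ...]]:
    """All index subsets of size 2..n, in (size, lexicographic) order."""
    return [t for k in range(2, n + 1) for t in combinations(range(n), k)]


@dataclass
class PerturbationSet:
    """Per-compound shifts of the pure Hill parameters inside a mixture.

    ``d_emax`` and ``d_slope`` are additive shifts of the maximum effect and
    the slope; ``d_m50`` is a multiplicative shift of the median-effect dose
    (the inactive value is 1).  Inactive entries are exactly (0, 0, 1).
    """

    d_emax: np.ndarray
    d_slope: np.ndarray
    d_m50: np.ndarray

    def __post_init__(self) -> None:
        self.d_emax = np.asarray(self.d_emax, dtype=float)
        self.d_slope = np.asarray(self.d_slope, dtype=float)
        self.d_m50 = np.asarray(self.d_m50, dtype=float)
        if not (self.d_emax.shape == self.d_slope.shape == self.d_m50.shape):
            raise ValueError("perturbation arrays must share one length")
        if np.any(self.d_m50 <= 0):
            raise ValueError("d_m50 entries must be > 0")

    @classmethod
    def inactive(cls, n: int) -> "PerturbationSet":
        return cls(np.zeros(n), np.zeros(n), np.ones(n))

    @property
    def is_inactive(self) -> bool:
        return (
            np.all(self.d_emax == 0)
            and np.all(self.d_slope == 0)
            and np.all(self.d_m50 == 1)
        )


@dataclass
class InteractionSet:
    """k-tuple interaction coefficients, one triple per compound subset.

    For every subset S with 2 <= |S| <= n there are three coefficients:
    ``d_m`` (position), ``d_emax`` (maximum effect) and ``d_slope`` (slope),
    each multiplying ``(prod_{i in S} m_i)^(1/|S|)`` in the bracket, the
    u_max numerator and the gamma numerator respectively.  Subsets are keyed
    by sorted index tuples; missing keys mean (0, 0, 0), the inactive value.
    """

    n: int
    d_m: dict[tuple[int, ...], float] = field(default_factory=dict)
    d_emax: dict[tuple[int, ...], float] = field(default_factory=dict)
    d_slope: dict[tuple[int, ...], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        valid = set(interaction_subsets(self.n))
        for name in ("d_m", "d_emax", "d_slope"):
            d = {tuple(sorted(k)): float(v) for k, v in getattr(self, name).items()}
            unknown = set(d) - valid
            if unknown:
                raise ValueError(f"{name}: invalid subset key(s) {sorted(unknown)}")
            setattr(self, name, d)

    @classmethod
    def inactive(cls, n: int) -> "InteractionSet":
        return cls(n)

    @property
    def is_inactive(self) -> bool:
        return not (
            any(self.d_m.values()) or any(self.d_emax.values()) or any(self.d_slope.values())
        )


@dataclass
class MixtureModel:
    """n Hill curves plus perturbation and interaction parameters.

    Fully determines the full-interaction surface :func:`u_ricc` (and the
    null surface :func:`u_null`, which ignores all perturbation/interaction
    entries).  ``umin_mode`` selects the baseline: ``"constant"`` (the
    physical choice — the no-drug response cannot depend on which drug was
    withheld) uses ``umin_value`` (default: the common e0 of the curves);
    ``"mixed"`` dose-weights the individual baselines.
    """

    curves: list[HillCurve]
    perturbations: PerturbationSet | None = None
    interactions: InteractionSet | None = None
    umin_mode: str = "constant"
    umin_value: float | None = None

    def __post_init__(self) -> None:
        self.curves = list(self.curves)
        n = len(self.curves)
        if n < 1:
            raise ValueError("need at least one curve")
        if self.perturbations is None:
            self.perturbations = PerturbationSet.inactive(n)
        if self.interactions is None:
            self.interactions = InteractionSet.inactive(n)
        if len(self.perturbations.d_emax) != n:
            raise ValueError("perturbation set length does not match curves")
        if self.interactions.n != n:
            raise ValueError("interaction set n does not match curves")
        if self.umin_mode not in ("constant", "mixed"):
            raise ValueError("umin_mode must be 'constant' or 'mixed'")
        emax = np.array([c.emax for c in self.curves])
        if np.any(emax + self.perturbations.d_emax > 1.0 + 1e-12):
            bad = [
                self.curves[i].name
                for i in np.where(emax + self.perturbations.d_emax > 1.0 + 1e-12)[0]
            ]
            raise ValueError(f"emax + d_emax exceeds 1 for {bad}")
        if self.umin_mode == "constant" and self.umin_value is None:
            e0s = {c.e0 for c in self.curves}
            if len(e0s) > 1:
                raise ValueError(
                    "constant umin requested but curve baselines differ; "
                    "pass umin_value explicitly"
                )
            self.umin_value = float(e0s.pop())

    # -- convenience -------------------------------------------------------
    @property
    def n(self) -> int:
        return len(self.curves)

    @property
    def names(self) -> list[str]:
        return [c.name for c in self.curves]

    @property
    def is_null(self) -> bool:
        return self.perturbations.is_inactive and self.interactions.is_inactive

    def ec50(self) -> np.ndarray:
        return np.array([c.ec50 for c in self.curves])

    def null_model(self) -> "MixtureModel":
        return MixtureModel(
            self.curves, None, None, self.umin_mode, self.umin_value
        )


def scaled_doses(model: MixtureModel, doses, shifted: bool = False) -> np.ndarray:
    """Scaled doses m_i = d_i / EC50_i, optionally EC50-shift perturbed.

    With ``shifted`` the perturbed median ``EC50_i * d_m50_i`` is used, i.e.
    m_i = d_i / (EC50_i d_m50_i); m_i is zero exactly where d_i is zero.
    """
    d = np.asarray(doses, dtype=float)
    if np.any(d < 0) or not np.all(np.isfinite(d)):
        raise ValueError("doses must be nonnegative and finite")
    denom = model.ec50()
    if shifted:
        denom = denom * model.perturbations.d_m50
    return d / denom


def _geo_terms(m: np.ndarray, subsets: Sequence[tuple[int, ...]]) -> dict:
    """(prod_{i in S} m_i)^{1/|S|} per subset; zero where any member is 0."""
    out = {}
    for t in subsets:
        out[t] = np.prod(m[..., t], axis=-1) ** (1.0 / len(t))
    return out


def _sigmoid_power(S: np.ndarray, gamma: np.ndarray) -> np.ndarray:
    """1 / (1 + S^(-gamma)) with under/overflow guarded."""
    logS = np.log(np.maximum(S, _TINY))
    expo = np.clip(-gamma * logS, -745.0, 745.0)
    return 1.0 / (1.0 + np.exp(expo))


def _surface_terms(model: MixtureModel, doses, *, null: bool):
    """Effective (u, u_max, gamma, u_min) of the surface at each dose row.

    The null path ignores every perturbation/interaction entry and uses
    unshifted scaled doses throughout (the strict-null evaluation); the full
    path uses EC50-shifted scaled doses in every term, as the dose-domain
    form of the surface is written.
    """
    d = np.atleast_2d(np.asarray(doses, dtype=float))
    n = model.n
    if d.shape[-1] != n:
        raise ValueError(f"dose vectors must have length {n}")
    m = scaled_doses(model, d, shifted=not null)

    emax = np.array([c.emax for c in model.curves])
    e0 = np.array([c.e0 for c in model.curves])
    slope = np.array([c.slope for c in model.curves])

    msum = m.sum(axis=-1)
    zero = msum == 0
    safe = np.where(zero, 1.0, msum)
    # m-weighted mixing of the pure slopes and maxima
    gamma = (slope * m).sum(axis=-1) / safe
    umax = (emax * m).sum(axis=-1) / safe
    if model.umin_mode == "mixed":
        umin = (e0 * m).sum(axis=-1) / safe
        umin = np.where(zero, e0.mean(), umin)
    else:
        umin = np.full_like(msum, model.umin_value)

    S = msum.copy()
    if not null:
        subs = interaction_subsets(n)
        g = _geo_terms(m, subs)
        denom_full = msum + sum(g.values())
        safe_full = np.where(zero, 1.0, denom_full)

        pert, inter = model.perturbations, model.interactions
        d_emax_num = (pert.d_emax * m).sum(axis=-1)
        d_slope_num = (pert.d_slope * m).sum(axis=-1)
        for t in subs:
            gt = g[t]
            cm = inter.d_m.get(t, 0.0)
            if cm:
                S = S + cm * gt
            ca = inter.d_emax.get(t, 0.0)
            if ca:
                d_emax_num = d_emax_num + ca * gt
            cs = inter.d_slope.get(t, 0.0)
            if cs:
                d_slope_num = d_slope_num + cs * gt
        umax = umax + d_emax_num / safe_full
        gamma = gamma + d_slope_num / safe_full

        neg = S < 0
        if np.any(neg):
            worst = min(inter.d_m.items(), key=lambda kv: kv[1], default=(None, 0.0))
            names = (
                tuple(model.names[i] for i in worst[0]) if worst[0] else "unknown"
            )
            raise BracketError(
                f"dose bracket negative at {int(neg.sum())} dose point(s); "
                f"position interaction d_m{names} = {worst[1]} is too negative"
            )

    frac = _sigmoid_power(S, gamma)
    u = umin + (umax - umin) * frac
    u = np.where(zero, umin, u)
    return u, np.where(zero, umin, umax), gamma, umin, zero


def u_null(model: MixtureModel, doses):
    """Null-interaction (reference) surface at the given dose vector(s).

    All perturbation and interaction entries of ``model`` are ignored.  At
    the all-zero dose the continuous limit ``u_min`` is returned; on a
    single-compound axis the value is exactly that compound's Hill curve.
    """
    u, *_ = _surface_terms(model, doses, null=True)
    d = np.asarray(doses, dtype=float)
    return u if d.ndim > 1 else float(u[0])


def u_ricc(model: MixtureModel, doses):
    """Full-interaction (Riccati) surface at the given dose vector(s).

    Reduces to :func:`u_null` when the model carries no active perturbation
    or interaction parameters.  On a single-compound axis all interaction
    terms vanish automatically and the value is the perturbed Hill curve of
    that compound.
    """
    u, *_ = _surface_terms(model, doses, null=False)
    d = np.asarray(doses, dtype=float)
    return u if d.ndim > 1 else float(u[0])


def pde_residual(
    model: MixtureModel,
    log_dose_point,
    surface: str = "ricc",
    step: float = 1e-5,
) -> float:
    """Numerical residual of the governing Riccati PDE at one log-dose point.

    Central differences estimate ``sum_i du/dx_i`` (x_i = ln d_i) and the
    right-hand side ``gamma (u - u_min)(u_max - u)/(u_max - u_min)`` is
    evaluated with the surface's own effective gamma and u_max (including
    the perturbation/interaction contributions for the full surface).  For
    valid solutions the residual vanishes as ``step -> 0``.
    """
    x = np.asarray(log_dose_point, dtype=float)
    if x.shape != (model.n,) or not np.all(np.isfinite(x)):
        raise ValueError("log_dose_point must be a finite vector of length n")
    null = surface == "null"
    if surface not in ("null", "ricc"):
        raise ValueError("surface must be 'null' or 'ricc'")

    d0 = np.exp(x)
    u0, umax, gamma, umin, _ = _surface_terms(model, d0[None, :], null=null)
    u0, umax, gamma, umin = u0[0], umax[0], gamma[0], umin[0]

    dsum = 0.0
    for i in range(model.n):
        xp = x.copy()
        xp[i] += step
        xm = x.copy()
        xm[i] -= step
        up, *_ = _surface_terms(model, np.exp(xp)[None, :], null=null)
        um, *_ = _surface_terms(model, np.exp(xm)[None, :], null=null)
        dsum += (up[0] - um[0]) / (2.0 * step)

    rhs = gamma * (u0 - umin) * (umax - u0) / (umax - umin)
    return float(dsum - rhs)
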
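"""Constrained estimation of mixture response-surface parameters.

Workflow: the pure-compound Hill curves are fitted first
(:func:`fit_pure`) and then held fixed; the perturbation/interaction
parameters selected by a :class:`ParameterMask` are estimated by bounded
nonlinear least squares with deterministic Latin-hypercube multi-start
(:func:`fit_mixture`); :func:`reduce_model` performs backward elimination
of parameters guided by the Akaike information criterion until no removal
improves it.

Fit quality is summarised by RSS/RMSE/adjusted r^2/AIC
(:func:`fit_statistics`), a two-sample Wilcoxon-Mann-Whitney test that the
observed and modelled effects describe the same distribution
(:func:`mw_test`), and a Shapiro-Wilk test for normality of the residuals
(:func:`shapiro_test`).

AIC convention: Gaussian likelihood with the MLE variance
``sigma^2 = RSS/N`` gives ``ln L = -N/2 (ln(2 pi sigma^2) + 1)`` and
``AIC = 2k - 2 ln L`` with k counting active surface parameters only.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy import stats
from scipy.optimize import least_squares
from scipy.stats import qmc

from .models import (
    BracketError,
    HillCurve,
    InteractionSet,
    MixtureModel,
    PerturbationSet,
    hill_effect,
    u_null,
    u_ricc,
)
from .table import DoseResponseTable

__all__ = [
    "ParameterMask",
    "FitStats",
    "FitResult",
    "fit_statistics",
    "mw_test",
    "shapiro_test",
    "fit_pure",
    "fit_mixture",
    "reduce_model",
    "null_reference_rmse",
    "informative_reference_rows",
]

# Fit bounds per parameter kind.  d_emax per compound is additionally capped
# so that emax_i + d_emax_i <= 1 (physically possible responses only); the
# d_m lower bound keeps the dose bracket positive on typical data ranges and
# is re-checked per fit.
_BOUNDS = {
    "demax_pert": (-1.0, 1.0),
    "demax_int": (-1.0, 1.0),
    "dslope": (-20.0, 20.0),
    "dm50": (0.01, 100.0),
    "dm": (-1.9, 50.0),
}
# Narrower windows used only to place multi-start points.
_START = {
    "demax_pert": (-0.5, 0.5),
    "demax_int": (-0.5, 0.5),
    "dslope": (-15.0, 15.0),
    "dm50": (0.1, 10.0),
    "dm": (-1.5, 5.0),
}


def _subset_label(names: tuple[str, ...]) -> str:
    return "+".join(sorted(names))


class ParameterMask:
    """Set of active perturbation/interaction parameters of a mixture model.

    Parameters are addressed by string ids: ``demax[name]``,
    ``dslope[name]``, ``dm50[name]`` for the per-compound perturbations and
    ``demax[a+b]``, ``dslope[a+b]``, ``dm[a+b]`` for every subset of two or
    more compounds (names sorted alphabetically inside the brackets).
    Parameters not in the mask are pinned at their inactive values (0, or 1
    for the multiplicative ``dm50``).
    """

    def __init__(self, names: list[str], active: set[str] | frozenset[str] = frozenset()):
        self.names = list(names)
        valid = set(self.all_ids(self.names))
        active = frozenset(active)
        unknown = active - valid
        if unknown:
            raise ValueError(f"unknown parameter id(s): {sorted(unknown)}")
        self.active = active

    # -- constructors ------------------------------------------------------
    @staticmethod
    def all_ids(names: list[str]) -> list[str]:
        ids = []
        for nm in names:
            ids += [f"demax[{nm}]", f"dslope[{nm}]", f"dm50[{nm}]"]
        n = len(names)
        for k in range(2, n + 1):
            for t in combinations(range(n), k):
                lab = _subset_label(tuple(names[i] for i in t))
                ids += [f"demax[{lab}]", f"dslope[{lab}]", f"dm[{lab}]"]
        return ids

    @classmethod
    def full(cls, names: list[str]) -> "ParameterMask":
        return cls(names, set(cls.all_ids(names)))

    @classmethod
    def interactions_only(
        cls, names: list[str], subsets: list[tuple[str, ...]] | None = None
    ) -> "ParameterMask":
        """All (or the given) subset interaction triples, no perturbations."""
        ids = set()
        n = len(names)
        all_subsets = [
            tuple(names[i] for i in t)
            for k in range(2, n + 1)
            for t in combinations(range(n), k)
        ]
        wanted = all_subsets if subsets is None else [tuple(s) for s in subsets]
        for s in wanted:
            lab = _subset_label(s)
            ids |= {f"demax[{lab}]", f"dslope[{lab}]", f"dm[{lab}]"}
        return cls(names, ids)

    @classmethod
    def empty(cls, names: list[str]) -> "ParameterMask":
        return cls(names)

    # -- set protocol ------------------------------------------------------
    def __len__(self) -> int:
        return len(self.active)

    def __iter__(self):
        return iter(self.ordered())

    def __contains__(self, pid: str) -> bool:
        return pid in self.active

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, ParameterMask)
            and set(self.names) == set(other.names)
            and self.active == other.active
        )

    def ordered(self) -> list[str]:
        """Deterministic (alphabetical) parameter order used by the fitter."""
        return sorted(self.active)

    def without(self, pid: str) -> "ParameterMask":
        if pid not in self.active:
            raise KeyError(pid)
        return ParameterMask(self.names, self.active - {pid})

    def __repr__(self) -> str:
        return f"ParameterMask({sorted(self.active)})"


def _param_kind(pid: str) -> str:
    head, inner = pid.split("[", 1)
    inner = inner[:-1]
    if head == "dm50":
        return "dm50"
    if head == "dm":
        return "dm"
    if head == "dslope":
        return "dslope"
    return "demax_int" if "+" in inner else "demax_pert"


def _inactive_value(pid: str) -> float:
    return 1.0 if _param_kind(pid) == "dm50" else 0.0


def _param_bounds(pid: str, curves: list[HillCurve]) -> tuple[float, float]:
    kind = _param_kind(pid)
    lo, hi = _BOUNDS[kind]
    if kind == "demax_pert":
        name = pid.split("[", 1)[1][:-1]
        emax = next(c.emax for c in curves if c.name == name)
        hi = min(hi, 1.0 - emax)  # hard physical cap emax + d_emax <= 1
    return lo, hi


def build_model(
    curves: list[HillCurve],
    mask: ParameterMask,
    values: dict[str, float] | np.ndarray,
    umin_value: float | None = None,
) -> MixtureModel:
    """Assemble a :class:`MixtureModel` from active parameter values.

    ``values`` may be a dict keyed by parameter id or a vector in the
    mask's :meth:`ParameterMask.ordered` order.
    """
    names = [c.name for c in curves]
    if set(mask.names) != set(names):
        raise ValueError("mask compound names do not match curves")
    if not isinstance(values, dict):
        values = dict(zip(mask.ordered(), np.asarray(values, dtype=float)))
    pert = PerturbationSet.inactive(len(curves))
    inter = InteractionSet.inactive(len(curves))
    pos = {nm: i for i, nm in enumerate(names)}
    label_to_idx = {}
    for k in range(2, len(names) + 1):
        for t in combinations(range(len(names)), k):
            label_to_idx[_subset_label(tuple(names[i] for i in t))] = t
    for pid in mask.ordered():
        v = float(values[pid])
        head, inner = pid.split("[", 1)
        inner = inner[:-1]
        if "+" in inner or inner not in pos:
            t = label_to_idx[inner]
            {"demax": inter.d_emax, "dslope": inter.d_slope, "dm": inter.d_m}[head][t] = v
        else:
            i = pos[inner]
            if head == "demax":
                pert.d_emax[i] = v
            elif head == "dslope":
                pert.d_slope[i] = v
            else:
                pert.d_m50[i] = v
    return MixtureModel(curves, pert, inter, umin_value=umin_value)


# ---------------------------------------------------------------------------
# fit statistics and hypothesis tests
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FitStats:
    rss: float
    rmse: float
    adjusted_r2: float
    aic: float


def fit_statistics(observed, predicted, n_params: int) -> FitStats:
    """RSS, RMSE = sqrt(RSS/N), adjusted r^2 and Gaussian-MLE AIC.

    A perfect fit (RSS = 0) has no finite Gaussian likelihood; the AIC is
    returned as ``-inf`` (sentinel) with a warning.
    """
    y = np.asarray(observed, dtype=float)
    p = np.asarray(predicted, dtype=float)
    if y.shape != p.shape or y.ndim != 1:
        raise ValueError("observed and predicted must be equal-length vectors")
    n = y.size
    k = int(n_params)
    if n <= k:
        raise ValueError(f"need more observations ({n}) than parameters ({k})")
    rss = float(np.sum((y - p) ** 2))
    rmse = math.sqrt(rss / n)
    tss = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - rss / tss if tss > 0 else (1.0 if rss == 0 else -np.inf)
    denom = n - k - 1
    adj = 1.0 - (1.0 - r2) * (n - 1) / denom if denom > 0 else np.nan
    if rss == 0:
        warnings.warn("perfect fit: AIC is -inf (sentinel)", RuntimeWarning)
        aic = -np.inf
    else:
        sigma2 = rss / n
        loglik = -0.5 * n * (math.log(2.0 * math.pi * sigma2) + 1.0)
        aic = 2.0 * k - 2.0 * loglik
    return FitStats(rss, rmse, adj, aic)


def mw_test(observed, predicted) -> float:
    """Two-sided two-sample Wilcoxon-Mann-Whitney p-value.

    Exact permutation enumeration for combined N <= 12 (valid under ties);
    tie-corrected normal approximation otherwise.  All-tied samples return
    p = 1 with a warning.
    """
    x = np.asarray(observed, dtype=float)
    y = np.asarray(predicted, dtype=float)
    if x.size < 3 or y.size < 3:
        raise ValueError("each sample needs at least 3 values")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        warnings.warn("all values tied; MW p-value is 1", RuntimeWarning)
        return 1.0
    n, m = x.size, y.size
    if n + m <= 12:
        # exact: condition on the pooled values, enumerate group assignments
        def ustat(a, b):
            diff = a[:, None] - b[None, :]
            return float(np.sum(diff > 0) + 0.5 * np.sum(diff == 0))

        u_obs = ustat(x, y)
        centre = n * m / 2.0
        dev = abs(u_obs - centre)
        total = 0
        hits = 0
        idx = np.arange(n + m)
        for comb in combinations(idx, n):
            sel = np.zeros(n + m, bool)
            sel[list(comb)] = True
            u = ustat(pooled[sel], pooled[~sel])
            total += 1
            if abs(u - centre) >= dev - 1e-12:
                hits += 1
        return hits / total
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return float(res.pvalue)


def shapiro_test(residuals) -> float:
    """Shapiro-Wilk p-value for normality of the residuals."""
    r = np.asarray(residuals, dtype=float)
    if r.size < 3:
        raise ValueError("need at least 3 residuals")
    return float(stats.shapiro(r).pvalue)


# ---------------------------------------------------------------------------
# results container
# ---------------------------------------------------------------------------

@dataclass
class FitResult:
    """Estimated model plus fit diagnostics.

    ``subset_rmse`` reports the RMSE over row subsets of the fitted table:
    ``"all"`` (the full fit set), ``"pure"`` / ``"mixture"``, and one entry
    per mixture group keyed by its sorted compound names (``"a+b"``).
    ``trail`` records backward-elimination steps when produced by
    :func:`reduce_model`.
    """

    model: MixtureModel
    mask: ParameterMask
    params: dict[str, float]
    stderr: dict[str, float]
    rss: float
    rmse: float
    adjusted_r2: float
    aic: float
    mw_p: float
    shapiro_p: float
    n_obs: int
    n_params: int
    predicted: np.ndarray
    subset_rmse: dict[str, float] = field(default_factory=dict)
    trail: list[dict] = field(default_factory=list)
    n_starts_converged: int = 0


def _subset_rmses(table: DoseResponseTable, resid: np.ndarray) -> dict[str, float]:
    out = {"all": float(np.sqrt(np.mean(resid**2)))}
    pure = table.pure_rows()
    mix = table.mixture_rows()
    if pure.any():
        out["pure"] = float(np.sqrt(np.mean(resid[pure] ** 2)))
    if mix.any():
        out["mixture"] = float(np.sqrt(np.mean(resid[mix] ** 2)))
    for key, mask in table.groups().items():
        out[_subset_label(key)] = float(np.sqrt(np.mean(resid[mask] ** 2)))
    return out


def _make_result(
    table: DoseResponseTable,
    model: MixtureModel,
    mask: ParameterMask,
    params: dict[str, float],
    stderr: dict[str, float],
    n_starts_converged: int = 0,
) -> FitResult:
    pred = u_ricc(model, table.doses)
    resid = table.effects - pred
    st = fit_statistics(table.effects, pred, len(mask))
    return FitResult(
        model=model,
        mask=mask,
        params=params,
        stderr=stderr,
        rss=st.rss,
        rmse=st.rmse,
        adjusted_r2=st.adjusted_r2,
        aic=st.aic,
        mw_p=mw_test(table.effects, pred),
        shapiro_p=shapiro_test(resid) if np.ptp(resid) > 0 else 1.0,
        n_obs=len(table),
        n_params=len(mask),
        predicted=pred,
        subset_rmse=_subset_rmses(table, resid),
        n_starts_converged=n_starts_converged,
    )


# ---------------------------------------------------------------------------
# pure-compound fits
# ---------------------------------------------------------------------------

def fit_pure(
    table: DoseResponseTable,
    compound: str,
    fix_e0: float | None = None,
    fix_emax: float | None = None,
    seed: int = 0,
) -> tuple[HillCurve, FitStats]:
    """Least-squares Hill parameters from one compound's single-drug rows.

    ``fix_e0`` / ``fix_emax`` pin the corresponding parameter (common when
    the assay is normalised, e.g. quantal 0..1 responses).  The fit is a
    deterministic multi-start over log-EC50 and slope; EC50 is estimated in
    the log domain.
    """
    mask = table.pure_rows(compound)
    j = table.compounds.index(compound)
    d = table.doses[mask, j]
    y = table.effects[mask]
    free = 4 - (fix_e0 is not None) - (fix_emax is not None)
    if d.size < free:
        raise ValueError(
            f"{compound}: {d.size} single-drug rows cannot identify {free} parameters"
        )
    if np.ptp(y) == 0:
        raise ValueError(f"{compound}: constant effect, Hill fit is degenerate")

    dmin, dmax = d[d > 0].min(), d.max()

    def unpack(p):
        i = 0
        if fix_e0 is None:
            e0 = p[i]; i += 1
        else:
            e0 = fix_e0
        if fix_emax is None:
            span = p[i]; i += 1
            emax = e0 + span
        else:
            emax = fix_emax
        ec50 = math.exp(p[i]); i += 1
        slope = p[i]
        return e0, emax, ec50, slope

    def resid(p):
        e0, emax, ec50, slope = unpack(p)
        m = d / ec50
        with np.errstate(over="ignore"):
            frac = np.where(m > 0, 1.0 / (1.0 + np.maximum(m, 1e-300) ** -slope), 0.0)
        r = e0 + (emax - e0) * frac - y
        over = max(0.0, emax - 1.0)  # soft cap keeps e0 + span <= 1
        return np.append(r, 1e3 * over)

    lo, hi = [], []
    if fix_e0 is None:
        lo.append(0.0); hi.append(1.0)
    if fix_emax is None:
        lo.append(0.0); hi.append(1.0)
    lo += [math.log(dmin / 100.0), 0.01]
    hi += [math.log(dmax * 100.0), 50.0]

    best = None
    for lec in np.linspace(math.log(dmin), math.log(dmax), 5):
        for sl in (0.5, 1.0, 2.0, 4.0, 8.0, 16.0):
            x0 = []
            if fix_e0 is None:
                x0.append(float(y.min()))
            if fix_emax is None:
                x0.append(float(np.clip(y.max() - y.min(), 0.05, 1.0)))
            x0 += [lec, sl]
            x0 = np.clip(x0, lo, hi)
            try:
                r = least_squares(
                    resid, x0, bounds=(lo, hi), xtol=1e-14, ftol=1e-14, gtol=1e-14
                )
            except Exception:
                continue
            if best is None or r.cost < best.cost:
                best = r
    if best is None:
        raise RuntimeError(f"{compound}: all Hill fit starts failed")
    e0, emax, ec50, slope = unpack(best.x)
    curve = HillCurve(compound, float(e0), float(min(emax, 1.0)), float(ec50), float(slope))
    stats_ = fit_statistics(y, hill_effect(curve, d), free)
    return curve, stats_


# ---------------------------------------------------------------------------
# mixture-surface fits
# ---------------------------------------------------------------------------

def _starts(
    mask: ParameterMask,
    curves: list[HillCurve],
    n_starts: int,
    seed: int,
    warm: dict[str, float] | None,
) -> list[np.ndarray]:
    ids = mask.ordered()
    k = len(ids)
    inact = np.array([_inactive_value(pid) for pid in ids])
    pts = [inact]
    if warm is not None:
        pts.append(np.array([warm.get(pid, _inactive_value(pid)) for pid in ids]))
    extra = n_starts - len(pts)
    if extra > 0 and k > 0:
        sampler = qmc.LatinHypercube(d=k, seed=seed)
        unit = sampler.random(extra)
        cols = []
        for j, pid in enumerate(ids):
            kind = _param_kind(pid)
            lo, hi = _START[kind]
            if kind == "dm50":
                vals = np.exp(
                    np.log(lo) + unit[:, j] * (np.log(hi) - np.log(lo))
                )
            else:
                vals = lo + unit[:, j] * (hi - lo)
            blo, bhi = _param_bounds(pid, curves)
            cols.append(np.clip(vals, blo, bhi))
        pts += list(np.column_stack(cols))
    return pts


def fit_mixture(
    table: DoseResponseTable,
    base_curves: list[HillCurve],
    mask: ParameterMask,
    bounds: dict[str, tuple[float, float]] | None = None,
    seed: int = 0,
    n_starts: int = 16,
    warm_start: dict[str, float] | None = None,
) -> FitResult:
    """Fit the active surface parameters to all rows of ``table``.

    The pure-compound curves are held fixed; only the parameters in
    ``mask`` vary, inside hard bounds (notably ``emax_i + d_emax_i <= 1``).
    The best of ``n_starts`` deterministic starts (inactive start, optional
    ``warm_start``, remainder seeded Latin hypercube) is returned.  Pass a
    table already restricted to the compounds of interest: every row is
    used, so the fit set is typically the pure rows plus the mixture rows
    of those compounds.

    With an empty mask no optimisation runs and the result carries the
    null-interaction model's prediction statistics.
    """
    names = [c.name for c in base_curves]
    if names != table.compounds:
        raise ValueError("base_curves order must match table compounds")
    ids = mask.ordered()
    if not ids:
        model = build_model(base_curves, mask, {})
        return _make_result(table, model, mask, {}, {})

    lo = np.empty(len(ids))
    hi = np.empty(len(ids))
    for j, pid in enumerate(ids):
        lo[j], hi[j] = (bounds or {}).get(pid, _param_bounds(pid, base_curves))

    def resid(x):
        model = build_model(base_curves, mask, x)
        try:
            pred = u_ricc(model, table.doses)
        except BracketError:
            return np.full(len(table), 1e3)
        return pred - table.effects

    best = None
    n_ok = 0
    for x0 in _starts(mask, base_curves, n_starts, seed, warm_start):
        x0 = np.clip(x0, lo, hi)
        try:
            r = least_squares(resid, x0, bounds=(lo, hi), xtol=1e-12, ftol=1e-12)
        except Exception:
            continue
        if not np.all(np.isfinite(r.x)):
            continue
        n_ok += 1
        if best is None or r.cost < best.cost:
            best = r
    if best is None:
        raise RuntimeError(
            f"all {n_starts} starts failed for mask {sorted(mask.active)}"
        )

    params = dict(zip(ids, (float(v) for v in best.x)))
    model = build_model(base_curves, mask, params)
    # standard errors from the Gauss-Newton covariance at the optimum
    n, k = len(table), len(ids)
    rssv = 2.0 * best.cost
    stderr: dict[str, float] = {}
    if n > k and rssv > 0:
        jtj = best.jac.T @ best.jac
        cov = np.linalg.pinv(jtj) * (rssv / (n - k))
        se = np.sqrt(np.clip(np.diag(cov), 0, None))
        stderr = dict(zip(ids, (float(v) for v in se)))
    return _make_result(table, model, mask, params, stderr, n_ok)


def reduce_model(
    table: DoseResponseTable,
    base_curves: list[HillCurve],
    start_mask: ParameterMask | None = None,
    criterion: str = "aic",
    seed: int = 0,
    n_starts: int = 16,
    inner_starts: int = 6,
    likelihood_tol: float = 0.05,
) -> FitResult:
    """AIC-guided backward elimination of surface parameters.

    Starting from ``start_mask`` (default: all parameters), each step
    refits the model with every single active parameter removed and
    considers the removal with the lowest AIC (ties broken by the smallest
    |estimate - inactive|/SE).  Two acceptance rules are available:

    * ``criterion="aic"`` (default): accept any removal that lowers the
      AIC; stop when none does.  Standard stepwise selection.
    * ``criterion="conservative"``: accept a removal only when it costs
      essentially no likelihood — the AIC gain reaches the full 2-unit
      parameter penalty within ``likelihood_tol``.  Only parameters the
      data make exactly redundant are dropped; parameters carrying any
      likelihood weight survive.  On noisy data this retains more
      (possibly noise-fitting) parameters than the AIC rule.

    Either way the accepted AICs decrease strictly along the returned
    ``trail``, which records every candidate AIC per step.
    """
    if criterion not in ("aic", "conservative"):
        raise ValueError("criterion must be 'aic' or 'conservative'")
    names = [c.name for c in base_curves]
    if start_mask is None:
        start_mask = ParameterMask.full(names)
    current = fit_mixture(
        table, base_curves, start_mask, seed=seed, n_starts=n_starts
    )
    trail: list[dict] = [
        {"removed": None, "aic": current.aic, "mask_size": len(current.mask)}
    ]
    while len(current.mask) > 0:
        candidates: dict[str, FitResult] = {}
        for pid in current.mask.ordered():
            sub = current.mask.without(pid)
            candidates[pid] = fit_mixture(
                table,
                base_curves,
                sub,
                seed=seed,
                n_starts=inner_starts,
                warm_start=current.params,
            )
        best_aic = min(fr.aic for fr in candidates.values())
        threshold = (
            current.aic if criterion == "aic"
            else current.aic - 2.0 + likelihood_tol
        )
        if not best_aic < threshold:
            trail.append(
                {
                    "removed": None,
                    "aic": current.aic,
                    "candidates": {p: fr.aic for p, fr in candidates.items()},
                    "stopped": True,
                }
            )
            break
        tied = [p for p, fr in candidates.items() if fr.aic <= best_aic + 1e-9]
        if len(tied) > 1:
            # remove the least significant of the tied parameters
            def tstat(pid):
                se = current.stderr.get(pid, np.inf)
                if not se or not np.isfinite(se):
                    return np.inf
                return abs(current.params[pid] - _inactive_value(pid)) / se

            pick = min(tied, key=tstat)
        else:
            pick = tied[0]
        trail.append(
            {
                "removed": pick,
                "aic": candidates[pick].aic,
                "candidates": {p: fr.aic for p, fr in candidates.items()},
            }
        )
        current = candidates[pick]
    current.trail = trail
    return current


# ---------------------------------------------------------------------------
# reference-model scoring
# ---------------------------------------------------------------------------

def informative_reference_rows(table: DoseResponseTable) -> np.ndarray:
    """Mixture rows scored against the reference model.

    Within each mixture group (rows in table order, i.e. ascending along
    the dose ray) rows *after* the first fully saturated response
    (effect = 1) are dropped: further escalation steps replicate the
    ceiling and carry no information about the surface shape.  Rows up to
    and including the first ceiling response are kept.
    """
    keep = np.zeros(len(table), dtype=bool)
    for _, gmask in table.groups().items():
        idx = np.where(gmask)[0]
        sat = np.where(table.effects[idx] >= 1.0 - 1e-12)[0]
        last = idx[sat[0]] if sat.size else idx[-1]
        keep[idx[idx <= last]] = True
    return keep


def null_reference_rmse(
    table: DoseResponseTable,
    curves: list[HillCurve],
    names: list[str] | None = None,
    drop_saturated_tail: bool = True,
) -> float:
    """RMSE of the null-interaction surface on mixture rows (no fitting).

    ``names`` restricts scoring to the mixture group with exactly that
    support.  See :func:`informative_reference_rows` for the default row
    convention; pass ``drop_saturated_tail=False`` to score every row.
    """
    order = {c.name: c for c in curves}
    model = MixtureModel([order[nm] for nm in table.compounds])
    mask = table.mixture_rows(names)
    if drop_saturated_tail:
        mask &= informative_reference_rows(table)
    if not mask.any():
        raise ValueError("no mixture rows to score")
    pred = u_null(model, table.doses[mask])
    return float(np.sqrt(np.mean((table.effects[mask] - pred) ** 2)))
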
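"""Synergy surfaces, their extrema, and iso-level sets.

The synergy surface is the pointwise difference between the fitted
full-interaction surface and the null-interaction reference,
``u_ricc - u_null``; positive values mean synergism, negative antagonism.
Its extrema over the experimentally covered dose box locate the dose
combinations of peak synergism/antagonism.  Iso-effect lines (isoboles) and
iso-synergy level sets are extracted by marching squares/cubes.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from skimage import measure

from .models import MixtureModel, u_null, u_ricc

__all__ = [
    "SynergySurface",
    "SurfaceExtremum",
    "dose_axes",
    "synergy_surface",
    "find_extrema",
    "iso_levels",
    "effect_iso_levels",
    "surface_to_dict",
]


@dataclass(frozen=True)
class SurfaceExtremum:
    """A located extremum of a synergy surface."""

    doses: np.ndarray
    value: float
    kind: str  # "maximum" | "minimum"


@dataclass
class SynergySurface:
    """Synergy values on a dose grid, with the models that produced them.

    ``axes`` hold the per-compound dose grids (log-spaced across ``bounds``
    plus an exact-zero node at the start); ``values`` is the full tensor of
    ``u_ricc(full) - u_null(null)`` at every grid node.
    """

    compounds: list[str]
    axes: list[np.ndarray]
    values: np.ndarray
    bounds: list[tuple[float, float]]
    null_model: MixtureModel = field(repr=False, default=None)
    full_model: MixtureModel = field(repr=False, default=None)

    def synergy_at(self, doses) -> np.ndarray | float:
        """Direct evaluation of u_ricc - u_null at arbitrary dose vectors."""
        return u_ricc(self.full_model, doses) - u_null(self.null_model, doses)


def dose_axes(
    bounds: list[tuple[float, float]],
    n_points: int = 201,
    include_zero: bool = True,
) -> list[np.ndarray]:
    """Log-spaced dose grids over per-compound (low, high) bounds."""
    axes = []
    for lo, hi in bounds:
        if not 0 < lo < hi:
            raise ValueError("bounds must satisfy 0 < low < high")
        ax = np.geomspace(lo, hi, n_points)
        if include_zero:
            ax = np.concatenate([[0.0], ax])
        axes.append(ax)
    return axes


def synergy_surface(
    null_model: MixtureModel,
    full_model: MixtureModel,
    axes: list[np.ndarray] | None = None,
    bounds: list[tuple[float, float]] | None = None,
    n_points: int | None = None,
) -> SynergySurface:
    """Evaluate u_ricc(full) - u_null(null) on a dose grid.

    Models must share compounds and pure-compound curves.  Either ``axes``
    or per-compound ``bounds`` must be given; the default grid is 201
    log-spaced points per axis (81 for three or more compounds) plus a zero
    node.
    """
    if null_model.names != full_model.names:
        raise ValueError("models do not share the same compounds in order")
    for ca, cb in zip(null_model.curves, full_model.curves):
        if (ca.e0, ca.emax, ca.ec50, ca.slope) != (cb.e0, cb.emax, cb.ec50, cb.slope):
            raise ValueError(f"pure-compound curves differ for {ca.name}")
    n = full_model.n
    if axes is None:
        if bounds is None:
            raise ValueError("provide axes or bounds")
        if n_points is None:
            n_points = 201 if n == 2 else 81
        axes = dose_axes(bounds, n_points)
    else:
        axes = [np.asarray(a, dtype=float) for a in axes]
        if bounds is None:
            bounds = [(a[a > 0].min(), a.max()) for a in axes]
    grids = np.meshgrid(*axes, indexing="ij")
    pts = np.stack([g.ravel() for g in grids], axis=-1)
    vals = u_ricc(full_model, pts) - u_null(null_model, pts)
    return SynergySurface(
        compounds=list(full_model.names),
        axes=axes,
        values=vals.reshape(grids[0].shape),
        bounds=[(float(lo), float(hi)) for lo, hi in bounds],
        null_model=null_model,
        full_model=full_model,
    )


def _reflect(t: np.ndarray, lo: np.ndarray, hi: np.ndarray) -> np.ndarray:
    """Fold unconstrained coordinates into [lo, hi] by reflection."""
    width = hi - lo
    y = np.mod(t - lo, 2.0 * width)
    y = np.where(y > width, 2.0 * width - y, y)
    return lo + y


def find_extrema(surface: SynergySurface, refine: bool = True) -> list[SurfaceExtremum]:
    """Global maximum and minimum of the synergy surface within its bounds.

    The best grid node (restricted to the search box, excluding the zero
    nodes) seeds a Nelder-Mead refinement in log-dose space, with the box
    constraint imposed by coordinate reflection; the refined value can only
    improve on the grid value.  On an all-zero surface both extrema are 0,
    reported at the lexicographically smallest in-box node.
    """
    axes, vals = surface.axes, surface.values
    inbox = np.ones(vals.shape, dtype=bool)
    for dim, (ax, (lo, hi)) in enumerate(zip(axes, surface.bounds)):
        ok = (ax >= lo - 1e-15) & (ax <= hi + 1e-15)
        shape = [1] * vals.ndim
        shape[dim] = ax.size
        inbox &= ok.reshape(shape)
    masked = np.where(inbox, vals, np.nan)

    lo = np.log([b[0] for b in surface.bounds])
    hi = np.log([b[1] for b in surface.bounds])

    out = []
    for kind, pick in (("maximum", np.nanargmax), ("minimum", np.nanargmin)):
        if np.nanmax(np.abs(masked)) == 0:
            idx = tuple(int(np.argmax(ax >= surface.bounds[i][0]))
                        for i, ax in enumerate(axes))
        else:
            idx = np.unravel_index(pick(masked), vals.shape)
        doses = np.array([ax[i] for ax, i in zip(axes, idx)])
        value = float(vals[idx])
        if refine:
            sign = -1.0 if kind == "maximum" else 1.0

            def objective(t):
                d = np.exp(_reflect(t, lo, hi))
                return sign * float(surface.synergy_at(d[None, :])[0])

            x0 = np.log(np.clip(doses, np.exp(lo), np.exp(hi)))
            res = minimize(
                objective,
                x0,
                method="Nelder-Mead",
                options={"xatol": 1e-8, "fatol": 1e-12, "maxiter": 2000},
            )
            cand_d = np.exp(_reflect(res.x, lo, hi))
            cand_v = float(surface.synergy_at(cand_d[None, :])[0])
            better = cand_v >= value if kind == "maximum" else cand_v <= value
            if better:
                doses, value = cand_d, cand_v
        out.append(SurfaceExtremum(doses=doses, value=value, kind=kind))
    return out


def _index_to_coords(axes: list[np.ndarray], pts: np.ndarray) -> np.ndarray:
    """Map fractional grid indices to dose coordinates per axis."""
    out = np.empty_like(pts)
    for j, ax in enumerate(axes):
        out[..., j] = np.interp(pts[..., j], np.arange(ax.size), ax)
    return out


def iso_levels(
    surface_values: np.ndarray,
    axes: list[np.ndarray],
    levels: list[float],
) -> dict[float, list[np.ndarray]]:
    """Level sets of a gridded scalar field in dose coordinates.

    2-D grids yield contour polylines (marching squares); 3-D grids yield
    triangulated iso-surfaces returned as vertex arrays (marching cubes).
    Levels outside the field's range yield an empty list with a warning.
    """
    vals = np.asarray(surface_values, dtype=float)
    out: dict[float, list[np.ndarray]] = {}
    vmin, vmax = float(vals.min()), float(vals.max())
    for level in levels:
        if not vmin <= level <= vmax:
            warnings.warn(
                f"level {level} outside surface range [{vmin:.4g}, {vmax:.4g}]",
                RuntimeWarning,
            )
            out[level] = []
            continue
        if vals.ndim == 2:
            segs = measure.find_contours(vals, level)
            out[level] = [_index_to_coords(axes, s) for s in segs]
        elif vals.ndim == 3:
            verts, faces, *_ = measure.marching_cubes(vals, level)
            out[level] = [_index_to_coords(axes, verts)]
        else:
            raise ValueError("iso_levels supports 2-D and 3-D grids")
    return out


def effect_iso_levels(
    model: MixtureModel,
    axes: list[np.ndarray],
    levels: list[float],
    surface: str = "null",
) -> dict[float, list[np.ndarray]]:
    """Iso-effect sets (isoboles) of a model surface on a dose grid."""
    grids = np.meshgrid(*axes, indexing="ij")
    pts = np.stack([g.ravel() for g in grids], axis=-1)
    fn = u_null if surface == "null" else u_ricc
    vals = fn(model, pts).reshape(grids[0].shape)
    return iso_levels(vals, axes, levels)


def surface_to_dict(surface: SynergySurface) -> dict:
    """JSON-serialisable export: axis vectors, value tensor, bounds."""
    return {
        "compounds": surface.compounds,
        "axes": [a.tolist() for a in surface.axes],
        "values": surface.values.tolist(),
        "bounds": [list(b) for b in surface.bounds],
    }


def write_surface(surface: SynergySurface, path) -> None:
    with open(path, "w") as fh:
        json.dump(surface_to_dict(surface), fh)
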
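"""Optimum location and surface export on the integrated desirability.

The working domain is the region the design actually sampled: the coded
star-cube [-alpha, alpha] per factor (alpha = 1.682 for the rotatable
three-factor design), with the lower corner clipped where it would imply
a negative actual level.  Predictions outside this box are extrapolation
and are deliberately not searched.

``find_optimum`` is a dense-grid screen followed by Nelder-Mead
refinement from the best node; for the smooth low-dimensional surfaces
produced by quadratic models this is deterministic and accurate to well
below the grid spacing.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np
import pandas as pd
from scipy import optimize as sp_optimize

from .design import Factor, to_actual
from .desirability import Scenario, desirability_value, overall_desirability
from .errors import SpecificationError
from .fitting import FitResult
from .models import QuadraticModel

__all__ = [
    "coded_domain",
    "evaluate_grid",
    "find_optimum",
    "slice_surface",
    "sucrose_flatness",
    "OptimumResult",
]

DEFAULT_ALPHA = 1.682
FLATNESS_EPS = 1e-12


def _common_factors(models: dict[str, QuadraticModel]) -> list[Factor]:
    factor_sets = {tuple(m.factors) for m in models.values()}
    if len(factor_sets) != 1:
        raise SpecificationError("all response models must share identical factors")
    return list(next(iter(factor_sets)))


def coded_domain(
    factors: list[Factor], alpha: float = DEFAULT_ALPHA
) -> list[tuple[float, float]]:
    """Per-factor coded bounds: [-alpha, alpha] clipped to actual >= 0."""
    bounds = []
    for f in factors:
        lo = max(-alpha, -f.center / f.half_range)
        bounds.append((lo, alpha))
    return bounds


def _grid_axes(bounds, resolution) -> list[np.ndarray]:
    if np.isscalar(resolution):
        resolution = [int(resolution)] * len(bounds)
    return [np.linspace(lo, hi, r) for (lo, hi), r in zip(bounds, resolution)]


def _predict_responses(
    models: dict[str, QuadraticModel], coded_points: np.ndarray
) -> dict[str, np.ndarray]:
    out = {}
    for name, model in models.items():
        out[name] = model.to_representation("coded").predict(coded_points)
    return out


def evaluate_grid(
    models: dict[str, QuadraticModel],
    scenario: Scenario,
    grid_spec: dict[str, np.ndarray] | int = 50,
    domain: list[tuple[float, float]] | None = None,
    alpha: float = DEFAULT_ALPHA,
) -> pd.DataFrame:
    """Tabulate predictions, desirabilities, and R over a coded grid.

    ``grid_spec`` is either a per-factor mapping name -> coded level array
    or an integer resolution applied to every factor over ``domain``.
    Returns one row per grid node with actual levels, coded levels,
    per-response predictions/desirabilities and the overall R.
    """
    factors = _common_factors(models)
    names = [f.name for f in factors]
    if isinstance(grid_spec, dict):
        axes = [np.asarray(grid_spec[n], float) for n in names]
    else:
        dom = domain or coded_domain(factors, alpha)
        axes = _grid_axes(dom, grid_spec)
    dom_check = domain or coded_domain(factors, alpha)
    for ax, (lo, hi), name in zip(axes, dom_check, names):
        if ax.min() < lo - 1e-9 or ax.max() > hi + 1e-9:
            warnings.warn(
                f"grid for {name} extends outside the sampled domain "
                f"[{lo:.3f}, {hi:.3f}] (coded); values there are extrapolation",
                stacklevel=2,
            )
    mesh = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, len(axes))
    actual = to_actual(factors, mesh)
    preds = _predict_responses(models, mesh)

    data = {}
    for j, n in enumerate(names):
        data[n] = actual[:, j]
        data[f"{n}_coded"] = mesh[:, j]
    d_values = {}
    for goal in scenario.goals:
        y = preds[goal.response_name]
        data[f"{goal.response_name}_pred"] = y
        d = desirability_value(goal, y)
        d_values[goal.response_name] = d
        data[f"d_{goal.response_name}"] = d
    data["R"] = overall_desirability(
        scenario, {g.response_name: preds[g.response_name] for g in scenario.goals}
    )
    return pd.DataFrame(data)


@dataclass
class OptimumResult:
    """Location and value of the best overall desirability found."""

    coded_levels: np.ndarray
    actual_levels: np.ndarray
    R: float
    predictions: dict[str, float]
    flat: bool = False

    def as_dict(self, factor_names: list[str]) -> dict:
        out = {"R": self.R, "flat": self.flat}
        for n, c, a in zip(factor_names, self.coded_levels, self.actual_levels):
            out[f"{n}_coded"] = float(c)
            out[n] = float(a)
        for resp, val in self.predictions.items():
            out[f"{resp}_pred"] = float(val)
        return out


def find_optimum(
    models: dict[str, QuadraticModel],
    scenario: Scenario,
    domain: list[tuple[float, float]] | None = None,
    grid_resolution: int = 50,
    alpha: float = DEFAULT_ALPHA,
    xatol: float = 1e-6,
) -> OptimumResult:
    """Locate the maximum of R over the coded box domain.

    Dense-grid screen at ``grid_resolution`` nodes per factor, then
    Nelder-Mead refinement from the best node (bounded to the domain).
    Deterministic for fixed resolution.  A flat surface (R constant over
    the grid) returns the domain center with ``flat=True``.
    """
    factors = _common_factors(models)
    dom = domain or coded_domain(factors, alpha)
    coded_models = {n: m.to_representation("coded") for n, m in models.items()}

    axes = _grid_axes(dom, grid_resolution)
    mesh = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, len(axes))
    preds = {n: m.predict(mesh) for n, m in coded_models.items()}
    r = overall_desirability(
        scenario, {g.response_name: preds[g.response_name] for g in scenario.goals}
    )
    if float(r.max() - r.min()) < FLATNESS_EPS:
        center = np.array([(lo + hi) / 2.0 for lo, hi in dom])
        return OptimumResult(
            coded_levels=center,
            actual_levels=to_actual(factors, center),
            R=float(r[0]),
            predictions={n: float(m.predict(center)) for n, m in coded_models.items()},
            flat=True,
        )

    best = mesh[int(np.argmax(r))]

    def neg_r(u):
        vals = {n: m.predict(u) for n, m in coded_models.items()}
        return -overall_desirability(scenario, vals)

    res = sp_optimize.minimize(
        neg_r,
        best,
        method="Nelder-Mead",
        bounds=dom,
        options={"xatol": xatol, "fatol": xatol, "maxiter": 5000},
    )
    # refinement never loses: keep the better of grid node and polish
    if -res.fun >= float(r.max()):
        u_star, r_star = np.asarray(res.x), float(-res.fun)
    else:
        u_star, r_star = best, float(r.max())
    return OptimumResult(
        coded_levels=u_star,
        actual_levels=to_actual(factors, u_star),
        R=r_star,
        predictions={n: float(m.predict(u_star)) for n, m in coded_models.items()},
        flat=False,
    )


def slice_surface(
    models: dict[str, QuadraticModel] | QuadraticModel,
    scenario: Scenario | None,
    fixed: dict[str, float],
    free: list[str],
    resolution: int = 50,
    fit: FitResult | None = None,
    domain: list[tuple[float, float]] | None = None,
    alpha: float = DEFAULT_ALPHA,
    fixed_in: str = "actual",
) -> pd.DataFrame:
    """Tabulate a 1-D or 2-D slice of the response or R surface.

    ``fixed`` pins factors at given levels (actual units by default) and
    ``free`` lists the one or two factors spanned by the slice; together
    they must cover every factor exactly once.  With a single model a
    prediction column is produced (plus a 95% t confidence band for the
    mean prediction when ``fit`` supplies a covariance); with a scenario,
    the per-response predictions and R.
    """
    single = isinstance(models, QuadraticModel)
    model_map = {models.response_name or "y": models} if single else models
    factors = _common_factors(model_map)
    names = [f.name for f in factors]
    overlap = set(fixed) & set(free)
    if overlap:
        raise SpecificationError(f"factors both fixed and free: {sorted(overlap)}")
    if set(fixed) | set(free) != set(names) or len(fixed) + len(free) != len(names):
        raise SpecificationError(
            f"fixed+free must cover factors {names} exactly once, "
            f"got fixed={sorted(fixed)}, free={free}"
        )
    dom = domain or coded_domain(factors, alpha)
    by_name = dict(zip(names, dom))

    axes = []
    for n in names:
        if n in fixed:
            level = float(fixed[n])
            if fixed_in == "actual":
                f = factors[names.index(n)]
                level = (level - f.center) / f.half_range
            axes.append(np.array([level]))
        else:
            lo, hi = by_name[n]
            axes.append(np.linspace(lo, hi, resolution))
    mesh = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, len(names))
    actual = to_actual(factors, mesh)

    data = {}
    for j, n in enumerate(names):
        data[n] = actual[:, j]
        data[f"{n}_coded"] = mesh[:, j]
    if single:
        model = next(iter(model_map.values()))
        coded_model = model.to_representation("coded")
        if fit is not None:
            rep = fit.model.representation
            pts = mesh if rep == "coded" else actual
            yhat, lo_b, hi_b = fit.confidence_band(pts)
            data["prediction"] = yhat
            data["ci_lower"] = lo_b
            data["ci_upper"] = hi_b
        else:
            data["prediction"] = coded_model.predict(mesh)
    else:
        if scenario is None:
            raise SpecificationError("a scenario is required for multi-response slices")
        preds = _predict_responses(model_map, mesh)
        for goal in scenario.goals:
            data[f"{goal.response_name}_pred"] = preds[goal.response_name]
        data["R"] = overall_desirability(
            scenario, {g.response_name: preds[g.response_name] for g in scenario.goals}
        )
    return pd.DataFrame(data)


def sucrose_flatness(
    models: dict[str, QuadraticModel],
    scenario: Scenario,
    sucrose: str = "S",
    from_actual: float = 35.0,
    fixed: dict[str, float] | None = None,
    resolution: int = 200,
    alpha: float = DEFAULT_ALPHA,
) -> float:
    """Relative change of R along sucrose from ``from_actual`` to the domain edge.

    A diagnostic for "the surface no longer responds to S beyond S0":
    returns (max R - min R) / max R over S in [from_actual, S_max] with
    the other factors held at ``fixed`` (actual units).  Small values
    mean the desirability has saturated in sucrose.
    """
    factors = _common_factors(models)
    names = [f.name for f in factors]
    fixed = dict(fixed or {})
    s_factor = factors[names.index(sucrose)]
    hi_actual = s_factor.center + alpha * s_factor.half_range
    grid = {
        n: (np.array([(fixed[n] - f.center) / f.half_range]) if n in fixed
            else np.linspace((from_actual - f.center) / f.half_range,
                             (hi_actual - f.center) / f.half_range, resolution))
        for n, f in zip(names, factors)
    }
    table = evaluate_grid(models, scenario, grid_spec=grid)
    r = table["R"].to_numpy()
    if r.max() <= 0:
        return 0.0
    return float((r.max() - r.min()) / r.max())
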
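"""Central composite designs and actual/coded factor-level mapping.

A central composite design (CCD) over ``k`` factors combines the ``2**k``
corners of a cube (factorial points), ``2*k`` axial "star" points at coded
distance ``alpha`` from the center, and ``n_center`` replicated center
points, for ``2**k + 2*k + n_center`` runs in total.  With the rotatable
choice ``alpha = 2**(k/4)`` the prediction variance of the fitted quadratic
depends only on the distance from the design center.

Factor levels live in two equivalent coordinate systems: *actual* units
(g/dL of sucrose or yeast, days of treatment) and dimensionless *coded*
units defined by ``coded = (actual - center) / half_range``, so the cube
faces sit at -1/+1.  All conversions in this package use that convention;
the sign is fixed so +1 is the high face.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DimensionError, InvalidDesignError, InvalidFactorError

__all__ = [
    "Factor",
    "CCDesign",
    "rotatable_alpha",
    "build_ccd",
    "to_coded",
    "to_actual",
    "read_design_csv",
]

POINT_FACTORIAL = "factorial"
POINT_AXIAL = "axial"
POINT_CENTER = "center"


@dataclass(frozen=True)
class Factor:
    """One experimental variable with its center and half-range.

    ``half_range`` is the center-to-face distance of the design cube in
    actual units; coded level u corresponds to actual level
    ``center + half_range * u``.
    """

    name: str
    center: float
    half_range: float
    units: str = ""

    def __post_init__(self) -> None:
        if not np.isfinite(self.center):
            raise InvalidFactorError(f"factor {self.name!r}: center must be finite")
        if not (np.isfinite(self.half_range) and self.half_range > 0):
            raise InvalidFactorError(
                f"factor {self.name!r}: half_range must be positive, got {self.half_range}"
            )


def _check_factors(factors: list[Factor]) -> None:
    names = [f.name for f in factors]
    if len(set(names)) != len(names):
        raise InvalidDesignError(f"factor names must be unique, got {names}")


def to_coded(factors: list[Factor], actual_levels) -> np.ndarray:
    """Map actual levels to coded units, ``(actual - center) / half_range``.

    ``actual_levels`` may be a length-k vector or an (n, k) array.
    """
    levels = np.asarray(actual_levels, dtype=float)
    if levels.shape[-1] != len(factors):
        raise DimensionError(
            f"expected {len(factors)} levels per point, got shape {levels.shape}"
        )
    centers = np.array([f.center for f in factors])
    halves = np.array([f.half_range for f in factors])
    return (levels - centers) / halves


def to_actual(factors: list[Factor], coded_levels) -> np.ndarray:
    """Inverse of :func:`to_coded`: ``center + half_range * coded``."""
    levels = np.asarray(coded_levels, dtype=float)
    if levels.shape[-1] != len(factors):
        raise DimensionError(
            f"expected {len(factors)} levels per point, got shape {levels.shape}"
        )
    centers = np.array([f.center for f in factors])
    halves = np.array([f.half_range for f in factors])
    return centers + halves * levels


def rotatable_alpha(k: int) -> float:
    """Star-point dilation giving a rotatable CCD: ``2**(k/4)``."""
    return float(2.0 ** (k / 4.0))


@dataclass
class CCDesign:
    """A central composite design: factors, star dilation, and the run table.

    ``runs`` has one row per run with columns ``run_id``, ``point_class``,
    ``<factor>_coded`` and ``<factor>`` (actual) for each factor.
    """

    factors: list[Factor]
    alpha: float
    n_center: int
    runs: pd.DataFrame = field(repr=False)

    @property
    def k(self) -> int:
        return len(self.factors)

    @property
    def n_runs(self) -> int:
        return len(self.runs)

    @property
    def factor_names(self) -> list[str]:
        return [f.name for f in self.factors]

    def coded_matrix(self) -> np.ndarray:
        return self.runs[[f"{n}_coded" for n in self.factor_names]].to_numpy(float)

    def actual_matrix(self) -> np.ndarray:
        return self.runs[self.factor_names].to_numpy(float)

    def to_csv(self, path) -> None:
        self.runs.to_csv(path, index=False)


def build_ccd(
    factors: list[Factor],
    n_center: int = 6,
    alpha: float | str = "rotatable",
    seed: int | None = None,
) -> CCDesign:
    """Construct a central composite design.

    Parameters
    ----------
    factors
        Two or more :class:`Factor` definitions.
    n_center
        Number of replicated center points (>= 1).
    alpha
        Star-point distance in coded units, or ``"rotatable"`` for
        ``2**(k/4)``.  ``alpha = 1`` gives a face-centered design.
    seed
        If given, run_id order is a seeded permutation of the canonical
        (factorial, axial, center) layout; the default order is canonical
        so that designs are reproducible without bookkeeping.
    """
    k = len(factors)
    if k < 2:
        raise InvalidDesignError(f"a CCD needs at least 2 factors, got {k}")
    if n_center < 1:
        raise InvalidDesignError(f"n_center must be >= 1, got {n_center}")
    _check_factors(factors)
    if isinstance(alpha, str):
        if alpha != "rotatable":
            raise InvalidDesignError(f"unknown alpha spec {alpha!r}")
        alpha_val = rotatable_alpha(k)
    else:
        alpha_val = float(alpha)
        if not alpha_val > 0:
            raise InvalidDesignError(f"alpha must be positive, got {alpha}")

    corners = np.array(list(itertools.product([-1.0, 1.0], repeat=k)))
    axial = np.zeros((2 * k, k))
    for i in range(k):
        axial[2 * i, i] = -alpha_val
        axial[2 * i + 1, i] = alpha_val
    center = np.zeros((n_center, k))

    coded = np.vstack([corners, axial, center])
    classes = (
        [POINT_FACTORIAL] * len(corners)
        + [POINT_AXIAL] * len(axial)
        + [POINT_CENTER] * n_center
    )
    if seed is not None:
        order = np.random.default_rng(seed).permutation(len(coded))
        coded = coded[order]
        classes = [classes[i] for i in order]

    actual = to_actual(factors, coded)
    data = {"run_id": np.arange(1, len(coded) + 1), "point_class": classes}
    for j, f in enumerate(factors):
        data[f"{f.name}_coded"] = coded[:, j]
    for j, f in enumerate(factors):
        data[f.name] = actual[:, j]
    return CCDesign(factors=list(factors), alpha=alpha_val, n_center=n_center,
                    runs=pd.DataFrame(data))


def read_design_csv(path, factors: list[Factor]) -> CCDesign:
    """Read a design table written by :meth:`CCDesign.to_csv`.

    ``alpha`` is recovered as the largest absolute coded level and
    ``n_center`` as the number of rows labelled center.
    """
    runs = pd.read_csv(path)
    coded_cols = [f"{f.name}_coded" for f in factors]
    missing = [c for c in coded_cols + [f.name for f in factors] if c not in runs]
    if missing:
        raise InvalidDesignError(f"design file {path} lacks columns {missing}")
    alpha_val = float(np.abs(runs[coded_cols].to_numpy(float)).max())
    n_center = int((runs["point_class"] == POINT_CENTER).sum())
    return CCDesign(factors=list(factors), alpha=alpha_val, n_center=n_center, runs=runs)
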
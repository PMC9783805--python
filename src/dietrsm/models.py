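"""Full second-order polynomial response models.

A quadratic response-surface model over k factors is

    y = b0 + sum_i bi * x_i + sum_i bii * x_i**2 + sum_{i<j} bij * x_i * x_j

with 1 + 2k + k(k-1)/2 coefficients.  The same surface can be written with
x in actual units or in coded units; the two coefficient sets are related
by the affine substitution x_i = center_i + half_range_i * u_i and carry a
``representation`` tag so the two are never mixed silently.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, replace

import numpy as np

from .design import Factor, to_coded
from .errors import ConversionError, DimensionError, RepresentationError

__all__ = ["QuadraticModel", "basis_matrix", "term_names"]

ACTUAL = "actual"
CODED = "coded"


def term_names(factor_names: list[str]) -> list[str]:
    """Column names of the second-order basis, in model coefficient order:
    intercept, linear, quadratic, pairwise interactions (i<j)."""
    k = len(factor_names)
    names = ["intercept"]
    names += list(factor_names)
    names += [f"{n}^2" for n in factor_names]
    names += [f"{factor_names[i]}:{factor_names[j]}"
              for i, j in itertools.combinations(range(k), 2)]
    return names


def basis_matrix(levels: np.ndarray) -> np.ndarray:
    """Expand (n, k) factor levels into the (n, p) second-order basis."""
    x = np.atleast_2d(np.asarray(levels, dtype=float))
    n, k = x.shape
    cols = [np.ones(n)]
    cols += [x[:, i] for i in range(k)]
    cols += [x[:, i] ** 2 for i in range(k)]
    cols += [x[:, i] * x[:, j] for i, j in itertools.combinations(range(k), 2)]
    return np.column_stack(cols)


@dataclass(frozen=True)
class QuadraticModel:
    """Coefficients of a full second-order model in one representation.

    ``interaction`` is ordered by ``itertools.combinations(range(k), 2)``,
    i.e. (0,1), (0,2), (1,2) for three factors.
    """

    representation: str
    factors: list[Factor]
    beta0: float
    linear: np.ndarray
    quadratic: np.ndarray
    interaction: np.ndarray
    response_name: str = ""

    def __post_init__(self) -> None:
        if self.representation not in (ACTUAL, CODED):
            raise RepresentationError(
                f"representation must be 'actual' or 'coded', got {self.representation!r}"
            )
        k = self.k
        object.__setattr__(self, "linear", np.asarray(self.linear, float))
        object.__setattr__(self, "quadratic", np.asarray(self.quadratic, float))
        object.__setattr__(self, "interaction", np.asarray(self.interaction, float))
        n_pairs = k * (k - 1) // 2
        if self.linear.shape != (k,) or self.quadratic.shape != (k,):
            raise DimensionError(f"linear/quadratic coefficients must have length {k}")
        if self.interaction.shape != (n_pairs,):
            raise DimensionError(f"interaction coefficients must have length {n_pairs}")

    @property
    def k(self) -> int:
        return len(self.factors)

    @property
    def p(self) -> int:
        return 1 + 2 * self.k + self.k * (self.k - 1) // 2

    @property
    def factor_names(self) -> list[str]:
        return [f.name for f in self.factors]

    def coefficients(self) -> np.ndarray:
        """Flat coefficient vector in basis order (see :func:`basis_matrix`)."""
        return np.concatenate([[self.beta0], self.linear, self.quadratic, self.interaction])

    @classmethod
    def from_coefficients(cls, coefs, factors, representation, response_name="") -> "QuadraticModel":
        coefs = np.asarray(coefs, float)
        k = len(factors)
        return cls(
            representation=representation,
            factors=list(factors),
            beta0=float(coefs[0]),
            linear=coefs[1 : 1 + k],
            quadratic=coefs[1 + k : 1 + 2 * k],
            interaction=coefs[1 + 2 * k :],
            response_name=response_name,
        )

    def interaction_between(self, name_a: str, name_b: str) -> float:
        """Interaction coefficient for an unordered pair of factor names."""
        idx = {n: i for i, n in enumerate(self.factor_names)}
        i, j = sorted((idx[name_a], idx[name_b]))
        pairs = list(itertools.combinations(range(self.k), 2))
        return float(self.interaction[pairs.index((i, j))])

    # -- prediction -------------------------------------------------------

    def predict(self, levels, covariance: np.ndarray | None = None,
                representation: str | None = None):
        """Evaluate the polynomial at one or more points.

        ``levels`` must be given in the model's own representation; pass
        ``representation=`` to assert which one you are using — a mismatch
        raises :class:`RepresentationError` rather than silently coercing.
        With ``covariance`` (the p x p coefficient covariance from a fit)
        the standard error of the mean prediction is returned as well.
        """
        if representation is not None and representation != self.representation:
            raise RepresentationError(
                f"model is in {self.representation!r} units but levels were "
                f"declared {representation!r}"
            )
        arr = np.asarray(levels, dtype=float)
        scalar = arr.ndim == 1
        z = basis_matrix(arr)
        if z.shape[1] != self.p:
            raise DimensionError(
                f"expected {self.k} levels per point, got shape {arr.shape}"
            )
        yhat = z @ self.coefficients()
        if covariance is None:
            return float(yhat[0]) if scalar else yhat
        se = np.sqrt(np.einsum("ij,jk,ik->i", z, covariance, z))
        if scalar:
            return float(yhat[0]), float(se[0])
        return yhat, se

    # -- representation conversion ---------------------------------------

    def _substitute(self, shift: np.ndarray, scale: np.ndarray) -> "QuadraticModel":
        """Coefficients after the substitution x_i = shift_i + scale_i * u_i."""
        k = self.k
        pairs = list(itertools.combinations(range(k), 2))
        bij = {pq: self.interaction[n] for n, pq in enumerate(pairs)}
        b0, bi, bii = self.beta0, self.linear, self.quadratic

        c0 = (
            b0
            + float(bi @ shift)
            + float(bii @ (shift**2))
            + sum(v * shift[i] * shift[j] for (i, j), v in bij.items())
        )
        ci = np.empty(k)
        for i in range(k):
            cross = sum(
                v * shift[j]
                for (p, q), v in bij.items()
                for j in ((q,) if p == i else (p,) if q == i else ())
            )
            ci[i] = scale[i] * (bi[i] + 2.0 * bii[i] * shift[i] + cross)
        cii = bii * scale**2
        cij = np.array([bij[(i, j)] * scale[i] * scale[j] for i, j in pairs])
        return replace(self, beta0=c0, linear=ci, quadratic=cii, interaction=cij)

    def to_representation(self, target: str) -> "QuadraticModel":
        """Convert between actual-unit and coded-unit coefficient sets.

        The polynomial is unchanged as a surface: predictions at
        corresponding points agree to numerical round-off.
        """
        if target not in (ACTUAL, CODED):
            raise RepresentationError(f"unknown representation {target!r}")
        if target == self.representation:
            return self
        if not self.factors:
            raise ConversionError("conversion requires factor centers and half-ranges")
        centers = np.array([f.center for f in self.factors])
        halves = np.array([f.half_range for f in self.factors])
        if self.representation == ACTUAL:
            out = self._substitute(centers, halves)  # x = m + a u
        else:
            out = self._substitute(-centers / halves, 1.0 / halves)  # u = (x - m)/a
        return replace(out, representation=target)

    def coded_levels_for(self, actual_levels) -> np.ndarray:
        return to_coded(self.factors, actual_levels)

    # -- serialization ----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "response_name": self.response_name,
            "representation": self.representation,
            "factors": [
                {"name": f.name, "center": f.center, "half_range": f.half_range,
                 "units": f.units}
                for f in self.factors
            ],
            "beta0": self.beta0,
            "linear": self.linear.tolist(),
            "quadratic": self.quadratic.tolist(),
            "interaction": self.interaction.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "QuadraticModel":
        return cls(
            representation=d["representation"],
            factors=[Factor(**f) for f in d["factors"]],
            beta0=float(d["beta0"]),
            linear=np.asarray(d["linear"], float),
            quadratic=np.asarray(d["quadratic"], float),
            interaction=np.asarray(d["interaction"], float),
            response_name=d.get("response_name", ""),
        )

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "QuadraticModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))
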
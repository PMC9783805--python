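"""Desirability transforms and multi-response integration.

Each response y is mapped to a desirability d(y) in [0, 1] by a linear
ramp between two anchors.  For a maximize goal
d = (y - min) / (max - min); for a minimize goal
d = (max - y) / (max - min); values beyond the anchors are clipped to
0 or 1.  Responses are integrated into the overall desirability

    R = (prod_i d_i)**(1/n),

the geometric mean, so any fully undesirable response (d = 0)
annihilates R.

The two responses modelled here are body fat (Bf) and fertility (F);
their four direction combinations are the named scenarios:
I Bf-high/F-low (the obesity + ovarian-dysfunction condition),
II Bf-low/F-high, III both high, IV both low.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DegenerateAnchorError, IncompleteInputError
from .models import QuadraticModel

__all__ = [
    "ResponseGoal",
    "Scenario",
    "SCENARIO_DIRECTIONS",
    "desirability_value",
    "overall_desirability",
    "model_anchors",
    "build_scenario",
]

MAXIMIZE = "maximize"
MINIMIZE = "minimize"

#: goal direction per response for the four named scenarios
SCENARIO_DIRECTIONS = {
    "I": {"Bf": MAXIMIZE, "F": MINIMIZE},
    "II": {"Bf": MINIMIZE, "F": MAXIMIZE},
    "III": {"Bf": MAXIMIZE, "F": MAXIMIZE},
    "IV": {"Bf": MINIMIZE, "F": MINIMIZE},
}


@dataclass(frozen=True)
class ResponseGoal:
    """Direction and anchor range for one response's desirability ramp."""

    response_name: str
    direction: str
    anchor_min: float
    anchor_max: float

    def __post_init__(self):
        if self.direction not in (MAXIMIZE, MINIMIZE):
            raise ValueError(f"direction must be maximize/minimize, got {self.direction!r}")
        if not self.anchor_min < self.anchor_max:
            raise DegenerateAnchorError(
                f"{self.response_name}: anchors must satisfy min < max, "
                f"got ({self.anchor_min}, {self.anchor_max})"
            )


@dataclass(frozen=True)
class Scenario:
    """A named set of per-response goals."""

    name: str
    goals: tuple[ResponseGoal, ...]

    @property
    def response_names(self) -> list[str]:
        return [g.response_name for g in self.goals]

    def goal_for(self, response_name: str) -> ResponseGoal:
        for g in self.goals:
            if g.response_name == response_name:
                return g
        raise IncompleteInputError(f"scenario {self.name} has no goal for {response_name!r}")


def desirability_value(goal: ResponseGoal, y):
    """Linear-ramp desirability of y under ``goal``, clipped to [0, 1]."""
    y = np.asarray(y, dtype=float)
    span = goal.anchor_max - goal.anchor_min
    if goal.direction == MAXIMIZE:
        d = (y - goal.anchor_min) / span
    else:
        d = (goal.anchor_max - y) / span
    d = np.clip(d, 0.0, 1.0)
    return float(d) if d.ndim == 0 else d


def overall_desirability(scenario: Scenario, responses: dict):
    """Geometric-mean overall desirability R of the scenario's responses.

    ``responses`` maps response name to a value (or array of values).
    """
    ds = []
    for goal in scenario.goals:
        if goal.response_name not in responses:
            raise IncompleteInputError(
                f"scenario {scenario.name} needs response {goal.response_name!r}"
            )
        ds.append(np.asarray(desirability_value(goal, responses[goal.response_name])))
    prod = np.prod(np.broadcast_arrays(*ds), axis=0)
    r = prod ** (1.0 / len(ds))
    return float(r) if np.ndim(r) == 0 else r


def model_anchors(
    model: QuadraticModel,
    coded_bounds: tuple[float, float] = (-1.682, 1.682),
    resolution: int = 41,
) -> tuple[float, float]:
    """Anchor range = min/max of model predictions over the design domain.

    The domain is a dense grid of the coded star-cube (default
    [-1.682, 1.682] per factor); anchors are model-based because the
    integrated surfaces are evaluated on model predictions, not raw data.
    """
    axes = [np.linspace(coded_bounds[0], coded_bounds[1], resolution)] * model.k
    grid = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, model.k)
    coded_model = model.to_representation("coded")
    preds = coded_model.predict(grid)
    return float(preds.min()), float(preds.max())


def build_scenario(
    name: str,
    models: dict[str, QuadraticModel],
    directions: dict[str, str] | None = None,
    anchors: dict[str, tuple[float, float]] | None = None,
    coded_bounds: tuple[float, float] = (-1.682, 1.682),
    resolution: int = 41,
) -> Scenario:
    """Build a scenario, deriving anchors from the model surfaces by default.

    ``name`` may be one of the four canonical scenarios (directions
    implied) or any label with explicit ``directions``.
    """
    if directions is None:
        try:
            directions = SCENARIO_DIRECTIONS[name]
        except KeyError:
            raise IncompleteInputError(
                f"unknown scenario {name!r}: give explicit directions"
            ) from None
    goals = []
    for response, direction in directions.items():
        if response not in models:
            raise IncompleteInputError(f"no model supplied for response {response!r}")
        if anchors and response in anchors:
            lo, hi = anchors[response]
        else:
            lo, hi = model_anchors(models[response], coded_bounds, resolution)
        goals.append(ResponseGoal(response, direction, lo, hi))
    return Scenario(name=name, goals=tuple(goals))
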
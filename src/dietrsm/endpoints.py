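"""Scalar assay endpoints computed from raw bench quantities.

All endpoints are simple normalizations — an amount divided by a size or
a time — and are therefore homogeneous of degree 1 in the numerator and
-1 in the denominator.
"""

from __future__ import annotations

from collections.abc import Iterable

import numpy as np

from .errors import UndefinedRatioError

__all__ = [
    "body_fat",
    "fertility",
    "inhibition_ratio",
    "hemolymph_glucose",
]


def body_fat(tg_concentration, buffer_volume: float, body_weight: float) -> float:
    """Body fat Bf in nmol triglyceride per mg body weight.

    Bf = C_TG (nmol/uL) x V (uL) / body weight (mg).  ``tg_concentration``
    may be an iterable of replicate aliquot concentrations (e.g. the three
    5-uL aliquots per homogenate); these are averaged before normalization
    — for a mean, aggregation before or after the division is identical.
    """
    if not body_weight > 0:
        raise ValueError(f"body_weight must be positive, got {body_weight}")
    if not buffer_volume > 0:
        raise ValueError(f"buffer_volume must be positive, got {buffer_volume}")
    if isinstance(tg_concentration, Iterable):
        c = float(np.mean(np.asarray(list(tg_concentration), dtype=float)))
    else:
        c = float(tg_concentration)
    if c < 0:
        raise ValueError(f"tg_concentration must be >= 0, got {c}")
    return c * float(buffer_volume) / float(body_weight)


def fertility(egg_count: int, n_females: int, n_days: float = 1.0) -> float:
    """Fertility F: mean eggs laid per female per day.

    ``n_females`` should be the number of flies alive during the laying
    window (survival-adjusted denominator).
    """
    if n_females < 1:
        raise ValueError(f"n_females must be >= 1, got {n_females}")
    if not n_days > 0:
        raise ValueError(f"n_days must be positive, got {n_days}")
    if egg_count < 0:
        raise ValueError(f"egg_count must be >= 0, got {egg_count}")
    return float(egg_count) / (float(n_females) * float(n_days))


def inhibition_ratio(f_treated: float, f_control: float) -> float:
    """Egg production under treatment divided by that under control.

    Values below 1 quantify suppression of egg laying by the treatment
    diet relative to its normal-sugar control.
    """
    if f_control <= 0:
        raise UndefinedRatioError(
            f"control fertility must be positive, got {f_control}"
        )
    if f_treated < 0:
        raise ValueError(f"f_treated must be >= 0, got {f_treated}")
    return float(f_treated) / float(f_control)


def hemolymph_glucose(glucose_mass: float, body_weight: float) -> float:
    """Hemolymph glucose normalized to body weight, ug glucose per mg."""
    if not body_weight > 0:
        raise ValueError(f"body_weight must be positive, got {body_weight}")
    if glucose_mass < 0:
        raise ValueError(f"glucose_mass must be >= 0, got {glucose_mass}")
    return float(glucose_mass) / float(body_weight)
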
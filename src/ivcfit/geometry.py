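"""Circle-fitting geometry for vessel cross-sections.

The inferior vena cava (IVC) has an oval cross-section before filter
placement and remodels toward a near-circular one afterwards.  This module
implements the predictive model built on that observation: treat the
pre-placement cross-section as an ellipse with axes equal to the maximum
and minimum projected diameters, approximate its perimeter with
Ramanujan's first formula,

    C = pi * [3(a + b) - sqrt((3a + b)(a + 3b))],

and report the diameter of the circle with the same circumference,

    D_eq = C / pi.

Composing the two steps with a = D_max/2 and b = D_min/2 gives the closed
form used throughout the package:

    D_eq = 1.5 (D_max + D_min) - sqrt((1.5 D_max + 0.5 D_min)(0.5 D_max + 1.5 D_min))

All diameters are carried in millimetres at double precision; rounding to
two decimals happens only at presentation time.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Union

import numpy as np

__all__ = [
    "ValidationError",
    "EdgeMeasurementPair",
    "VesselDiameters",
    "EllipseAxes",
    "PredictionResult",
    "mean_edge_diameter",
    "ramanujan_circumference",
    "equivalent_diameter",
    "equivalent_diameter_simplified",
    "predict_equivalent_diameter",
]

logger = logging.getLogger(__name__)


class ValidationError(ValueError):
    """Raised when an input violates a geometric or numeric precondition."""


def _require_positive_finite(value: float, name: str) -> float:
    value = float(value)
    if not math.isfinite(value):
        raise ValidationError(f"{name} must be finite, got {value!r}")
    if value <= 0:
        raise ValidationError(f"{name} must be positive, got {value!r}")
    return value


@dataclass(frozen=True)
class EdgeMeasurementPair:
    """Two edge diameters (mm) measured at one projection and stage.

    ``x1`` is taken at the superior margin of the region of interest and
    ``x2`` at the inferior margin; their mean is the stage diameter.
    """

    x1: float
    x2: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "x1", _require_positive_finite(self.x1, "x1"))
        object.__setattr__(self, "x2", _require_positive_finite(self.x2, "x2"))


@dataclass(frozen=True)
class VesselDiameters:
    """A subject's maximum/minimum diameter pair (mm) at one stage.

    ``stage`` is ``"pre"`` (before filter placement) or ``"post"`` (after).
    By default ``d_max < d_min`` is an error; pass ``auto_sort=True`` to
    tolerate swapped columns (a warning is logged), which can happen when
    single-angle measurement files are not ordered.
    """

    d_max: float
    d_min: float
    stage: str = "pre"
    auto_sort: bool = field(default=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        d_max = _require_positive_finite(self.d_max, "d_max")
        d_min = _require_positive_finite(self.d_min, "d_min")
        if self.stage not in ("pre", "post"):
            raise ValidationError(f"stage must be 'pre' or 'post', got {self.stage!r}")
        if d_max < d_min:
            if not self.auto_sort:
                raise ValidationError(
                    f"d_max ({d_max}) < d_min ({d_min}); pass auto_sort=True to reorder"
                )
            logger.warning("auto-sorting swapped diameters: d_max=%s < d_min=%s", d_max, d_min)
            d_max, d_min = d_min, d_max
        object.__setattr__(self, "d_max", d_max)
        object.__setattr__(self, "d_min", d_min)


@dataclass(frozen=True)
class EllipseAxes:
    """Semi-major and semi-minor axes (mm) of an elliptical cross-section."""

    a: float
    b: float

    def __post_init__(self) -> None:
        a = _require_positive_finite(self.a, "a")
        b = _require_positive_finite(self.b, "b")
        if a < b:
            raise ValidationError(f"semi-major axis a ({a}) must be >= semi-minor b ({b})")
        object.__setattr__(self, "a", a)
        object.__setattr__(self, "b", b)


@dataclass(frozen=True)
class PredictionResult:
    """Ellipse axes, approximated circumference, and equivalent diameter."""

    axes: EllipseAxes
    circumference: float
    d_eq: float


def mean_edge_diameter(pair: EdgeMeasurementPair) -> float:
    """Average the superior and inferior edge diameters of one projection.

    The same arithmetic applies before placement (vessel edges) and after
    (filter strut-junction edges): D = (x1 + x2) / 2.
    """
    if not isinstance(pair, EdgeMeasurementPair):
        pair = EdgeMeasurementPair(*pair)
    return (pair.x1 + pair.x2) / 2.0


def ramanujan_circumference(axes: EllipseAxes) -> float:
    """Approximate an ellipse perimeter with Ramanujan's first formula.

    Exact for circles (returned as 2*pi*a without roundoff); relative
    error stays below 0.5% over all aspect ratios and below 1e-4 for
    b/a >= 0.3, which covers physiological vessel ovality.
    """
    if not isinstance(axes, EllipseAxes):
        axes = EllipseAxes(*axes)
    a, b = axes.a, axes.b
    if a == b:
        return 2.0 * math.pi * a
    return math.pi * (3.0 * (a + b) - math.sqrt((3.0 * a + b) * (a + 3.0 * b)))


def equivalent_diameter(circumference: float) -> float:
    """Diameter of the circle whose circumference equals ``circumference``."""
    c = _require_positive_finite(circumference, "circumference")
    return c / math.pi


def equivalent_diameter_simplified(d_max, d_min):
    """Closed-form equivalent diameter from max/min diameters (vectorised).

    Algebraically identical to composing the ellipse construction,
    Ramanujan's perimeter, and the circumference-to-diameter conversion;
    accepts scalars or numpy arrays.  Circular inputs (d_max == d_min)
    return d_max exactly.  Inputs are assumed validated (d_max >= d_min > 0).
    """
    d_max = np.asarray(d_max, dtype=float)
    d_min = np.asarray(d_min, dtype=float)
    with np.errstate(invalid="ignore"):
        general = 1.5 * (d_max + d_min) - np.sqrt(
            (1.5 * d_max + 0.5 * d_min) * (0.5 * d_max + 1.5 * d_min)
        )
    out = np.where(d_max == d_min, d_max, general)
    if out.ndim == 0:
        return float(out)
    return out


def predict_equivalent_diameter(pre: VesselDiameters) -> PredictionResult:
    """Predict the post-placement diameter from pre-placement measurements.

    Models the pre-placement cross-section as an ellipse with semi-axes
    a = d_max/2 and b = d_min/2, estimates its circumference C with
    Ramanujan's formula, and returns D_eq = C/pi.  The result always
    satisfies d_min <= D_eq <= d_max, strictly when d_max > d_min.
    """
    if not isinstance(pre, VesselDiameters):
        raise ValidationError(
            f"predict_equivalent_diameter expects VesselDiameters, got {type(pre).__name__}"
        )
    axes = EllipseAxes(a=pre.d_max / 2.0, b=pre.d_min / 2.0)
    circumference = ramanujan_circumference(axes)
    # circular sections are their own equivalent (avoid pi*x/pi roundoff)
    d_eq = pre.d_max if pre.d_max == pre.d_min else circumference / math.pi
    return PredictionResult(axes=axes, circumference=circumference, d_eq=d_eq)
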
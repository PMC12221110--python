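"""Closed-form critical-DO2i models and body-surface-area scaling.

Three temperature-dependent models of the critical indexed oxygen delivery
(DO2i, mL·min⁻¹·m⁻²) during cardiopulmonary bypass:

* an exponential decay model driven by a Q10 metabolic coefficient,
* a linear per-degree reduction (Van't Hoff style approximation), and
* a calibrated quadratic curve, scaled by patient body surface area (BSA)
  to give an individualized total oxygen-delivery target (mL·min⁻¹).

All functions accept scalars or NumPy arrays of temperatures and are pure.
Values are computed at full precision; :func:`display_round` applies the
one-decimal presentation rounding used in reports and the CLI.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import ParameterError, TemperatureRangeError

__all__ = [
    "VALIDITY_RANGE",
    "QuadraticCoefficients",
    "CANONICAL_COEFFS",
    "Q10Model",
    "LinearModel",
    "Patient",
    "quadratic_per_m2",
    "q10_per_m2",
    "linear_per_m2",
    "scale_by_bsa",
    "bsa_from_anthropometrics",
    "display_round",
]

#: Temperature span (°C) over which the models are considered calibrated.
VALIDITY_RANGE: tuple[float, float] = (24.0, 37.0)


def _require_finite(name: str, value: float) -> float:
    value = float(value)
    if not math.isfinite(value):
        raise ParameterError(f"{name} must be a finite real number, got {value!r}")
    return value


@dataclass(frozen=True)
class QuadraticCoefficients:
    """Coefficients (a, b, c) of the per-m² quadratic DO2i curve a·T² + b·T + c.

    ``a`` controls curvature (mL·min⁻¹·m⁻²·°C⁻²), ``b`` the slope
    (mL·min⁻¹·m⁻²·°C⁻¹) and ``c`` the intercept (mL·min⁻¹·m⁻²).
    """

    a: float
    b: float
    c: float

    def __post_init__(self) -> None:
        for name in ("a", "b", "c"):
            object.__setattr__(self, name, _require_finite(name, getattr(self, name)))

    def __call__(self, temp_c):
        t = np.asarray(temp_c, dtype=float)
        out = self.a * t * t + self.b * t + self.c
        return float(out) if np.isscalar(temp_c) else out

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.a, self.b, self.c)


#: Canonical published coefficients of the calibrated quadratic curve.
CANONICAL_COEFFS = QuadraticCoefficients(a=0.057, b=10.754, c=-194.245)


@dataclass(frozen=True)
class Q10Model:
    """Exponential metabolic-decay model.

    ``q10`` is stored as a decay factor (< 1) applied per 10 °C of cooling:
    prediction = baseline_do2i · q10^((ref_temp − T)/10).  This is equivalent
    to the conventional Q10 > 1 form with exponent (T − ref_temp)/10 via
    q10_conventional = 1/q10.
    """

    baseline_do2i: float = 300.0
    q10: float = 0.6
    ref_temp: float = 37.0

    def __post_init__(self) -> None:
        if not self.baseline_do2i > 0:
            raise ParameterError(f"baseline_do2i must be > 0, got {self.baseline_do2i}")
        if not 0 < self.q10 <= 1:
            raise ParameterError(f"q10 must be in (0, 1], got {self.q10}")
        if not 30 <= self.ref_temp <= 40:
            raise ParameterError(f"ref_temp must be within 30-40 °C, got {self.ref_temp}")


@dataclass(frozen=True)
class LinearModel:
    """Linear per-degree metabolic-reduction model.

    prediction = baseline_do2i · (1 − fraction_per_degree · (ref_temp − T)).
    """

    baseline_do2i: float = 300.0
    fraction_per_degree: float = 0.06
    ref_temp: float = 37.0

    def __post_init__(self) -> None:
        if not self.baseline_do2i > 0:
            raise ParameterError(f"baseline_do2i must be > 0, got {self.baseline_do2i}")
        if not 0 < self.fraction_per_degree < 0.1:
            raise ParameterError(
                f"fraction_per_degree must be in (0, 0.1), got {self.fraction_per_degree}"
            )
        if not 30 <= self.ref_temp <= 40:
            raise ParameterError(f"ref_temp must be within 30-40 °C, got {self.ref_temp}")
        # prediction must stay non-negative over the validity span
        low = VALIDITY_RANGE[0]
        if self.baseline_do2i * (1 - self.fraction_per_degree * (self.ref_temp - low)) < 0:
            raise ParameterError(
                "linear model parameters yield a negative prediction at "
                f"{low} °C (inside the validity range)"
            )


_BSA_BOUNDS = (0.2, 3.0)


@dataclass(frozen=True)
class Patient:
    """Patient sizing for target individualization.

    Provide ``bsa`` (m²) directly, or ``height_cm`` and ``weight_kg`` from
    which BSA is derived (DuBois by default, Mosteller selectable).
    """

    bsa: float | None = None
    height_cm: float | None = None
    weight_kg: float | None = None
    bsa_formula: str = "dubois"

    def __post_init__(self) -> None:
        if self.bsa is None:
            if self.height_cm is None or self.weight_kg is None:
                raise ParameterError("provide bsa, or both height_cm and weight_kg")
            derived = bsa_from_anthropometrics(
                self.height_cm, self.weight_kg, self.bsa_formula
            )
            object.__setattr__(self, "bsa", derived)
        lo, hi = _BSA_BOUNDS
        if not lo <= self.bsa <= hi:
            raise ParameterError(f"bsa must be within {lo}-{hi} m², got {self.bsa:.3f}")


def _check_temperature(temp_c, extrapolate: bool) -> None:
    lo, hi = VALIDITY_RANGE
    t = np.asarray(temp_c, dtype=float)
    if not np.all(np.isfinite(t)):
        raise TemperatureRangeError("temperature must be finite")
    outside = (t < lo) | (t > hi)
    if np.any(outside):
        offending = np.atleast_1d(t)[np.atleast_1d(outside)]
        msg = (
            f"temperature {offending[0]:g} °C outside the model validity "
            f"range {lo:g}-{hi:g} °C"
        )
        if not extrapolate:
            raise TemperatureRangeError(msg)
        warnings.warn(msg + " (extrapolating)", stacklevel=3)


def quadratic_per_m2(
    temp_c,
    coeffs: QuadraticCoefficients = CANONICAL_COEFFS,
    *,
    extrapolate: bool = False,
):
    """Per-m² DO2i from the calibrated quadratic curve a·T² + b·T + c.

    Raises :class:`TemperatureRangeError` outside 24-37 °C unless
    ``extrapolate=True`` (which downgrades the error to a warning).
    """
    _check_temperature(temp_c, extrapolate)
    return coeffs(temp_c)


def q10_per_m2(temp_c, model: Q10Model = Q10Model(), *, extrapolate: bool = False):
    """Per-m² DO2i from the exponential Q10 decay model."""
    _check_temperature(temp_c, extrapolate)
    t = np.asarray(temp_c, dtype=float)
    out = model.baseline_do2i * model.q10 ** ((model.ref_temp - t) / 10.0)
    return float(out) if np.isscalar(temp_c) else out


def linear_per_m2(temp_c, model: LinearModel = LinearModel(), *, extrapolate: bool = False):
    """Per-m² DO2i from the linear per-degree reduction model."""
    _check_temperature(temp_c, extrapolate)
    t = np.asarray(temp_c, dtype=float)
    out = model.baseline_do2i * (1.0 - model.fraction_per_degree * (model.ref_temp - t))
    return float(out) if np.isscalar(temp_c) else out


def scale_by_bsa(per_m2, patient: Patient):
    """Total oxygen-delivery target (mL·min⁻¹): per-m² value × patient BSA."""
    p = np.asarray(per_m2, dtype=float)
    if np.any(p < 0):
        raise ParameterError("per_m2 must be non-negative")
    out = p * patient.bsa
    return float(out) if np.isscalar(per_m2) else out


def bsa_from_anthropometrics(height_cm: float, weight_kg: float, formula: str = "dubois") -> float:
    """Body surface area (m²) from height and weight.

    ``formula`` is ``"dubois"`` (0.007184·h^0.725·w^0.425) or
    ``"mosteller"`` (sqrt(h·w/3600)).
    """
    if not 30 <= height_cm <= 250:
        raise ParameterError(f"height_cm must be within 30-250, got {height_cm}")
    if not 1 <= weight_kg <= 300:
        raise ParameterError(f"weight_kg must be within 1-300, got {weight_kg}")
    formula = formula.lower()
    if formula == "dubois":
        return 0.007184 * height_cm**0.725 * weight_kg**0.425
    if formula == "mosteller":
        return math.sqrt(height_cm * weight_kg / 3600.0)
    raise ParameterError(f"unknown BSA formula {formula!r}; use 'dubois' or 'mosteller'")


def display_round(value, decimals: int = 1):
    """Presentation rounding (round-half-even, one decimal by default).

    Internal computation is always full precision; this is applied only at
    the display/report layer.
    """
    if np.isscalar(value):
        return round(float(value), decimals)
    return np.round(np.asarray(value, dtype=float), decimals)
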
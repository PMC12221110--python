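"""Target trajectories over bypass temperature profiles, comparison tables,
and a pump-flow helper.

A :class:`TemperatureProfile` (time-stamped core temperatures) is mapped
row-wise through the three DO2i models and BSA scaling into a
:class:`TargetTrajectory`.  No interpolation is performed between samples;
targets are computed at the given time points only.

The pump-flow helper uses the standard clinical arterial oxygen content
CaO2 = 1.36·Hb·(SaO2/100) + 0.003·PaO2 (mL O2/dL); these constants are a
clinical convention, not part of the published target model.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ParameterError, ParseError, TemperatureRangeError
from .models import (
    CANONICAL_COEFFS,
    LinearModel,
    Patient,
    Q10Model,
    QuadraticCoefficients,
    display_round,
    linear_per_m2,
    q10_per_m2,
    quadratic_per_m2,
    scale_by_bsa,
)

__all__ = [
    "ModelBundle",
    "TemperatureProfile",
    "TargetTrajectory",
    "compute_trajectory",
    "comparison_table",
    "flow_target",
    "TRAJECTORY_COLUMNS",
]

#: Fixed output column order for trajectory CSV/JSON.
TRAJECTORY_COLUMNS = (
    "time_min",
    "temp_c",
    "linear_do2i",
    "q10_do2i",
    "tado2i_per_m2",
    "tado2i_total",
)

_PROFILE_TEMP_BOUNDS = (15.0, 40.0)


@dataclass(frozen=True)
class ModelBundle:
    """Parameter bundle: one instance of each model plus the extrapolation flag."""

    quadratic: QuadraticCoefficients = CANONICAL_COEFFS
    q10: Q10Model = Q10Model()
    linear: LinearModel = LinearModel()
    extrapolate: bool = False


@dataclass(frozen=True)
class TemperatureProfile:
    """Ordered (time_min, temp_c) samples from bypass start."""

    time_min: np.ndarray
    temp_c: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.time_min, dtype=float).ravel()
        c = np.asarray(self.temp_c, dtype=float).ravel()
        if t.size == 0:
            raise ParameterError("profile needs at least one sample")
        if t.size != c.size:
            raise ParameterError("time_min and temp_c must have equal length")
        if not (np.all(np.isfinite(t)) and np.all(np.isfinite(c))):
            raise ParameterError("profile contains non-finite values")
        if np.any(np.diff(t) <= 0):
            raise ParameterError("time_min must be strictly increasing")
        lo, hi = _PROFILE_TEMP_BOUNDS
        if np.any((c < lo) | (c > hi)):
            raise ParameterError(
                f"profile temperatures must be within {lo:g}-{hi:g} °C (plausibility check)"
            )
        object.__setattr__(self, "time_min", t)
        object.__setattr__(self, "temp_c", c)

    def __len__(self) -> int:
        return int(self.time_min.size)

    @classmethod
    def from_csv(cls, path) -> "TemperatureProfile":
        """Read a profile CSV with named columns ``time_min,temp_c`` (header required)."""
        try:
            df = pd.read_csv(path, comment="#", encoding="utf-8", float_precision="round_trip")
        except (pd.errors.ParserError, pd.errors.EmptyDataError, UnicodeDecodeError) as exc:
            raise ParseError(f"cannot parse profile CSV {path}: {exc}") from exc
        missing = {"time_min", "temp_c"} - set(df.columns)
        if missing:
            raise ParseError(
                f"profile CSV {path} is missing required column(s): {sorted(missing)}"
            )
        for col in ("time_min", "temp_c"):
            bad = pd.to_numeric(df[col], errors="coerce").isna()
            if bad.any():
                line = int(bad.idxmax()) + 2
                raise ParseError(f"bad value in column {col!r} at line {line} of {path}")
        return cls(df["time_min"].to_numpy(float), df["temp_c"].to_numpy(float))


@dataclass(frozen=True)
class TargetTrajectory:
    """Per-sample DO2i targets for all three models, plus the BSA-scaled total."""

    frame: pd.DataFrame
    bsa: float

    def __len__(self) -> int:
        return len(self.frame)

    def to_csv(self, path=None, decimals: int | None = None) -> str:
        df = self._display(decimals)
        text = df.to_csv(index=False)
        if path is not None:
            Path(path).write_text(text, encoding="utf-8")
        return text

    def to_json(self, path=None, decimals: int | None = None) -> str:
        df = self._display(decimals)
        text = json.dumps(df.to_dict(orient="records"), indent=2) + "\n"
        if path is not None:
            Path(path).write_text(text, encoding="utf-8")
        return text

    def _display(self, decimals: int | None) -> pd.DataFrame:
        if decimals is None:
            return self.frame
        df = self.frame.copy()
        for col in TRAJECTORY_COLUMNS[2:]:
            df[col] = display_round(df[col].to_numpy(), decimals)
        return df


def compute_trajectory(
    profile: TemperatureProfile,
    patient: Patient,
    params: ModelBundle = ModelBundle(),
) -> TargetTrajectory:
    """Row-wise application of the three models and BSA scaling.

    Pure function of its inputs.  Out-of-range temperatures raise a
    :class:`TemperatureRangeError` naming the offending time point, unless
    ``params.extrapolate`` is set.
    """
    temps = profile.temp_c
    try:
        quad = quadratic_per_m2(temps, params.quadratic, extrapolate=params.extrapolate)
        q10 = q10_per_m2(temps, params.q10, extrapolate=params.extrapolate)
        lin = linear_per_m2(temps, params.linear, extrapolate=params.extrapolate)
    except TemperatureRangeError as exc:
        from .models import VALIDITY_RANGE

        lo, hi = VALIDITY_RANGE
        outside = (temps < lo) | (temps > hi)
        t_bad = profile.time_min[outside][0]
        raise TemperatureRangeError(
            f"{exc} (first offending sample at time_min={t_bad:g})"
        ) from None
    frame = pd.DataFrame(
        {
            "time_min": profile.time_min,
            "temp_c": temps,
            "linear_do2i": np.atleast_1d(lin),
            "q10_do2i": np.atleast_1d(q10),
            "tado2i_per_m2": np.atleast_1d(quad),
            "tado2i_total": np.atleast_1d(scale_by_bsa(quad, patient)),
        },
        columns=list(TRAJECTORY_COLUMNS),
    )
    return TargetTrajectory(frame=frame, bsa=patient.bsa)


def comparison_table(
    temps,
    patient: Patient,
    params: ModelBundle = ModelBundle(),
    decimals: int = 1,
) -> pd.DataFrame:
    """Model-comparison table: one row per temperature, values display-rounded.

    Columns: temp_c, linear_do2i, q10_do2i, tado2i_per_m2, tado2i_total.
    An empty temperature list yields an empty table.
    """
    temps = np.asarray(list(temps), dtype=float)
    cols = ["temp_c", "linear_do2i", "q10_do2i", "tado2i_per_m2", "tado2i_total"]
    if temps.size == 0:
        return pd.DataFrame(columns=cols)
    quad = quadratic_per_m2(temps, params.quadratic, extrapolate=params.extrapolate)
    return pd.DataFrame(
        {
            "temp_c": temps,
            "linear_do2i": display_round(
                linear_per_m2(temps, params.linear, extrapolate=params.extrapolate), decimals
            ),
            "q10_do2i": display_round(
                q10_per_m2(temps, params.q10, extrapolate=params.extrapolate), decimals
            ),
            "tado2i_per_m2": display_round(quad, decimals),
            "tado2i_total": display_round(scale_by_bsa(quad, patient), decimals),
        },
        columns=cols,
    )


def flow_target(
    total_do2: float,
    hb_g_dl: float,
    sao2_pct: float,
    pao2_mmhg: float,
) -> float:
    """Pump flow (L·min⁻¹) needed to deliver ``total_do2`` mL O2/min.

    flow = total_do2 / (CaO2 × 10) with CaO2 in mL O2/dL; the ×10 converts
    dL to L of blood.
    """
    if total_do2 < 0:
        raise ParameterError("total_do2 must be non-negative")
    if not 2 <= hb_g_dl <= 25:
        raise ParameterError(f"hb_g_dl must be within 2-25, got {hb_g_dl}")
    if not 50 <= sao2_pct <= 100:
        raise ParameterError(f"sao2_pct must be within 50-100, got {sao2_pct}")
    if not 30 <= pao2_mmhg <= 700:
        raise ParameterError(f"pao2_mmhg must be within 30-700, got {pao2_mmhg}")
    cao2 = 1.36 * hb_g_dl * (sao2_pct / 100.0) + 0.003 * pao2_mmhg
    return total_do2 / (cao2 * 10.0)
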
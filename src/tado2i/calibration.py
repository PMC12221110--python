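"""Quadratic least-squares calibration with bootstrap confidence intervals.

Fits per-m² DO2i as a quadratic function of core temperature by ordinary
least squares on the design (1, T, T²), reports R² and the standard error
of estimate (SEE, residual df = n − 3), and attaches seeded case-resampling
percentile bootstrap intervals for the coefficients.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DegenerateDataError, ParameterError, ParseError
from .models import QuadraticCoefficients

__all__ = [
    "CalibrationDataset",
    "RegressionFit",
    "fit_quadratic",
    "bootstrap_coefficients",
    "fit_with_bootstrap",
    "read_calibration_csv",
    "write_fit_json",
]

log = logging.getLogger(__name__)

_TEMP_BOUNDS = (20.0, 40.0)
_COEF_NAMES = ("a", "b", "c")


@dataclass(frozen=True)
class CalibrationDataset:
    """Ordered (temperature, per-m² DO2i) observations used for fitting."""

    temp_c: np.ndarray
    do2i_per_m2: np.ndarray
    provenance: str = "user"

    def __post_init__(self) -> None:
        t = np.asarray(self.temp_c, dtype=float).ravel()
        y = np.asarray(self.do2i_per_m2, dtype=float).ravel()
        if t.size != y.size:
            raise ParameterError("temp_c and do2i_per_m2 must have equal length")
        if t.size == 0:
            raise ParameterError("dataset is empty")
        if not (np.all(np.isfinite(t)) and np.all(np.isfinite(y))):
            raise ParameterError("dataset contains non-finite values")
        lo, hi = _TEMP_BOUNDS
        if np.any((t < lo) | (t > hi)):
            raise ParameterError(f"temperatures must be within {lo:g}-{hi:g} °C")
        if np.any(y <= 0):
            raise ParameterError("DO2i values must be positive")
        if self.provenance not in ("synthetic", "user"):
            raise ParameterError("provenance must be 'synthetic' or 'user'")
        object.__setattr__(self, "temp_c", t)
        object.__setattr__(self, "do2i_per_m2", y)

    def __len__(self) -> int:
        return int(self.temp_c.size)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"temp_c": self.temp_c, "do2i_per_m2": self.do2i_per_m2})


@dataclass(frozen=True)
class RegressionFit:
    """A fitted quadratic with goodness-of-fit statistics and optional CIs."""

    coeffs: QuadraticCoefficients
    r_squared: float
    see: float
    n: int
    ci: dict[str, tuple[float, float]] | None = None
    confidence: float | None = None
    n_resamples: int | None = None
    seed: int | None = None
    n_redrawn: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.r_squared <= 1.0 + 1e-12:
            raise ParameterError(f"r_squared out of [0, 1]: {self.r_squared}")
        if self.see < 0:
            raise ParameterError("see must be non-negative")
        if self.ci is not None:
            point = dict(zip(_COEF_NAMES, self.coeffs.as_tuple()))
            for name, (lo, hi) in self.ci.items():
                if not lo <= point[name] <= hi:
                    raise ParameterError(
                        f"CI for {name} [{lo}, {hi}] does not bracket {point[name]}"
                    )

    def to_dict(self) -> dict:
        d = {
            "coefficients": {"a": self.coeffs.a, "b": self.coeffs.b, "c": self.coeffs.c},
            "r_squared": self.r_squared,
            "see": self.see,
            "n": self.n,
        }
        if self.ci is not None:
            d["ci"] = {k: list(v) for k, v in self.ci.items()}
            d["confidence"] = self.confidence
            d["n_resamples"] = self.n_resamples
            d["seed"] = self.seed
            d["n_redrawn"] = self.n_redrawn
        return d


def _design(temp: np.ndarray) -> np.ndarray:
    return np.vander(temp, 3, increasing=True)  # columns 1, T, T²


def fit_quadratic(data: CalibrationDataset) -> RegressionFit:
    """Ordinary least squares of DO2i on (1, T, T²).

    R² = 1 − SS_res/SS_tot; SEE = sqrt(SS_res/(n − 3)).  Requires at least
    four points and three distinct temperatures.
    """
    t, y = data.temp_c, data.do2i_per_m2
    n = len(data)
    if n < 4:
        raise DegenerateDataError(
            f"need at least 4 points for a quadratic fit with residual df, got {n}"
        )
    if np.unique(t).size < 3:
        raise DegenerateDataError(
            "need at least 3 distinct temperatures for a quadratic fit"
        )
    beta, *_ = np.linalg.lstsq(_design(t), y, rcond=None)
    resid = y - _design(t) @ beta
    ss_res = float(resid @ resid)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r_squared = 1.0 if ss_tot == 0 else max(0.0, min(1.0, 1.0 - ss_res / ss_tot))
    see = float(np.sqrt(ss_res / (n - 3)))
    coeffs = QuadraticCoefficients(c=beta[0], b=beta[1], a=beta[2])
    return RegressionFit(coeffs=coeffs, r_squared=r_squared, see=see, n=n)


def bootstrap_coefficients(
    data: CalibrationDataset,
    n_resamples: int = 1000,
    confidence: float = 0.95,
    seed: int = 0,
) -> tuple[dict[str, tuple[float, float]], int]:
    """Case-resampling percentile bootstrap intervals for (a, b, c).

    Resamples observation pairs with replacement; resamples with fewer than
    three distinct temperatures are rank-deficient and are redrawn (the
    redraw count is returned and logged).  Identical seeds yield identical
    intervals.

    Returns ``(intervals, n_redrawn)`` with intervals keyed 'a', 'b', 'c'.
    """
    n = len(data)
    if n < 6:
        raise ParameterError(f"need at least 6 points for a stable bootstrap, got {n}")
    if n_resamples < 100:
        raise ParameterError(f"n_resamples must be >= 100, got {n_resamples}")
    if not 0 < confidence < 1:
        raise ParameterError(f"confidence must be in (0, 1), got {confidence}")
    fit_quadratic(data)  # full-data fit must succeed first

    rng = np.random.default_rng(seed)
    t, y = data.temp_c, data.do2i_per_m2

    idx = rng.integers(0, n, size=(n_resamples, n))
    n_redrawn = 0
    while True:
        distinct = (np.sort(t[idx], axis=1)[:, 1:] != np.sort(t[idx], axis=1)[:, :-1]).sum(
            axis=1
        ) + 1
        bad = distinct < 3
        if not bad.any():
            break
        n_redrawn += int(bad.sum())
        idx[bad] = rng.integers(0, n, size=(int(bad.sum()), n))
    if n_redrawn:
        log.info("redrew %d rank-deficient bootstrap resamples", n_redrawn)

    # batched least squares via QR on the stacked designs
    xb = _design(t)[idx]                      # (B, n, 3)
    yb = y[idx]                               # (B, n)
    q, r = np.linalg.qr(xb)
    rhs = np.einsum("bij,bi->bj", q, yb)[..., None]
    beta = np.linalg.solve(r, rhs)[..., 0]  # (B, 3) → columns c, b, a

    alpha = (1.0 - confidence) / 2.0
    lo = np.quantile(beta, alpha, axis=0)
    hi = np.quantile(beta, 1.0 - alpha, axis=0)
    # beta columns are intercept, slope, curvature
    intervals = {
        "a": (float(lo[2]), float(hi[2])),
        "b": (float(lo[1]), float(hi[1])),
        "c": (float(lo[0]), float(hi[0])),
    }
    return intervals, n_redrawn


def fit_with_bootstrap(
    data: CalibrationDataset,
    n_resamples: int = 1000,
    confidence: float = 0.95,
    seed: int = 0,
) -> RegressionFit:
    """Full-data fit plus bootstrap intervals in one :class:`RegressionFit`."""
    base = fit_quadratic(data)
    ci, n_redrawn = bootstrap_coefficients(data, n_resamples, confidence, seed)
    return dataclasses.replace(
        base,
        ci=ci,
        confidence=confidence,
        n_resamples=n_resamples,
        seed=seed,
        n_redrawn=n_redrawn,
    )


def read_calibration_csv(path, provenance: str = "user") -> CalibrationDataset:
    """Read a calibration CSV with named columns ``temp_c,do2i_per_m2``.

    Header required; ``#`` lines are treated as comments; UTF-8; '.' decimal
    separator.
    """
    try:
        df = pd.read_csv(path, comment="#", encoding="utf-8", float_precision="round_trip")
    except (pd.errors.ParserError, pd.errors.EmptyDataError, UnicodeDecodeError) as exc:
        raise ParseError(f"cannot parse calibration CSV {path}: {exc}") from exc
    missing = {"temp_c", "do2i_per_m2"} - set(df.columns)
    if missing:
        raise ParseError(
            f"calibration CSV {path} is missing required column(s): {sorted(missing)}"
        )
    for col in ("temp_c", "do2i_per_m2"):
        bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
        if bad.any():
            # +2: one for the header line, one for 1-based numbering
            line = int(bad.idxmax()) + 2
            raise ParseError(f"non-numeric value in column {col!r} at line {line} of {path}")
        if df[col].isna().any():
            line = int(df[col].isna().idxmax()) + 2
            raise ParseError(f"missing value in column {col!r} at line {line} of {path}")
    return CalibrationDataset(
        df["temp_c"].to_numpy(float), df["do2i_per_m2"].to_numpy(float), provenance
    )


def write_fit_json(fit: RegressionFit, path=None) -> str:
    """Serialize a fit report to JSON; write to ``path`` if given."""
    text = json.dumps(fit.to_dict(), indent=2, sort_keys=True) + "\n"
    if path is not None:
        Path(path).write_text(text, encoding="utf-8")
    return text
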
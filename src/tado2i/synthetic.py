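"""Seeded synthetic calibration datasets.

Generates (temperature, per-m² DO2i) reference data on a grid inside the
24-37 °C calibration span, with the noise-free mean given by one of the
closed-form models (Q10 exponential by default, linear, quadratic, or a
Q10/linear blend) plus additive Gaussian noise.  Everything is driven by an
explicit seed so outputs are byte-reproducible.
"""

from __future__ import annotations

import io
from dataclasses import dataclass

import numpy as np

from .calibration import CalibrationDataset
from .errors import ParameterError
from .models import (
    CANONICAL_COEFFS,
    LinearModel,
    Q10Model,
    QuadraticCoefficients,
    linear_per_m2,
    q10_per_m2,
    quadratic_per_m2,
)

__all__ = ["SyntheticSpec", "generate_dataset", "dataset_to_csv"]

_GENERATORS = ("q10", "linear", "quadratic", "blend")


@dataclass(frozen=True)
class SyntheticSpec:
    """Recipe for a synthetic calibration dataset.

    The default grid (24-37 °C, step 0.5) has 27 points; the default
    generator is the Q10 model with noise sd 3.0 mL·min⁻¹·m⁻².
    ``blend_weight`` is the Q10 share when ``generator_model='blend'``
    (mean = w·Q10 + (1−w)·linear).
    """

    temp_start: float = 24.0
    temp_stop: float = 37.0
    temp_step: float = 0.5
    generator_model: str = "q10"
    noise_sd: float = 3.0
    blend_weight: float = 0.8
    seed: int = 0
    q10_model: Q10Model = Q10Model()
    linear_model: LinearModel = LinearModel()
    quadratic_coeffs: QuadraticCoefficients = CANONICAL_COEFFS

    def __post_init__(self) -> None:
        if not 24.0 <= self.temp_start <= self.temp_stop <= 37.0:
            raise ParameterError("temperature grid must lie within 24-37 °C")
        if self.temp_step <= 0:
            raise ParameterError("temp_step must be positive")
        if self.generator_model not in _GENERATORS:
            raise ParameterError(
                f"generator_model must be one of {_GENERATORS}, got {self.generator_model!r}"
            )
        if self.noise_sd < 0:
            raise ParameterError("noise_sd must be non-negative")
        if not 0.0 <= self.blend_weight <= 1.0:
            raise ParameterError("blend_weight must be in [0, 1]")

    def grid(self) -> np.ndarray:
        n = int(np.floor((self.temp_stop - self.temp_start) / self.temp_step + 1e-9)) + 1
        return self.temp_start + self.temp_step * np.arange(n)

    def mean_curve(self, temps: np.ndarray) -> np.ndarray:
        if self.generator_model == "q10":
            return q10_per_m2(temps, self.q10_model)
        if self.generator_model == "linear":
            return linear_per_m2(temps, self.linear_model)
        if self.generator_model == "quadratic":
            return quadratic_per_m2(temps, self.quadratic_coeffs)
        w = self.blend_weight
        return w * q10_per_m2(temps, self.q10_model) + (1 - w) * linear_per_m2(
            temps, self.linear_model
        )


def generate_dataset(spec: SyntheticSpec) -> CalibrationDataset:
    """Draw one synthetic dataset: mean curve on the grid + Gaussian noise."""
    temps = spec.grid()
    if temps.size == 0:
        raise ParameterError("temperature grid is empty")
    mean = spec.mean_curve(temps)
    rng = np.random.default_rng(spec.seed)
    y = mean + rng.normal(0.0, spec.noise_sd, size=temps.size)
    # noise must not push values non-physical; clip is a no-op at default settings
    y = np.maximum(y, 1e-6)
    return CalibrationDataset(temps, y, provenance="synthetic")


def dataset_to_csv(data: CalibrationDataset, spec: SyntheticSpec | None = None, path=None) -> str:
    """Write the calibration CSV dialect, with provenance comment lines.

    When ``spec`` is given its fields are embedded as ``#``-prefixed header
    comments so the file is self-describing and regenerable.
    """
    buf = io.StringIO()
    if spec is not None:
        buf.write(
            "# synthetic calibration dataset\n"
            f"# generator_model={spec.generator_model} noise_sd={spec.noise_sd:g} "
            f"blend_weight={spec.blend_weight:g} seed={spec.seed}\n"
            f"# grid={spec.temp_start:g}:{spec.temp_stop:g}:{spec.temp_step:g}\n"
        )
    buf.write("temp_c,do2i_per_m2\n")
    for t, y in zip(data.temp_c, data.do2i_per_m2):
        # .17g round-trips doubles exactly, so refitting the CSV reproduces
        # the in-memory fit bit for bit
        buf.write(f"{t:.17g},{y:.17g}\n")
    text = buf.getvalue()
    if path is not None:
        from pathlib import Path

        Path(path).write_text(text, encoding="utf-8")
    return text
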
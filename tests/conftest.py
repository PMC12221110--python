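from fractions import Fraction

import numpy as np
import pytest

from tado2i import CalibrationDataset, Patient

# Published model-comparison table at BSA = 1.8 m²:
# temp -> (linear per-m², Q10 per-m², quadratic per-m², total)
TABLE1 = {
    25.0: (84.0, 162.5, 110.2, 198.4),
    28.0: (138.0, 189.4, 151.6, 272.8),
    30.0: (174.0, 209.8, 179.7, 323.4),
    33.0: (228.0, 244.6, 222.7, 400.9),
    35.0: (264.0, 270.9, 252.0, 453.5),
    37.0: (300.0, 300.0, 281.7, 507.0),
}

CANONICAL = (0.057, 10.754, -194.245)


def exact_quadratic_ols(temps, values):
    """Independent oracle: quadratic OLS via normal equations in exact
    rational arithmetic (immune to the ill-conditioning of the raw design).

    Returns (a, b, c) as floats.
    """
    pts = [(Fraction(str(t)), Fraction(str(v))) for t, v in zip(temps, values)]
    # design columns 1, T, T^2 -> X'X (3x3) and X'y (3,) in exact rationals
    xtx = [[Fraction(0)] * 3 for _ in range(3)]
    xty = [Fraction(0)] * 3
    for t, y in pts:
        row = [Fraction(1), t, t * t]
        for i in range(3):
            xty[i] += row[i] * y
            for j in range(3):
                xtx[i][j] += row[i] * row[j]
    # Gaussian elimination with exact arithmetic
    m = [xtx[i] + [xty[i]] for i in range(3)]
    for col in range(3):
        piv = next(r for r in range(col, 3) if m[r][col] != 0)
        m[col], m[piv] = m[piv], m[col]
        for r in range(3):
            if r != col and m[r][col] != 0:
                f = m[r][col] / m[col][col]
                m[r] = [m[r][k] - f * m[col][k] for k in range(4)]
    c, b, a = (m[i][3] / m[i][i] for i in range(3))
    return float(a), float(b), float(c)


@pytest.fixture
def patient_18():
    return Patient(bsa=1.8)


@pytest.fixture
def canonical_dataset():
    """Noise-free samples of the canonical quadratic at integer 24..37 °C."""
    a, b, c = CANONICAL
    temps = np.arange(24.0, 38.0)
    return CalibrationDataset(temps, a * temps**2 + b * temps + c, provenance="synthetic")
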
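"""Linear calibration and inverse prediction with confidence intervals.

An unknown concentration x0 is estimated from a measured mean response y0 by
inverting the fitted line, x0 = (y0 - b0) / b1, with the approximate
univariate-calibration standard error

    SE(x0) = (s / |b1|) * sqrt(1/m + 1/n + (x0 - xbar)^2 / Sxx)

where s is the residual SD of the calibration fit, m the number of replicate
measurements of the unknown, n the number of calibration points, and Sxx the
sum of squared deviations of the calibration concentrations.  The 1-alpha
interval is x0 +/- t(n-2, 1-alpha/2) * SE(x0) (Massart et al.'s approximation,
the default of the standard chemometric calibration tooling).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from . import chem

__all__ = [
    "CalibrationModel",
    "InversePrediction",
    "fit_calibration",
    "inverse_predict",
    "normalize_content",
    "CHICORIC_ACID_FORMULA",
    "QUANT_EIC",
]

#: Neutral formula of the quantified target compound (dicaffeoyl tartaric acid).
CHICORIC_ACID_FORMULA = "C22H18O12"

#: Acquisition metadata for the quantification EIC (positive-mode sodium
#: adduct, 5 ppm extraction tolerance).  Recorded as configuration only; peak
#: integration happens upstream of this package.
QUANT_EIC = {"mz": 497.06905, "adduct": "[M+Na]+", "ppm_tol": 5.0}


@dataclass(frozen=True)
class CalibrationModel:
    """OLS line y = b0 + b1 x with the statistics inverse prediction needs."""

    b0: float
    b1: float
    s: float       # residual SD, n-2 denominator
    n: int
    x_mean: float
    sxx: float
    r_squared: float
    x_min: float
    x_max: float

    def predict(self, x: float) -> float:
        return self.b0 + self.b1 * x


@dataclass(frozen=True)
class InversePrediction:
    estimate: float
    lower: float
    upper: float
    level: float
    m: int
    se: float
    extrapolated: bool


def fit_calibration(
    concentrations: Sequence[float], areas: Sequence[float]
) -> CalibrationModel:
    """Ordinary least squares of response on concentration."""
    x = np.asarray(concentrations, float)
    y = np.asarray(areas, float)
    if x.shape != y.shape:
        raise ValueError("concentrations and areas must have equal length")
    if np.unique(x).size < 3:
        raise ValueError("need at least 3 distinct concentrations")
    n = x.size
    x_mean = x.mean()
    sxx = float(((x - x_mean) ** 2).sum())
    if sxx <= 0:
        raise ValueError("degenerate concentration design")
    b1 = float(((x - x_mean) * (y - y.mean())).sum() / sxx)
    b0 = float(y.mean() - b1 * x_mean)
    resid = y - (b0 + b1 * x)
    sse = float((resid**2).sum())
    sst = float(((y - y.mean()) ** 2).sum())
    s = float(np.sqrt(sse / (n - 2)))
    r2 = 1.0 if sst == 0 else 1.0 - sse / sst
    return CalibrationModel(b0, b1, s, n, float(x_mean), sxx, r2, float(x.min()), float(x.max()))


def inverse_predict(
    y0_mean: float,
    model: CalibrationModel,
    m: int = 1,
    level: float = 0.95,
) -> InversePrediction:
    """Point estimate and confidence interval for the concentration behind a
    mean response of ``m`` replicate measurements."""
    if m < 1:
        raise ValueError("replicate count m must be >= 1")
    if model.b1 == 0 or abs(model.b1) < 1e-12 * max(1.0, abs(model.b0)):
        raise ValueError("slope is (near) zero; inverse prediction undefined")
    x0 = (y0_mean - model.b0) / model.b1
    se = (model.s / abs(model.b1)) * np.sqrt(
        1.0 / m + 1.0 / model.n + (x0 - model.x_mean) ** 2 / model.sxx
    )
    t = stats.t.ppf(0.5 + level / 2, model.n - 2)
    extrapolated = not (model.x_min <= x0 <= model.x_max)
    return InversePrediction(
        float(x0), float(x0 - t * se), float(x0 + t * se), level, m, float(se), extrapolated
    )


def normalize_content(
    concentration_uM: float,
    extract_volume_L: float,
    molar_mass: float | str = CHICORIC_ACID_FORMULA,
    dry_weight_g: float | None = None,
) -> tuple[float, float | None]:
    """Convert a molar concentration to compound content.

    Returns (µg per seedling, µg per g dry weight).  ``molar_mass`` may be a
    number in g/mol or a neutral formula string (average molar mass is then
    computed).  The per-gram value is None when no dry weight is given.
    """
    if extract_volume_L <= 0:
        raise ValueError("extract volume must be positive")
    if isinstance(molar_mass, str):
        molar_mass = chem.average_mass(chem.parse_formula(molar_mass))
    if molar_mass <= 0:
        raise ValueError("molar mass must be positive")
    # µM x L = µmol; µmol x g/mol = µg
    ug_per_seedling = concentration_uM * extract_volume_L * molar_mass
    if dry_weight_g is None:
        return ug_per_seedling, None
    if dry_weight_g <= 0:
        raise ValueError("dry weight must be positive")
    return ug_per_seedling, ug_per_seedling / dry_weight_g
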
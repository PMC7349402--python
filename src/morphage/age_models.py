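"""Chronological-age vs predicted-age model fits and the AUC deviation index.

Predicted age is regressed on chronological age with polynomial fits of
degree 1-3; the best fit (by adjusted R^2) is summarized by the normalized
area under the fitted curve over the sample age range,

    AUC = 2 / (age_max - age_min)^2 * integral_{age_min}^{age_max}
          (yhat(y) - age_min) dy,

which equals 1 for the ideal model yhat = y, exceeds 1 under systematic age
overestimation and falls below 1 under underestimation. The signed
deviation AUC - 1 is the reported index.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .metrics import r2 as r2_score


@dataclass
class AgeModelFit:
    """A polynomial fit of predicted age on chronological age.

    ``coefficients`` are highest power first (p1..p_{d+1} layout).
    """

    degree: int
    coefficients: np.ndarray
    r2: float
    adjusted_r2: float
    age_min: float
    age_max: float

    def predict(self, age) -> np.ndarray:
        return np.polyval(self.coefficients, np.asarray(age, float))


@dataclass
class AucIndex:
    auc: float            # normalized area under the fitted curve
    deviation: float      # auc - 1 (negative: underestimation prevalence)


def fit_age_models(age, predicted, degrees=(1, 2, 3)) -> list[AgeModelFit]:
    """Least-squares polynomial fits of predicted on chronological age.

    Degrees with too few observations (n <= degree + 1) are skipped with a
    warning. Adjusted R^2 = 1 - (1 - R^2)(n - 1)/(n - d - 1).
    """
    y = np.asarray(age, float)
    yhat = np.asarray(predicted, float)
    if y.shape != yhat.shape:
        raise ValueError("length mismatch")
    n = y.size
    if n < 5:
        raise ValueError("need at least 5 observations")
    if np.ptp(y) == 0:
        raise ValueError("constant chronological age")
    fits = []
    for d in degrees:
        if n <= d + 1:
            warnings.warn(f"skipping degree {d}: n={n} too small",
                          RuntimeWarning, stacklevel=2)
            continue
        coeffs = np.polyfit(y, yhat, d)
        fitted = np.polyval(coeffs, y)
        r2_val = r2_score(yhat, fitted)
        adj = 1 - (1 - r2_val) * (n - 1) / (n - d - 1)
        fits.append(AgeModelFit(d, coeffs, r2_val, adj,
                                float(y.min()), float(y.max())))
    return fits


def select_best_fit(fits: list[AgeModelFit]) -> AgeModelFit:
    """Maximum adjusted R^2; ties resolve toward the lower degree."""
    if not fits:
        raise ValueError("no fits supplied")
    best = fits[0]
    for f in fits[1:]:
        if f.adjusted_r2 > best.adjusted_r2:
            best = f
    return best


def auc_deviation_index(fit: AgeModelFit) -> AucIndex:
    """Normalized AUC of the fit over [age_min, age_max], and AUC - 1.

    The polynomial integral is evaluated in closed form; the integrand is
    shifted by age_min so the ideal model scores exactly 1 on any range.
    """
    a, b = fit.age_min, fit.age_max
    if not b > a:
        raise ValueError("degenerate age range")
    antideriv = np.polyint(fit.coefficients)
    area = np.polyval(antideriv, b) - np.polyval(antideriv, a)
    area_shifted = area - a * (b - a)
    auc = 2.0 / (b - a) ** 2 * area_shifted
    return AucIndex(float(auc), float(auc - 1.0))
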
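"""Calibration-curve fitting, back-calculation checks, Mandel linearity and
matrix effects.

Quantification uses matrix-matched bracketing calibration: standards prepared
in blank milk extract are injected before, in the middle of and after each
sequence, an unweighted straight line is fitted through all standard
injections plus the point of origin, and every standard's back-calculated
concentration must fall strictly within 80-120% of nominal for the sequence
to be usable.

Linearity of the working range is delimited with Mandel's F-test: the
residual variance of the straight-line fit is compared against a second-order
fit; while the test rejects, the highest level is dropped.

The matrix effect is the relative slope loss of the matrix-matched curve
versus the solvent curve, SE = (1 - m_matrix / m_solvent) x 100%; positive
values are ion suppression.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .prep import PrepModel, extract_to_milk


class CalibrationError(ValueError):
    """Series unusable for regression."""


@dataclass
class CalibrationSeries:
    """Per-analyte (concentration, area) calibration data in extract units."""

    analyte_id: str
    conc: np.ndarray       # ng/mL extract, nominal
    area: np.ndarray       # counts x min
    matrix_matched: bool = True
    replicate_id: np.ndarray | None = None
    position: np.ndarray | None = None  # before / middle / after the sequence

    def __post_init__(self) -> None:
        self.conc = np.asarray(self.conc, dtype=float)
        self.area = np.asarray(self.area, dtype=float)
        if self.conc.shape != self.area.shape or self.conc.ndim != 1:
            raise CalibrationError("conc and area must be equal-length 1-D")
        if np.any(self.conc < 0):
            raise CalibrationError("concentrations must be >= 0")
        if len(np.unique(self.conc[self.conc > 0])) < 3:
            raise CalibrationError("need >= 3 distinct nonzero concentrations")

    @property
    def levels(self) -> np.ndarray:
        return np.unique(self.conc)


@dataclass
class CalibrationFit:
    """OLS straight-line fit plus the regression statistics downstream stages
    need (detection limits use x_bar, Q_x and the residual standard deviation)."""

    analyte_id: str
    slope: float                 # area per (ng/mL)
    intercept: float             # area
    residual_sd: float           # area units, n-2 degrees of freedom
    s_x0: float                  # ng/mL, residual_sd / slope
    mean_x: float                # ng/mL
    sum_sq_x: float              # (ng/mL)^2, Q_x = sum (x - x_bar)^2
    n_points: int
    r_squared: float
    matrix_matched: bool = True
    back_calc_accuracy: dict = field(default_factory=dict)  # nominal -> [%]
    include_origin: bool = True

    def predict(self, conc: float) -> float:
        return self.intercept + self.slope * conc

    def invert(self, area) -> np.ndarray | float:
        """Back-calculated extract concentration for a measured area."""
        return (np.asarray(area, dtype=float) - self.intercept) / self.slope


def fit_calibration(series: CalibrationSeries, *,
                    include_origin: bool = True) -> CalibrationFit:
    """Unweighted OLS of area on concentration.

    ``include_origin`` appends one (0, 0) observation -- the bracketing
    quantification calibration includes the point of origin as a datum (the
    intercept is still free).  Detection-limit regressions are fitted on the
    measured series alone.
    """
    x = series.conc
    y = series.area
    if include_origin:
        x = np.concatenate((x, [0.0]))
        y = np.concatenate((y, [0.0]))
    n = len(x)
    if n < 3:
        raise CalibrationError("need at least 3 points for a straight line")
    mean_x = float(np.mean(x))
    qx = float(np.sum((x - mean_x) ** 2))
    if qx == 0:
        raise CalibrationError("all concentrations identical: singular design")
    slope = float(np.sum((x - mean_x) * (y - np.mean(y))) / qx)
    intercept = float(np.mean(y) - slope * mean_x)
    resid = y - (intercept + slope * x)
    sse = float(np.sum(resid ** 2))
    residual_sd = float(np.sqrt(sse / (n - 2)))
    sst = float(np.sum((y - np.mean(y)) ** 2))
    r_squared = 1.0 if sst == 0 else max(0.0, 1.0 - sse / sst)
    fit = CalibrationFit(
        analyte_id=series.analyte_id, slope=slope, intercept=intercept,
        residual_sd=residual_sd,
        s_x0=residual_sd / slope if slope != 0 else float("inf"),
        mean_x=mean_x, sum_sq_x=qx, n_points=n, r_squared=r_squared,
        matrix_matched=series.matrix_matched, include_origin=include_origin)
    acc: dict[float, list[float]] = {}
    for c, a in zip(series.conc, series.area):
        if c > 0:
            acc.setdefault(float(c), []).append(float(fit.invert(a) / c * 100.0))
    fit.back_calc_accuracy = acc
    return fit


def back_calc_check(fit: CalibrationFit, *, low: float = 80.0,
                    high: float = 120.0) -> dict:
    """Strict 80 < accuracy < 120% check per nonzero level.

    Returns ``{"per_point": {nominal: [bool, ...]}, "usable": bool}``; one
    failing standard makes the whole calibration unusable.
    """
    if not fit.back_calc_accuracy:
        raise CalibrationError("fit carries no nonzero calibration levels")
    per_point = {c: [low < a < high for a in accs]
                 for c, accs in fit.back_calc_accuracy.items()}
    usable = all(all(v) for v in per_point.values())
    return {"per_point": per_point, "usable": usable}


def mandel_test(conc: np.ndarray, area: np.ndarray,
                alpha: float = 0.01) -> tuple[float, float]:
    """Mandel's F statistic for straight line vs second-order calibration.

    F = ((n-2) s_lin^2 - (n-3) s_quad^2) / s_quad^2 ~ F(1, n-3) under
    linearity; returns ``(F, critical value at 1 - alpha)``.
    """
    x = np.asarray(conc, dtype=float)
    y = np.asarray(area, dtype=float)
    n = len(x)
    if n < 5:
        raise CalibrationError("Mandel's test needs at least 5 points")
    res1 = y - np.polyval(np.polyfit(x, y, 1), x)
    res2 = y - np.polyval(np.polyfit(x, y, 2), x)
    s1sq = np.sum(res1 ** 2) / (n - 2)
    s2sq = np.sum(res2 ** 2) / (n - 3)
    if s2sq == 0:
        return (0.0 if np.allclose(res1, 0) else float("inf"),
                float(stats.f.ppf(1 - alpha, 1, n - 3)))
    f_val = ((n - 2) * s1sq - (n - 3) * s2sq) / s2sq
    return float(f_val), float(stats.f.ppf(1 - alpha, 1, n - 3))


def mandel_linearity(series: CalibrationSeries, alpha: float = 0.01, *,
                     prep: PrepModel = PrepModel()) -> dict:
    """Highest calibration level retained by iterated Mandel testing.

    While the F-test rejects linearity, the highest concentration level is
    removed and the test repeated.  Returns the retained upper bound in both
    extract (ng/mL) and milk (ug/L) units, or flags a nonlinear range when
    fewer than 5 levels remain.
    """
    x, y = series.conc.copy(), series.area.copy()
    while True:
        if len(np.unique(x)) < 5:
            return {"linear": False, "upper_ng_mL": None, "upper_ugL": None,
                    "note": "nonlinear range: fewer than 5 levels retained"}
        f_val, crit = mandel_test(x, y, alpha)
        if f_val <= crit:
            top = float(np.max(x))
            return {"linear": True, "upper_ng_mL": top,
                    "upper_ugL": extract_to_milk(top, prep),
                    "f_value": f_val, "f_critical": crit}
        keep = x < np.max(x)
        x, y = x[keep], y[keep]


def matrix_effect(m_matrix: float, m_solvent: float) -> float:
    """Matrix suppression/enhancement SE = (1 - m_matrix/m_solvent) x 100%.

    Positive = suppression, negative = enhancement; scale-invariant in the
    two slopes.
    """
    if m_solvent <= 0:
        raise ValueError("solvent calibration slope must be > 0")
    return (1.0 - m_matrix / m_solvent) * 100.0
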
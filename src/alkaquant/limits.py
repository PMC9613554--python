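"""Detection and quantification limits by the DIN 32645 calibration-curve
procedure.

From a low-concentration calibration regression with residual standard
deviation of the procedure s_x0 = s_y / b, n points, mean concentration x_bar
and spread Q_x = sum (x - x_bar)^2, the detection limit (decision limit,
"Nachweisgrenze") is

    x_NG = s_x0 * t(n-2; 1-alpha) * sqrt(1/m + 1/n + x_bar^2 / Q_x)

for m future determinations, and the quantification limit
("Bestimmungsgrenze") at relative result uncertainty 1/k solves the fixed
point

    x_BG = k * s_x0 * t(n-2; 1-alpha) * sqrt(1/m + 1/n + (x_BG - x_bar)^2 / Q_x).

The method defaults are an error probability alpha = 1% and k = 3, i.e. a
33.3% result uncertainty at the quantification limit.

Per analyte, the reported LOD is that of the *less* sensitive of the two mass
transitions (the qualifier must be detectable too, or identity cannot be
confirmed), while the reported LOQ is that of the quantifier transition,
which does the quantifying.  Reported limits are converted from extract
(ng/mL) to milk (ug/L) units with the sample-preparation factor.
"""
from __future__ import annotations

from dataclasses import dataclass, field

from scipy import stats

from .calibration import CalibrationFit
from .prep import PrepModel


class LimitsError(ValueError):
    """Detection-limit computation failed."""


@dataclass
class DetectionLimits:
    """Per-analyte reported limits in milk units plus per-transition detail."""

    analyte_id: str
    lod: float              # ug/L milk
    loq: float              # ug/L milk
    alpha: float = 0.01
    k: float = 3.0
    per_transition: dict = field(default_factory=dict)  # role -> (lod, loq) ng/mL
    grid_used: str | None = None
    degenerate: bool = False


def din_limits(fit: CalibrationFit, alpha: float = 0.01, k: float = 3.0,
               m_future: int = 1) -> tuple[float, float]:
    """Detection and quantification limits in extract units (ng/mL).

    A zero-residual fit is degenerate and returns ``(0.0, 0.0)``.  The
    quantification limit is iterated from 3 x LOD to a relative tolerance of
    1e-6 (at most 100 iterations).
    """
    if not (0 < alpha < 0.5):
        raise LimitsError("alpha must lie in (0, 0.5)")
    if k < 1:
        raise LimitsError("k must be >= 1")
    if fit.slope <= 0:
        raise LimitsError("calibration slope must be > 0")
    # numerically zero residuals (relative to the signal scale) are degenerate
    if fit.residual_sd <= 1e-9 * fit.slope * max(fit.mean_x, 1e-30):
        return 0.0, 0.0
    n = fit.n_points
    df = n - 2
    if df < 1:
        raise LimitsError("need at least 3 calibration points")
    t_q = stats.t.ppf(1 - alpha, df)
    s_x0 = fit.s_x0
    lod = s_x0 * t_q * (1 / m_future + 1 / n
                        + fit.mean_x ** 2 / fit.sum_sq_x) ** 0.5
    # the fixed-point map is a contraction iff (k t s_x0)^2 < Q_x; otherwise
    # no finite quantification limit exists for this transition
    if (k * t_q * s_x0) ** 2 >= fit.sum_sq_x:
        return float(lod), float("inf")
    x = 3.0 * lod
    for _ in range(100):
        x_new = k * s_x0 * t_q * (1 / m_future + 1 / n
                                  + (x - fit.mean_x) ** 2 / fit.sum_sq_x) ** 0.5
        if abs(x_new - x) <= 1e-6 * abs(x_new):
            return float(lod), float(x_new)
        x = x_new
    raise LimitsError("quantification-limit iteration did not converge")


def reported_limits(quant: tuple[float, float], qual: tuple[float, float],
                    prep: PrepModel = PrepModel(), *, analyte_id: str = "",
                    alpha: float = 0.01, k: float = 3.0,
                    grid_used: str | None = None) -> DetectionLimits:
    """Aggregate per-transition limits to the analyte's reported LOD/LOQ.

    LOD = max of the two transition LODs (confirmation needs both); LOQ = the
    quantifier's LOQ; both divided by the preparation concentration factor.
    """
    if quant is None or qual is None:
        raise LimitsError("both transitions must be evaluated")
    f = prep.concentration_factor
    lod = max(quant[0], qual[0]) / f
    loq = quant[1] / f
    degenerate = (lod == 0.0 or loq == 0.0)
    return DetectionLimits(
        analyte_id=analyte_id, lod=float(lod), loq=float(loq), alpha=alpha,
        k=k, per_transition={"quantifier": tuple(map(float, quant)),
                             "qualifier": tuple(map(float, qual))},
        grid_used=grid_used, degenerate=degenerate)


def sn_limits(height_per_conc: float, noise_sd: float) -> tuple[float, float]:
    """Classical S/N-based 3-sigma / 10-sigma limits, as a cross-check only.

    ``height_per_conc`` is peak height per unit concentration.
    """
    if height_per_conc <= 0:
        raise LimitsError("sensitivity must be > 0")
    return 3.0 * noise_sd / height_per_conc, 10.0 * noise_sd / height_per_conc
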
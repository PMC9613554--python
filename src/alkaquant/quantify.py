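"""Confirmation rules, censored quantification, sum contents, validation
statistics and dietary-exposure arithmetic.

A compound is *confirmed* in a sample only if, in both duplicate injections,
the peak retention time matches the bracketing standards within +-0.10 min
and the qualifier/quantifier ion ratio matches the standards within a
relative +-20%.  Unconfirmed signals are reported as not detected regardless
of their size.  Confirmed concentrations are censored against the analyte's
detection limits: below the LOD they are not detected, between LOD and LOQ
they are reported as "< LOQ", and only above the LOQ as a number.  Sum
contents count "< LOQ" analytes at half their LOQ.  Results are never
corrected for process recovery.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .calibration import CalibrationFit
from .limits import DetectionLimits
from .panel import SEMIQUANTITATIVE
from .peaks import Peak
from .prep import PrepModel

NOT_DETECTED = "not_detected"
DETECTED_BELOW_LOQ = "detected_below_loq"
QUANTIFIED = "quantified"

RT_TOLERANCE_MIN = 0.10
ION_RATIO_TOLERANCE = 0.20  # relative
SANTE_RECOVERY_BAND = (70.0, 120.0)  # percent


def round_half_away(x: float, decimals: int = 3) -> float:
    """Round half away from zero (so 0.0195 -> 0.020 at 3 decimals)."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class ConfirmationFlags:
    rt_ok: bool
    ratio_ok: bool
    duplicate_ok: bool

    @property
    def confirmed(self) -> bool:
        return self.rt_ok and self.ratio_ok and self.duplicate_ok


@dataclass
class QuantResult:
    """Per-analyte outcome for one sample (duplicate injections)."""

    analyte_id: str
    status: str
    conc: float | None = None           # ug/L milk, only when quantified
    conc_calculated: float | None = None  # uncensored back-calculated value
    rt_observed: list = field(default_factory=list)
    ion_ratio_observed: list = field(default_factory=list)
    confirmation: ConfirmationFlags | None = None
    semiquantitative: bool = False


def confirm_analyte(replicate_peaks: Sequence[Mapping[str, Peak | None]],
                    reference_rt: float, reference_ratio: float, *,
                    rt_tol: float = RT_TOLERANCE_MIN,
                    ratio_tol: float = ION_RATIO_TOLERANCE) -> ConfirmationFlags:
    """SANTE-style identity confirmation over duplicate injections.

    ``replicate_peaks`` holds one mapping per replicate with keys
    ``"quantifier"`` and ``"qualifier"`` (value ``None`` if no accepted peak).
    Reference retention time and ion ratio come from the same sequence's
    bracketing standards.
    """
    if reference_ratio <= 0:
        raise ValueError("reference ion ratio must be > 0")
    duplicate_ok = all(rep.get("quantifier") is not None
                       and rep.get("qualifier") is not None
                       for rep in replicate_peaks) and len(replicate_peaks) >= 2
    # rt and ratio are judged on whatever peaks exist; a missing peak is the
    # duplicate_ok flag's business, so the three flags stay independent
    rt_ok = True
    ratio_ok = True
    for rep in replicate_peaks:
        qn, ql = rep.get("quantifier"), rep.get("qualifier")
        if qn is not None and abs(qn.apex_rt - reference_rt) > rt_tol:
            rt_ok = False
        if qn is not None and ql is not None:
            ratio = ql.area / qn.area
            if abs(ratio - reference_ratio) > ratio_tol * reference_ratio:
                ratio_ok = False
    return ConfirmationFlags(rt_ok=rt_ok, ratio_ok=ratio_ok,
                             duplicate_ok=duplicate_ok)


def quantify_analyte(quant_areas: Sequence[float], fit: CalibrationFit,
                     limits: DetectionLimits, prep: PrepModel,
                     confirmed: ConfirmationFlags, *,
                     analyte_id: str | None = None) -> QuantResult:
    """Censored milk concentration from duplicate quantifier areas.

    The duplicate back-calculated extract concentrations are averaged,
    converted to milk units and censored against LOD/LOQ; results are not
    recovery-corrected.
    """
    aid = analyte_id or limits.analyte_id or fit.analyte_id
    conc_extract = float(np.mean([fit.invert(a) for a in quant_areas]))
    conc_milk = conc_extract / prep.concentration_factor
    semi = aid in SEMIQUANTITATIVE
    if not confirmed.confirmed or conc_milk < limits.lod:
        return QuantResult(analyte_id=aid, status=NOT_DETECTED,
                           conc_calculated=conc_milk, confirmation=confirmed,
                           semiquantitative=semi)
    if conc_milk < limits.loq:
        return QuantResult(analyte_id=aid, status=DETECTED_BELOW_LOQ,
                           conc_calculated=conc_milk, confirmation=confirmed,
                           semiquantitative=semi)
    return QuantResult(analyte_id=aid, status=QUANTIFIED,
                       conc=round_half_away(conc_milk, 3),
                       conc_calculated=conc_milk, confirmation=confirmed,
                       semiquantitative=semi)


def sum_content(results: Sequence[QuantResult],
                limits: Mapping[str, DetectionLimits | float]) -> float:
    """Sample sum content in ug/L milk.

    Quantified analytes contribute their concentration, analytes detected
    between LOD and LOQ contribute 0.5 x LOQ, not-detected ones zero; the sum
    is rounded half away from zero to 3 decimals.  ``limits`` may map analyte
    ids to either DetectionLimits or plain LOQ values.
    """
    total = 0.0
    for r in results:
        if r.status == QUANTIFIED:
            total += r.conc
        elif r.status == DETECTED_BELOW_LOQ:
            lim = limits[r.analyte_id]
            loq = lim.loq if isinstance(lim, DetectionLimits) else float(lim)
            total += 0.5 * loq
    return round_half_away(total, 3)


def recovery_rsd(concs: Sequence[float], nominal: float, *,
                 loq: float | None = None) -> dict:
    """Recovery (% of nominal) and repeatability RSD_r (%) of spike replicates.

    The level is skipped (all-NaN row) when the nominal concentration lies
    below the analyte's LOQ -- recovery is not evaluable there.
    """
    if nominal <= 0:
        raise ValueError("nominal spike concentration must be > 0")
    if loq is not None and nominal < loq:
        return {"recovery_pct": math.nan, "rsd_r_pct": math.nan,
                "n": 0, "skipped": True, "in_sante_band": None}
    vals = np.asarray([c for c in concs if c is not None], dtype=float)
    if len(vals) < 2:
        raise ValueError("need at least 2 evaluable replicates")
    mean = float(np.mean(vals))
    if mean == 0:
        raise ValueError("all replicates not detected")
    recovery = mean / nominal * 100.0
    rsd = float(np.std(vals, ddof=1)) / mean * 100.0
    lo, hi = SANTE_RECOVERY_BAND
    return {"recovery_pct": recovery, "rsd_r_pct": rsd, "n": int(len(vals)),
            "skipped": False, "in_sante_band": bool(lo <= recovery <= hi)}


def build_validation_table(rows: Mapping[str, Mapping[float, dict]],
                           extra: Mapping[str, Mapping] | None = None
                           ) -> pd.DataFrame:
    """Assemble a per-analyte x spike-level validation table.

    ``rows[analyte][level]`` are ``recovery_rsd`` results; ``extra[analyte]``
    may add lod/loq/r_squared/matrix-suppression columns.
    """
    records = []
    for aid, per_level in rows.items():
        rec: dict = {"analyte_id": aid,
                     "semiquantitative": aid in SEMIQUANTITATIVE}
        for level, res in sorted(per_level.items()):
            tag = f"{level:g}"
            rec[f"recovery_pct_{tag}"] = res["recovery_pct"]
            rec[f"rsd_r_pct_{tag}"] = res["rsd_r_pct"]
        if extra and aid in extra:
            rec.update(extra[aid])
        records.append(rec)
    return pd.DataFrame(records)


@dataclass
class ExposureResult:
    """Dietary exposure and margin of exposure for a milk concentration."""

    conc: float         # ug/L milk
    intake: float       # g/day
    bodyweight: float   # kg
    exposure: float     # ng/kg bw/day
    bmdl10: float       # ug/kg bw/day
    moe: float          # dimensionless


def exposure_moe(conc: float, intake: float, bw: float,
                 bmdl10: float = 237.0, density: float = 1.0) -> ExposureResult:
    """Exposure (ng/kg bw/day) and margin of exposure for a consumer group.

    exposure = conc x intake / (density x bw); MOE = 1000 x BMDL10 / exposure
    (+inf at zero exposure).  Milk density defaults to 1.0 g/mL so g/day and
    mL/day coincide.
    """
    if intake <= 0 or bw <= 0 or density <= 0 or bmdl10 <= 0:
        raise ValueError("intake, bodyweight, density and BMDL10 must be > 0")
    if conc < 0:
        raise ValueError("concentration must be >= 0")
    exposure = conc * intake / (density * bw)
    moe = math.inf if exposure == 0 else bmdl10 * 1000.0 / exposure
    return ExposureResult(conc=conc, intake=intake, bodyweight=bw,
                          exposure=exposure, bmdl10=bmdl10, moe=moe)
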
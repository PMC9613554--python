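"""End-to-end orchestration: simulate -> integrate -> calibrate -> limits ->
quantify/validate, driven by an experiment manifest.

The stages mirror a routine LC-MS/MS sequence: matrix-matched bracketing
standards are fitted per analyte, low-level series give DIN 32645 detection
limits, spiked replicates give recovery and repeatability, and unknown
samples are confirmed and quantified against the standards.
"""
from __future__ import annotations

import math
from pathlib import Path

import numpy as np
import pandas as pd

from .calibration import (CalibrationSeries, back_calc_check, fit_calibration,
                          mandel_linearity, matrix_effect)
from .limits import DetectionLimits, din_limits, reported_limits
from .panel import Panel, QUALIFIER, QUANTIFIER, load_default_panel
from .peaks import detect_peak, measure_forced_areas
from .prep import PrepModel
from .quantify import (ConfirmationFlags, QuantResult, confirm_analyte,
                       quantify_analyte, recovery_rsd, sum_content)
from .simulate import (Batch, DEFAULT_CAL_LEVELS, DEFAULT_SPIKE_LEVELS,
                       MatrixRecoveryModel, generate_calibration_batch,
                       generate_limits_series, generate_spike_experiment,
                       simulate_injection)


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


def _areas_by_level(batch: Batch, panel: Panel) -> pd.DataFrame:
    """Forced-integration areas joined with manifest concentration levels."""
    areas = measure_forced_areas(batch, panel)
    levels = {e["injection_id"]: e["level_ng_mL"]
              for e in batch.manifest.get("injections", [])}
    areas["level_ng_mL"] = areas["injection_id"].map(levels)
    if areas["level_ng_mL"].isna().any():
        raise PipelineError("calibration: manifest lacks levels for some injections")
    return areas


def calibrate_batch(batch: Batch, panel: Panel, *,
                    include_origin: bool = True) -> dict:
    """Per-analyte straight-line fits from a calibration batch (quantifier)."""
    areas = _areas_by_level(batch, panel)
    matrix = bool(batch.manifest.get("matrix_matched", True))
    fits = {}
    for aid in panel.analyte_ids:
        g = areas[(areas.analyte_id == aid) & (areas.role == QUANTIFIER)]
        series = CalibrationSeries(analyte_id=aid,
                                   conc=g.level_ng_mL.to_numpy(),
                                   area=g.area.to_numpy(),
                                   matrix_matched=matrix)
        fits[aid] = fit_calibration(series, include_origin=include_origin)
    return fits


def limits_from_batch(batch: Batch, panel: Panel, *,
                      prep: PrepModel = PrepModel(), alpha: float = 0.01,
                      k: float = 3.0) -> dict:
    """Per-analyte DIN 32645 limits from a two-grid low-level series.

    The low grid is used unless an analyte's fitted detection limit exceeds
    its top level, in which case the high grid takes over.
    """
    from .limits import LimitsError

    areas = _areas_by_level(batch, panel)
    grids = {e["injection_id"]: e["grid"]
             for e in batch.manifest.get("injections", [])}
    areas["grid"] = areas["injection_id"].map(grids)
    top_low = max(e["level_ng_mL"] for e in batch.manifest["injections"]
                  if e["grid"] == "low")

    def grid_limits(aid: str, grid_name: str):
        """(lod, loq) per role on one grid, or None if the grid is unusable
        for this analyte (non-positive fitted slope at these levels)."""
        per_role = {}
        for role in (QUANTIFIER, QUALIFIER):
            g = areas[(areas.analyte_id == aid) & (areas.role == role)
                      & (areas.grid == grid_name)]
            series = CalibrationSeries(analyte_id=aid,
                                       conc=g.level_ng_mL.to_numpy(),
                                       area=g.area.to_numpy())
            fit = fit_calibration(series, include_origin=False)
            try:
                per_role[role] = din_limits(fit, alpha=alpha, k=k)
            except LimitsError:
                return None
        return per_role

    out = {}
    for aid in panel.analyte_ids:
        low = grid_limits(aid, "low")
        chosen, per_role = "low", low
        if (low is None
                or max(low[QUANTIFIER][0], low[QUALIFIER][0]) > top_low
                or not math.isfinite(low[QUANTIFIER][1])
                or low[QUANTIFIER][1] > top_low):
            chosen, per_role = "high", grid_limits(aid, "high")
        if per_role is None:
            out[aid] = DetectionLimits(analyte_id=aid, lod=float("nan"),
                                       loq=float("nan"), alpha=alpha, k=k,
                                       grid_used=None, degenerate=True)
            continue
        out[aid] = reported_limits(per_role[QUANTIFIER], per_role[QUALIFIER],
                                   prep, analyte_id=aid, alpha=alpha, k=k,
                                   grid_used=chosen)
    return out


def reference_values(cal_batch: Batch, panel: Panel, *,
                     min_level: float = 1.0) -> dict:
    """Mean retention time and ion ratio of the bracketing standards.

    Only standards at or above ``min_level`` ng/mL are used, where both
    transitions are comfortably detectable.
    """
    levels = {e["injection_id"]: e["level_ng_mL"]
              for e in cal_batch.manifest.get("injections", [])}
    refs: dict[str, dict[str, float]] = {}
    for aid in panel.analyte_ids:
        rts, ratios = [], []
        for inj in cal_batch.injections:
            if levels.get(inj.injection_id, 0.0) < min_level:
                continue
            qn = detect_peak(inj.trace(aid, QUANTIFIER), panel.expected_rt(aid))
            ql = detect_peak(inj.trace(aid, QUALIFIER), panel.expected_rt(aid))
            if qn is not None:
                rts.append(qn.apex_rt)
            if qn is not None and ql is not None:
                ratios.append(ql.area / qn.area)
        if not rts or not ratios:
            raise PipelineError(
                f"reference values: no usable standard peaks for {aid}")
        refs[aid] = {"rt": float(np.mean(rts)),
                     "ion_ratio": float(np.mean(ratios))}
    return refs


def validate_spike_batch(spike_batch: Batch, fits: dict, limits: dict,
                         panel: Panel, *,
                         prep: PrepModel = PrepModel()) -> pd.DataFrame:
    """Recovery / RSD_r table from a spike experiment (Table-3 shaped)."""
    areas = measure_forced_areas(spike_batch, panel)
    level_of = {e["injection_id"]: e["level_ugL"]
                for e in spike_batch.manifest["injections"]}
    areas["level_ugL"] = areas["injection_id"].map(level_of)
    rows = []
    for aid in panel.analyte_ids:
        rec = {"analyte_id": aid}
        for level, g in areas[(areas.analyte_id == aid)
                              & (areas.role == QUANTIFIER)].groupby("level_ugL"):
            concs = [float(fits[aid].invert(a)) / prep.concentration_factor
                     for a in g.area]
            res = recovery_rsd(concs, float(level), loq=limits[aid].loq)
            tag = f"{level:g}"
            rec[f"recovery_pct_{tag}"] = res["recovery_pct"]
            rec[f"rsd_r_pct_{tag}"] = res["rsd_r_pct"]
        rec["lod_ugL"] = limits[aid].lod
        rec["loq_ugL"] = limits[aid].loq
        rec["r_squared"] = fits[aid].r_squared
        rows.append(rec)
    return pd.DataFrame(rows)


def quantify_sample(sample_injections: list, fits: dict, limits: dict,
                    refs: dict, panel: Panel, *,
                    prep: PrepModel = PrepModel(),
                    sample_id: str = "sample") -> dict:
    """Confirm and quantify one sample analysed in duplicate.

    Returns ``{"sample_id", "results": {analyte: QuantResult}, "sum_ugL"}``.
    """
    if len(sample_injections) < 2:
        raise PipelineError("quantify: samples are analysed in duplicate")
    results: dict[str, QuantResult] = {}
    for aid in panel.analyte_ids:
        rep_peaks = []
        quant_areas = []
        for inj in sample_injections:
            qn = detect_peak(inj.trace(aid, QUANTIFIER), panel.expected_rt(aid))
            ql = detect_peak(inj.trace(aid, QUALIFIER), panel.expected_rt(aid))
            rep_peaks.append({"quantifier": qn, "qualifier": ql})
            quant_areas.append(qn.area if qn is not None else math.nan)
        flags = confirm_analyte(rep_peaks, refs[aid]["rt"],
                                refs[aid]["ion_ratio"])
        if flags.duplicate_ok:
            result = quantify_analyte(quant_areas, fits[aid], limits[aid],
                                      prep, flags, analyte_id=aid)
        else:
            result = QuantResult(analyte_id=aid, status="not_detected",
                                 confirmation=flags)
        results[aid] = result
    return {"sample_id": sample_id, "results": results,
            "sum_ugL": sum_content(list(results.values()), limits)}


def occurrence_table(sample_reports: list, limits: dict) -> pd.DataFrame:
    """Per-sample occurrence report (Table-4 shaped): status/conc + sum.

    Quantified analytes show their concentration, trace-level detections show
    "< LOQ" with the analyte's LOQ, everything else "n.d.".
    """
    rows = []
    for rep in sample_reports:
        row: dict = {"sample_id": rep["sample_id"]}
        for aid, r in rep["results"].items():
            if r.status == "quantified":
                row[aid] = f"{r.conc:.3f}"
            elif r.status == "detected_below_loq":
                row[aid] = f"<{limits[aid].loq:.3f}"
            else:
                row[aid] = "n.d."
        row["sum_ugL"] = rep["sum_ugL"]
        rows.append(row)
    return pd.DataFrame(rows)


def run_pipeline(manifest: dict, out_dir: str | Path | None = None,
                 panel: Panel | None = None) -> dict:
    """Execute the design named in the manifest end to end.

    Supported designs: ``calibration`` (fits + Mandel + matrix effects),
    ``limits`` (DIN LOD/LOQ table), ``spike`` (validation table) and
    ``sample`` (confirmation + quantification of unknowns).  All randomness
    flows from the manifest seed; auxiliary batches a design needs
    (calibration for spikes, etc.) are derived from it deterministically.
    """
    design = manifest.get("design")
    if design not in {"calibration", "limits", "spike", "sample"}:
        raise PipelineError(f"manifest: unknown or missing design {design!r}")
    if "seed" not in manifest:
        raise PipelineError("manifest: missing seed")
    seed = int(manifest["seed"])
    panel = panel or load_default_panel()
    if manifest.get("analytes"):
        panel = panel.subset(list(manifest["analytes"]))
    prep = PrepModel(**manifest.get("prep", {}))
    model_kwargs = manifest.get("model", {})
    model = (MatrixRecoveryModel(**model_kwargs) if model_kwargs
             else MatrixRecoveryModel.default())
    out: dict = {"design": design, "seed": seed}

    cal_batch = generate_calibration_batch(
        panel, manifest.get("calibration_levels", DEFAULT_CAL_LEVELS),
        model, seed + 1, prep=prep)
    fits = calibrate_batch(cal_batch, panel)
    out["calibration"] = {aid: {"slope": f.slope, "intercept": f.intercept,
                                "r_squared": f.r_squared,
                                "usable": back_calc_check(f)["usable"]}
                          for aid, f in fits.items()}

    if design == "calibration":
        solvent_batch = generate_calibration_batch(
            panel, manifest.get("calibration_levels", DEFAULT_CAL_LEVELS),
            model, seed + 2, matrix_matched=False, prep=prep)
        solvent_fits = calibrate_batch(solvent_batch, panel)
        areas = _areas_by_level(cal_batch, panel)
        for aid, f in fits.items():
            g = areas[(areas.analyte_id == aid) & (areas.role == QUANTIFIER)]
            series = CalibrationSeries(aid, g.level_ng_mL.to_numpy(),
                                       g.area.to_numpy())
            out["calibration"][aid]["mandel"] = mandel_linearity(
                series, prep=prep)
            out["calibration"][aid]["matrix_suppression_pct"] = matrix_effect(
                f.slope, solvent_fits[aid].slope)

    if design in {"limits", "spike", "sample"}:
        lim_batch = generate_limits_series(panel, model, seed + 3, prep=prep)
        limits = limits_from_batch(lim_batch, panel, prep=prep,
                                   alpha=manifest.get("alpha", 0.01),
                                   k=manifest.get("k", 3.0))
        out["limits"] = {aid: {"lod_ugL": l.lod, "loq_ugL": l.loq,
                               "grid": l.grid_used}
                         for aid, l in limits.items()}

    if design == "spike":
        spike_batch = generate_spike_experiment(
            panel, manifest.get("spike_levels", DEFAULT_SPIKE_LEVELS),
            manifest.get("n_rep", 5), model, seed, prep=prep)
        out["validation_table"] = validate_spike_batch(
            spike_batch, fits, limits, panel, prep=prep)

    if design == "sample":
        samples = manifest.get("samples")
        if not samples:
            raise PipelineError("sample design: manifest lists no samples")
        refs = reference_values(cal_batch, panel)
        reports = []
        for i, spec in enumerate(samples):
            conc_map = {k: float(v) for k, v in spec.get("conc_ugL", {}).items()}
            duplicates = [
                simulate_injection(panel, conc_map, model, prep,
                                   in_matrix=True, seed=seed + 100 + 2 * i + d,
                                   injection_id=f"{spec.get('sample_id', i)}_d{d}")
                for d in range(2)]
            reports.append(quantify_sample(
                duplicates, fits, limits, refs, panel, prep=prep,
                sample_id=str(spec.get("sample_id", f"sample_{i + 1}"))))
        out["samples"] = reports
        out["occurrence_table"] = occurrence_table(reports, limits)

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        pd.DataFrame(out["calibration"]).T.to_csv(out_dir / "calibration.csv")
        if "limits" in out:
            pd.DataFrame(out["limits"]).T.to_csv(out_dir / "limits.csv")
        if "validation_table" in out:
            out["validation_table"].to_csv(out_dir / "validation.csv",
                                           index=False)
        if "occurrence_table" in out:
            out["occurrence_table"].to_csv(out_dir / "occurrence.csv",
                                           index=False)
    return out
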
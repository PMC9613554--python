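"""Plain-text readers and writers: traces, peak tables, manifests, reports.

The native interchange formats are deliberately plain tabular text (the
downstream computations consume peak areas, not profile spectra): a trace
file holds ``injection_id, analyte_id, role, time_min, intensity`` rows for a
whole batch, with the ground-truth manifest kept alongside as YAML.  Times
are stored in minutes with 4 decimals; round-trips are lossless at the
stated precision.
"""
from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .chromatogram import Chromatogram
from .panel import Panel, read_panel  # noqa: F401  (re-exported reader)
from .peaks import PEAK_TABLE_COLUMNS
from .simulate import Batch, Injection

TRACE_COLUMNS = ["injection_id", "analyte_id", "role", "time_min", "intensity"]


def write_traces(batch: Batch, path: str | Path,
                 manifest_path: str | Path | None = None) -> None:
    """Write all traces of a batch to one tabular file (+ YAML manifest)."""
    frames = []
    for inj in batch.injections:
        for (aid, role), tr in inj.traces.items():
            frames.append(pd.DataFrame({
                "injection_id": inj.injection_id, "analyte_id": aid,
                "role": role, "time_min": np.round(tr.times, 4),
                "intensity": tr.intensities}))
    df = (pd.concat(frames, ignore_index=True) if frames
          else pd.DataFrame(columns=TRACE_COLUMNS))
    df.to_csv(path, index=False, float_format="%.6g")
    if manifest_path is not None:
        write_manifest(batch.manifest, manifest_path)


def read_traces(path: str | Path, panel: Panel) -> Batch:
    """Rebuild a batch of chromatograms from a trace file.

    Transition metadata is re-attached from the panel; non-monotone time
    columns are rejected.
    """
    df = pd.read_csv(path)
    missing = set(TRACE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"trace file missing columns: {sorted(missing)}")
    injections = []
    for iid, inj_df in df.groupby("injection_id", sort=False):
        traces = {}
        for (aid, role), g in inj_df.groupby(["analyte_id", "role"], sort=False):
            t = g["time_min"].to_numpy(dtype=float)
            if np.any(np.diff(t) <= 0):
                raise ValueError(
                    f"non-monotone time column for {iid}/{aid}/{role}")
            trans = (panel.quantifier(aid) if role == "quantifier"
                     else panel.qualifier(aid))
            traces[(aid, role)] = Chromatogram(
                transition=trans, times=t,
                intensities=g["intensity"].to_numpy(dtype=float),
                injection_id=str(iid))
        injections.append(Injection(injection_id=str(iid), traces=traces,
                                    true_conc_milk={}, in_matrix=True, seed=-1))
    return Batch(injections, manifest={})


def write_manifest(manifest: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)


def read_manifest(path: str | Path) -> dict:
    with open(path) as fh:
        manifest = yaml.safe_load(fh)
    if not isinstance(manifest, dict):
        raise ValueError("manifest must be a mapping")
    return manifest


def write_peak_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, index=False, columns=[c for c in PEAK_TABLE_COLUMNS
                                             if c in table.columns])


def read_peak_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_report(df: pd.DataFrame, path: str | Path) -> None:
    """Tabular report (validation- or occurrence-table shaped)."""
    df.to_csv(path, index=False)
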
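"""Analyte panel: MRM transition definitions and the packaged instrument table.

A targeted scheduled-MRM method monitors two precursor->product transitions per
analyte: the *quantifier* (the more sensitive transition, used for
quantification) and the *qualifier* (used for identity confirmation).  The
expected qualifier/quantifier peak-area ratio ("ion ratio") is part of the
method definition and is stored once per analyte, on the qualifier record.

The packaged panel covers 58 analytes (30 pyrrolizidine alkaloids, 26
pyrrolizidine-alkaloid N-oxides and the two tropane alkaloids atropine and
scopolamine), i.e. 116 transitions.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterator

import pandas as pd

QUANTIFIER = "quantifier"
QUALIFIER = "qualifier"

#: analytes whose determination is only semiquantitative (poor or excessive
#: process recovery); carried as a report flag, never as a numerical change.
SEMIQUANTITATIVE = frozenset({"RlN", "MkN", "MxN"})

#: analytes excluded from the validated cation-exchange clean-up (recoveries
#: below 1%); present in the instrument panel but absent from validation data.
EXCLUDED = frozenset({"AcImN", "AcLyN"})


class PanelError(ValueError):
    """Malformed or inconsistent panel definition."""


@dataclass(frozen=True)
class TransitionDef:
    """One MRM transition of one analyte."""

    analyte_id: str
    analyte_name: str
    role: str  # quantifier | qualifier
    expected_rt: float  # minutes
    precursor_mz: float
    product_mz: float
    expected_ion_ratio: float | None = None  # qualifier records only
    voltages: dict = field(default_factory=dict, compare=False)  # DP/CE/CXP [V]

    def __post_init__(self) -> None:
        if self.role not in (QUANTIFIER, QUALIFIER):
            raise PanelError(f"unknown transition role {self.role!r}")
        if not (self.expected_rt > 0):
            raise PanelError(f"{self.analyte_id}: retention time must be > 0")
        if self.role == QUALIFIER:
            r = self.expected_ion_ratio
            if r is None or not (0 < r <= 2) or not math.isfinite(r):
                raise PanelError(
                    f"{self.analyte_id}: qualifier needs an ion ratio in (0, 2]")


class Panel:
    """An ordered collection of analytes, each with a quantifier/qualifier pair."""

    def __init__(self, transitions: list[TransitionDef]):
        self.transitions = list(transitions)
        by_analyte: dict[str, dict[str, TransitionDef]] = {}
        for t in self.transitions:
            roles = by_analyte.setdefault(t.analyte_id, {})
            if t.role in roles:
                raise PanelError(f"duplicate {t.role} for analyte {t.analyte_id}")
            roles[t.role] = t
        for aid, roles in by_analyte.items():
            if set(roles) != {QUANTIFIER, QUALIFIER}:
                missing = {QUANTIFIER, QUALIFIER} - set(roles)
                raise PanelError(f"analyte {aid} missing {sorted(missing)} record")
        self._by_analyte = by_analyte

    @property
    def analyte_ids(self) -> list[str]:
        seen: list[str] = []
        for t in self.transitions:
            if t.analyte_id not in seen:
                seen.append(t.analyte_id)
        return seen

    def __len__(self) -> int:
        return len(self._by_analyte)

    def __iter__(self) -> Iterator[str]:
        return iter(self.analyte_ids)

    def __contains__(self, analyte_id: str) -> bool:
        return analyte_id in self._by_analyte

    def quantifier(self, analyte_id: str) -> TransitionDef:
        return self._by_analyte[analyte_id][QUANTIFIER]

    def qualifier(self, analyte_id: str) -> TransitionDef:
        return self._by_analyte[analyte_id][QUALIFIER]

    def expected_rt(self, analyte_id: str) -> float:
        return self._by_analyte[analyte_id][QUANTIFIER].expected_rt

    def ion_ratio(self, analyte_id: str) -> float:
        return self._by_analyte[analyte_id][QUALIFIER].expected_ion_ratio

    def subset(self, analyte_ids: list[str]) -> "Panel":
        keep = set(analyte_ids)
        unknown = keep - set(self.analyte_ids)
        if unknown:
            raise PanelError(f"unknown analytes: {sorted(unknown)}")
        return Panel([t for t in self.transitions if t.analyte_id in keep])

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for t in self.transitions:
            rows.append({
                "analyte_id": t.analyte_id, "analyte_name": t.analyte_name,
                "role": t.role, "expected_rt_min": t.expected_rt,
                "precursor_mz": t.precursor_mz, "product_mz": t.product_mz,
                "expected_ion_ratio": t.expected_ion_ratio,
            })
        return pd.DataFrame(rows)


def read_panel(path: str | Path) -> Panel:
    """Read a panel from tabular text (one row per transition)."""
    df = pd.read_csv(path)
    required = {"analyte_id", "role", "expected_rt_min", "precursor_mz",
                "product_mz", "expected_ion_ratio"}
    missing = required - set(df.columns)
    if missing:
        raise PanelError(f"panel file missing columns: {sorted(missing)}")
    transitions = []
    for row in df.itertuples(index=False):
        ratio = getattr(row, "expected_ion_ratio")
        ratio = None if pd.isna(ratio) else float(ratio)
        voltages = {}
        for key, col in (("DP", "dp_v"), ("CE", "ce_v"), ("CXP", "cxp_v")):
            if col in df.columns:
                voltages[key] = getattr(row, col)
        transitions.append(TransitionDef(
            analyte_id=str(row.analyte_id),
            analyte_name=str(getattr(row, "analyte_name", row.analyte_id)),
            role=str(row.role),
            expected_rt=float(row.expected_rt_min),
            precursor_mz=float(row.precursor_mz),
            product_mz=float(row.product_mz),
            expected_ion_ratio=ratio,
            voltages=voltages,
        ))
    return Panel(transitions)


def load_default_panel() -> Panel:
    """The packaged 58-analyte / 116-transition instrument panel."""
    with resources.as_file(
            resources.files("alkaquant.data") / "panel.csv") as p:
        return read_panel(p)


def load_validation_summary() -> pd.DataFrame:
    """Packaged per-analyte method-validation summary.

    Columns: spike recoveries and repeatability (RSD_r, %) at 0.05/0.50/3.00
    ug/L, LOD/LOQ (ug/L milk), calibration R^2, Mandel linear range upper bound
    (ug/L milk) and matrix suppression (%).  Isomer pairs that cannot be
    chromatographically resolved are reported combined (e.g. "IcN/LyN").
    """
    with resources.as_file(
            resources.files("alkaquant.data") / "validation_summary.csv") as p:
        return pd.read_csv(p)
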
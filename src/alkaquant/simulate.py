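"""Synthetic scheduled-MRM chromatogram generator with known ground truth.

Every trace carries a single exponentially-modified-Gaussian (EMG) peak at the
analyte's expected retention time on top of a constant baseline with additive
Gaussian noise (clipped at zero counts).  The EMG was chosen as the minimal
peak shape that reproduces realistic tailing factors (T about 1.5-2.2).

The peak area encodes the full measurement model:

    area = conc_milk x f_prep x recovery x (1 - suppression x in_matrix)
           x response_factor                     [qualifier: x ion ratio]

where f_prep is the sample-preparation concentration factor, recovery the
process recovery of extraction/clean-up and suppression the matrix ion
suppression (so matrix-matched standards and samples are suppressed alike).
Default per-analyte recovery and suppression come from the packaged
validation summary; the absolute response factor and the baseline noise are
an arbitrary instrument scale.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.special import erfcx

from .chromatogram import Chromatogram
from .panel import EXCLUDED, Panel, QUALIFIER, QUANTIFIER, load_validation_summary
from .prep import PrepModel, extract_to_milk, milk_to_extract

#: default sMRM acquisition window width, seconds
WINDOW_WIDTH_S = 120.0
#: sampling density: 3 points per second (>= 20 points across the narrowest peak)
POINTS_PER_SECOND = 3.0


def _expand_combined(table, column: str, scale: float = 1.0) -> dict[str, float]:
    """Per-analyte dict from a validation table whose rows may combine isomers."""
    out: dict[str, float] = {}
    for row in table.itertuples(index=False):
        value = getattr(row, column)
        if value != value:  # NaN: level below LOQ, no datum
            continue
        for aid in str(row.analyte_id).split("/"):
            out[aid] = float(value) * scale
    return out


@dataclass
class MatrixRecoveryModel:
    """Per-analyte signal model: recovery, suppression, response and peak shape.

    ``recovery`` and ``suppression`` are fractions (0.929 recovery means 92.9%);
    ``response_factor`` is peak area (counts x min) per ng/mL of extract
    concentration on the quantifier transition; ``tailing_tau`` is the EMG
    exponential tail constant and ``peak_sigma`` the Gaussian width, both in
    minutes; ``noise_sd`` the baseline noise standard deviation in counts.
    Scalar entries apply to every analyte; dicts override per analyte.
    """

    recovery: float | Mapping[str, float] = 1.0
    suppression: float | Mapping[str, float] = 0.0
    response_factor: float | Mapping[str, float] = 1.0e4
    peak_sigma: float = 0.03
    tailing_tau: float | Mapping[str, float] = 0.018
    noise_sd: float = 1200.0
    baseline_level: float = 10000.0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.peak_sigma <= 0:
            raise ValueError("peak_sigma must be > 0")
        for v in self._values(self.suppression):
            if not (0 <= v < 1):
                raise ValueError("suppression fractions must lie in [0, 1)")
        for v in self._values(self.recovery):
            if not (0 <= v <= 2):
                raise ValueError("recovery fractions must lie in [0, 2]")
        for v in self._values(self.response_factor):
            if not v > 0:
                raise ValueError("response_factor must be > 0")

    @staticmethod
    def _values(x):
        return x.values() if isinstance(x, Mapping) else (x,)

    @staticmethod
    def _get(x, analyte_id: str):
        return float(x[analyte_id]) if isinstance(x, Mapping) else float(x)

    def recovery_of(self, analyte_id: str) -> float:
        return self._get(self.recovery, analyte_id)

    def suppression_of(self, analyte_id: str) -> float:
        return self._get(self.suppression, analyte_id)

    def response_of(self, analyte_id: str) -> float:
        return self._get(self.response_factor, analyte_id)

    def tau_of(self, analyte_id: str) -> float:
        return self._get(self.tailing_tau, analyte_id)

    @classmethod
    def unit(cls, noise_sd: float = 0.0) -> "MatrixRecoveryModel":
        """Ideal instrument: unit recovery, no suppression, optional noise."""
        return cls(recovery=1.0, suppression=0.0, noise_sd=noise_sd,
                   baseline_level=0.0 if noise_sd == 0 else 10000.0)

    @classmethod
    def default(cls) -> "MatrixRecoveryModel":
        """Realistic per-analyte model from the packaged validation summary.

        Recovery uses the mid spike level (0.50 ug/L); suppression the matrix
        suppression column.  Analytes excluded from the validated clean-up are
        given neutral values so the full panel remains simulable.
        """
        table = load_validation_summary()
        recovery = _expand_combined(table, "recovery_pct_0p50", 1 / 100)
        suppression = _expand_combined(table, "matrix_suppression_pct", 1 / 100)
        for aid in EXCLUDED:
            recovery.setdefault(aid, 1.0)
            suppression.setdefault(aid, 0.35)
        return cls(recovery=recovery, suppression=suppression)


def emg_profile(times: np.ndarray, apex_rt: float, sigma: float, tau: float,
                area: float) -> np.ndarray:
    """Exponentially-modified-Gaussian profile with the given integrated area.

    ``apex_rt`` is the Gaussian-component centre (the observed maximum shifts
    right by O(tau) for tailed peaks); ``tau = 0`` degenerates to a Gaussian.
    Evaluated in the numerically stable scaled-complementary-erf form.
    """
    for name, v in (("apex_rt", apex_rt), ("sigma", sigma),
                    ("tau", tau), ("area", area)):
        if not math.isfinite(v):
            raise ValueError(f"{name} must be finite")
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    if tau < 0:
        raise ValueError("tau must be >= 0")
    if area < 0:
        raise ValueError("area must be >= 0")
    t = np.asarray(times, dtype=float)
    if area == 0:
        return np.zeros_like(t)
    z = (t - apex_rt) / sigma
    if tau < 1e-9 * sigma:
        return area / (sigma * math.sqrt(2 * math.pi)) * np.exp(-0.5 * z * z)
    arg = (sigma / tau - z) / math.sqrt(2)
    # erfcx overflows for strongly negative arguments (far right tail); there
    # erfc ~ 2, so the plain exponential form of the tail is exact enough
    out = np.empty_like(z)
    safe = arg > -25.0
    with np.errstate(over="ignore", invalid="ignore"):
        out[safe] = (area / (2 * tau) * np.exp(-0.5 * z[safe] ** 2)
                     * erfcx(arg[safe]))
    tail = ~safe
    out[tail] = (area / tau
                 * np.exp(0.5 * (sigma / tau) ** 2 - z[tail] * sigma / tau))
    return out


@dataclass
class Injection:
    """All traces of one injected sample or standard."""

    injection_id: str
    traces: dict  # (analyte_id, role) -> Chromatogram
    true_conc_milk: dict  # analyte_id -> ug/L in milk equivalents
    in_matrix: bool
    seed: int

    def trace(self, analyte_id: str, role: str = QUANTIFIER) -> Chromatogram:
        return self.traces[(analyte_id, role)]


@dataclass
class Batch:
    """A labelled set of injections plus its ground-truth manifest."""

    injections: list
    manifest: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.injections)

    def select(self, **labels) -> "Batch":
        """Injections whose manifest labels all match (e.g. grid='low')."""
        by_id = {e["injection_id"]: e for e in self.manifest.get("injections", [])}
        keep = [inj for inj in self.injections
                if all(by_id.get(inj.injection_id, {}).get(k) == v
                       for k, v in labels.items())]
        entries = [by_id[i.injection_id] for i in keep if i.injection_id in by_id]
        manifest = dict(self.manifest, injections=entries)
        return Batch(keep, manifest)


def simulate_injection(panel: Panel, conc_map: Mapping[str, float],
                       model: MatrixRecoveryModel,
                       prep: PrepModel = PrepModel(), *,
                       in_matrix: bool = True, seed: int = 0,
                       injection_id: str = "inj") -> Injection:
    """Simulate one injection: one trace per transition of the panel.

    ``conc_map`` gives milk-equivalent concentrations in ug/L; analytes not in
    the map are simulated blank (baseline + noise only).
    """
    unknown = set(conc_map) - set(panel.analyte_ids)
    if unknown:
        raise ValueError(f"analytes not in panel: {sorted(unknown)}")
    for aid, c in conc_map.items():
        if c < 0:
            raise ValueError(f"negative concentration for {aid}")
    rng = np.random.default_rng(seed)
    n = int(round(WINDOW_WIDTH_S * POINTS_PER_SECOND)) + 1
    half = WINDOW_WIDTH_S / 60.0 / 2.0  # minutes
    traces = {}
    for aid in panel.analyte_ids:
        conc_extract = milk_to_extract(conc_map.get(aid, 0.0), prep)
        base_area = (conc_extract * model.recovery_of(aid)
                     * (1.0 - model.suppression_of(aid) * bool(in_matrix))
                     * model.response_of(aid))
        rt = panel.expected_rt(aid)
        times = np.linspace(rt - half, rt + half, n)
        for trans in (panel.quantifier(aid), panel.qualifier(aid)):
            area = base_area
            if trans.role == QUALIFIER:
                area *= panel.ion_ratio(aid)
            y = emg_profile(times, rt, model.peak_sigma, model.tau_of(aid), area)
            y = y + model.baseline_level
            if model.noise_sd > 0:
                y = y + rng.normal(0.0, model.noise_sd, size=n)
            traces[(aid, trans.role)] = Chromatogram(
                transition=trans, times=times,
                intensities=np.clip(y, 0.0, None),
                injection_id=injection_id, window_center=rt,
                window_width_s=WINDOW_WIDTH_S)
    return Injection(injection_id=injection_id, traces=traces,
                     true_conc_milk=dict(conc_map), in_matrix=bool(in_matrix),
                     seed=int(seed))


def _child_seeds(seed: int, n: int) -> list[int]:
    rng = np.random.default_rng(seed)
    return [int(s) for s in rng.integers(0, 2**31 - 1, size=n)]


DEFAULT_CAL_LEVELS = (0.0, 0.1, 0.5, 1.25, 2.5, 5.0, 10.0)  # ng/mL extract


def generate_calibration_batch(panel: Panel,
                               levels: Sequence[float] = DEFAULT_CAL_LEVELS,
                               model: MatrixRecoveryModel | None = None,
                               seed: int = 0, *, n_rep: int = 1,
                               matrix_matched: bool = True,
                               prep: PrepModel = PrepModel()) -> Batch:
    """Calibration standards at the given extract concentrations (ng/mL)."""
    levels = [float(x) for x in levels]
    if any(x < 0 for x in levels):
        raise ValueError("calibration levels must be >= 0")
    if len({x for x in levels if x > 0}) < 3:
        raise ValueError("need at least 3 distinct nonzero levels for regression")
    model = model or MatrixRecoveryModel.default()
    seeds = _child_seeds(seed, len(levels) * n_rep)
    injections, entries = [], []
    k = 0
    for rep in range(n_rep):
        for level in levels:
            conc_milk = extract_to_milk(level, prep)
            iid = f"cal_r{rep + 1}_{level:g}"
            inj = simulate_injection(
                panel, {aid: conc_milk for aid in panel.analyte_ids}, model,
                prep, in_matrix=matrix_matched, seed=seeds[k], injection_id=iid)
            injections.append(inj)
            entries.append({"injection_id": iid, "level_ng_mL": level,
                            "replicate": rep + 1, "seed": seeds[k]})
            k += 1
    manifest = {"design": "calibration", "levels_ng_mL": levels, "n_rep": n_rep,
                "matrix_matched": matrix_matched, "seed": int(seed),
                "prep": vars(prep), "injections": entries}
    return Batch(injections, manifest)


DEFAULT_LOW_GRID = (0.01, 0.12, 12)   # ng/mL extract: start, stop, levels
DEFAULT_HIGH_GRID = (0.2, 1.2, 11)


def generate_limits_series(panel: Panel,
                           model: MatrixRecoveryModel | None = None,
                           seed: int = 0, *,
                           low_grid: tuple = DEFAULT_LOW_GRID,
                           high_grid: tuple = DEFAULT_HIGH_GRID,
                           prep: PrepModel = PrepModel()) -> Batch:
    """Low-level equidistant series in blank milk extract, for LOD/LOQ regression.

    Two grids are produced (12 levels 0.01-0.12 and 11 levels 0.2-1.2 ng/mL by
    default); the limits stage picks the grid adaptively per analyte.
    """
    grids = {"low": np.linspace(*low_grid), "high": np.linspace(*high_grid)}
    model = model or MatrixRecoveryModel.default()
    n_total = sum(len(g) for g in grids.values())
    seeds = _child_seeds(seed, n_total)
    injections, entries = [], []
    k = 0
    for grid_name, grid in grids.items():
        for level in grid:
            conc_milk = extract_to_milk(float(level), prep)
            iid = f"lim_{grid_name}_{level:.4g}"
            inj = simulate_injection(
                panel, {aid: conc_milk for aid in panel.analyte_ids}, model,
                prep, in_matrix=True, seed=seeds[k], injection_id=iid)
            injections.append(inj)
            entries.append({"injection_id": iid, "grid": grid_name,
                            "level_ng_mL": float(level), "seed": seeds[k]})
            k += 1
    manifest = {"design": "limits", "seed": int(seed), "prep": vars(prep),
                "low_grid_ng_mL": [float(x) for x in grids["low"]],
                "high_grid_ng_mL": [float(x) for x in grids["high"]],
                "injections": entries}
    return Batch(injections, manifest)


DEFAULT_SPIKE_LEVELS = (0.05, 0.50, 3.00)  # ug/L in milk


def generate_spike_experiment(panel: Panel,
                              spike_levels: Sequence[float] = DEFAULT_SPIKE_LEVELS,
                              n_rep: int = 5,
                              model: MatrixRecoveryModel | None = None,
                              seed: int = 0, *,
                              loq_map: Mapping[str, float] | None = None,
                              prep: PrepModel = PrepModel()) -> Batch:
    """Recovery/repeatability experiment: spiked milk, n_rep replicates per level.

    The manifest flags, per level, the analytes whose LOQ exceeds the spike
    level (no recovery is evaluable there).  ``loq_map`` defaults to the
    packaged validation summary.
    """
    if n_rep < 2:
        raise ValueError("need at least 2 replicates")
    model = model or MatrixRecoveryModel.default()
    if loq_map is None:
        loq_map = _expand_combined(load_validation_summary(), "loq_ugL")
    seeds = _child_seeds(seed, len(spike_levels) * n_rep)
    injections, entries = [], []
    k = 0
    for level in spike_levels:
        below_loq = sorted(aid for aid in panel.analyte_ids
                           if loq_map.get(aid, 0.0) > level)
        for rep in range(n_rep):
            iid = f"spike_{level:g}_r{rep + 1}"
            inj = simulate_injection(
                panel, {aid: float(level) for aid in panel.analyte_ids}, model,
                prep, in_matrix=True, seed=seeds[k], injection_id=iid)
            injections.append(inj)
            entries.append({"injection_id": iid, "level_ugL": float(level),
                            "replicate": rep + 1, "seed": seeds[k],
                            "below_loq_analytes": below_loq})
            k += 1
    manifest = {"design": "spike", "levels_ugL": [float(x) for x in spike_levels],
                "n_rep": int(n_rep), "seed": int(seed), "prep": vars(prep),
                "injections": entries}
    return Batch(injections, manifest)
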
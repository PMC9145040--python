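"""The method-validation battery: bias, precision, carryover, LOD/LOQ,
interference, matrix effects, stability and dilution integrity.

Bias is the relative deviation of the grand-mean back-calculated
concentration from nominal.  Precision follows the one-way ANOVA
decomposition of a balanced runs x replicates design: the pooled within-run
CV is sqrt(MS_within) / grand mean, and the between-run (intermediate)
precision adds the between-run variance component
max(0, (MS_between - MS_within) / n_replicates), so it can never fall below
the within-run CV.  A "literal" mode (SD of run means over the grand mean)
is kept selectable for comparison with spreadsheets that compute it that
way.

Matrix effect compares post-extraction-spiked samples (set B) with neat
standards (set A) as 100 x mean(B)/mean(A); processed-sample stability
compares re-injection peak areas against day zero; carryover and
interference look for target peaks above the LOD where none should be.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .method_model import MethodConfig, MrmMethod, ToleranceSet
from .peaks import Chromatogram, detect_peak
from .quant import CalibrationFit, back_calculate, compute_par, fit_calibration
from .synthetic_data import (
    BatchDesign,
    SimulationParams,
    make_calibration_slots,
    make_qc_slots,
    simulate_batch,
    simulate_chromatogram,
)

#: Default LOD search grid (ng/mL).
LOD_GRID: tuple[float, ...] = (0.05, 0.1, 0.2, 0.3, 0.5, 1.0)


class ValidationError(ValueError):
    pass


# -- bias ------------------------------------------------------------------


def bias_pct(measurements: Sequence[float], nominal: float) -> float:
    """Relative deviation (%) of the grand mean from the nominal value."""
    if len(measurements) == 0:
        raise ValidationError("empty measurement list")
    if nominal <= 0:
        raise ValidationError("nominal concentration must be positive")
    return 100.0 * (float(np.mean(measurements)) - nominal) / nominal


# -- precision -------------------------------------------------------------


@dataclass(frozen=True)
class ReplicateTable:
    """Balanced runs x replicates measurements for one analyte and level."""

    analyte: str
    qc_level: float
    data: np.ndarray  # shape (runs, replicates)

    def __post_init__(self) -> None:
        arr = np.asarray(self.data, dtype=float)
        object.__setattr__(self, "data", arr)
        if arr.ndim != 2 or arr.shape[0] < 1 or arr.shape[1] < 1:
            raise ValidationError("replicate table must be a runs x replicates matrix")


@dataclass(frozen=True)
class PrecisionResult:
    within_run_cv_pct: float
    between_run_cv_pct: float
    per_run: pd.DataFrame  # columns: run, mean, sd, cv_pct


def precision(table: ReplicateTable, mode: str = "anova") -> PrecisionResult:
    """Within-run and between-run %CV for a balanced replicate design."""
    if mode not in {"anova", "literal"}:
        raise ValidationError("mode must be 'anova' or 'literal'")
    data = table.data
    k, n = data.shape
    if k < 2 or n < 2:
        raise ValidationError("need at least 2 runs and 2 replicates")
    grand = float(data.mean())
    if grand == 0:
        raise ValidationError("grand mean is zero")
    run_means = data.mean(axis=1)
    run_sds = data.std(axis=1, ddof=1)
    per_run = pd.DataFrame(
        {
            "run": np.arange(1, k + 1),
            "mean": run_means,
            "sd": run_sds,
            "cv_pct": 100.0 * run_sds / run_means,
        }
    )
    ms_within = float(np.mean(run_sds**2))
    within_cv = 100.0 * np.sqrt(ms_within) / grand
    if mode == "anova":
        ms_between = n * float(np.var(run_means, ddof=1))
        sigma_b2 = max(0.0, (ms_between - ms_within) / n)
        between_cv = 100.0 * np.sqrt(ms_within + sigma_b2) / grand
    else:
        between_cv = 100.0 * float(np.std(run_means, ddof=1)) / grand
    return PrecisionResult(float(within_cv), float(between_cv), per_run)


# -- carryover & interference ---------------------------------------------


def _apparent_concentration(
    chrom: Chromatogram,
    fit: CalibrationFit,
    expected_rt: float,
    window: float,
    is_area_ref: float,
) -> float:
    """Back-convert a (possibly absent) blank peak to ng/mL using a
    reference internal-standard area from the same batch.

    The intercept is deliberately ignored: a blank carries no calibration
    baseline, so the area is divided by the sensitivity (slope) alone —
    otherwise a slightly negative fitted intercept would manufacture an
    apparent concentration out of nothing.
    """
    peak = detect_peak(chrom, expected_rt, window)
    if not peak.found:
        return 0.0
    par = compute_par(peak.area, is_area_ref)
    return max(0.0, par / fit.slope)


def carryover_check(
    blanks_after_top: Mapping[str, Iterable[Chromatogram]],
    lods: Mapping[str, float],
    fits: Mapping[str, CalibrationFit],
    method: MrmMethod,
    is_area_ref: float,
) -> dict[str, bool]:
    """Per-analyte carryover verdict from blanks injected after the top
    calibrator: pass when every blank's apparent concentration stays below
    the analyte's LOD.

    ``blanks_after_top`` maps analyte -> quantifier-channel traces of the
    blank injections.
    """
    tol = method.config.tolerances
    out: dict[str, bool] = {}
    for analyte, chroms in blanks_after_top.items():
        if analyte not in lods:
            raise ValidationError(f"missing LOD for {analyte}")
        rec = method.quantifier_for(analyte)
        ok = True
        for chrom in chroms:
            conc = _apparent_concentration(
                chrom, fits[analyte], rec.rt_min, tol.rt_window_min, is_area_ref
            )
            if conc >= lods[analyte]:
                ok = False
        out[analyte] = ok
    return out


def interference_screen(
    blank_panels: Mapping[str, Iterable[Chromatogram]],
    lods: Mapping[str, float],
    fits: Mapping[str, CalibrationFit],
    method: MrmMethod,
    is_area_ref: float,
) -> pd.DataFrame:
    """Flag false-positive target signals in analyte-free panels.

    ``blank_panels`` maps panel name (drug-free matrix, IS-only, drug
    panel, ...) to the target-channel traces acquired on it.  Any target
    peak whose apparent concentration reaches the LOD is flagged.
    """
    tol = method.config.tolerances
    rows = []
    for panel, chroms in blank_panels.items():
        for chrom in chroms:
            rec = method.quantifier_for(chrom.analyte)
            conc = _apparent_concentration(
                chrom, fits[chrom.analyte], rec.rt_min, tol.rt_window_min, is_area_ref
            )
            rows.append(
                {
                    "panel": panel,
                    "analyte": chrom.analyte,
                    "apparent_ng_ml": conc,
                    "flagged": conc >= lods.get(chrom.analyte, np.inf),
                }
            )
    return pd.DataFrame(rows)


# -- LOD / LOQ -------------------------------------------------------------


def estimate_lod(
    series: Mapping[float, Sequence[float]], sn_lod: float = 3.0
) -> float:
    """Lowest tested concentration whose mean S/N meets the detection
    threshold, requiring every higher tested level to pass as well.

    ``series`` maps concentration -> replicate S/N values.  Raises when no
    level passes; when every level passes the lowest tested one is
    returned.
    """
    if len(series) < 2:
        raise ValidationError("need at least two tested concentrations")
    concs = sorted(series)
    passing = {c: float(np.mean(series[c])) >= sn_lod for c in concs}
    if not any(passing.values()):
        raise ValidationError("no concentration reaches the detection S/N threshold")
    failing = [c for c in concs if not passing[c]]
    cutoff = max(failing) if failing else -np.inf
    candidates = [c for c in concs if c > cutoff]
    return float(min(candidates))


def assign_loq(config: MethodConfig, lod: float | None = None) -> float:
    """The lowest calibrator is assigned as the LOQ of the method."""
    loq = float(min(config.calibration_levels))
    if lod is not None and loq <= lod:
        warnings.warn(
            f"assigned LOQ {loq} ng/mL does not exceed the estimated LOD {lod} ng/mL",
            stacklevel=2,
        )
    return loq


def simulate_lod_series(
    method: MrmMethod,
    params: SimulationParams,
    analyte: str,
    *,
    grid: Sequence[float] = LOD_GRID,
    replicates: int = 3,
) -> dict[float, list[float]]:
    """Measure replicate S/N values on simulated low-level injections."""
    rec = method.quantifier_for(analyte)
    tol = method.config.tolerances
    series: dict[float, list[float]] = {}
    for conc in grid:
        vals = []
        for rep in range(replicates):
            chrom = simulate_chromatogram(
                rec,
                conc,
                params,
                sample_id=f"LOD-{analyte}-{conc:g}-{rep}",
            )
            peak = detect_peak(chrom, rec.rt_min, tol.rt_window_min)
            vals.append(peak.sn)
        series[float(conc)] = vals
    return series


# -- matrix effects, stability, dilution ----------------------------------


def matrix_effects(
    set_a_areas: Sequence[float],
    set_b_areas: Sequence[float],
    tolerances: ToleranceSet | None = None,
) -> tuple[float, float, bool]:
    """Matrix effect as 100 x mean(B)/mean(A) with its between-sample CV.

    Values below 100 % indicate ion suppression, above 100 % enhancement.
    Pass requires the deviation from 100 % within the configured limit and
    the CV of set B within its limit.
    """
    tol = tolerances or ToleranceSet()
    a = np.asarray(set_a_areas, dtype=float)
    b = np.asarray(set_b_areas, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValidationError("need at least two samples per set")
    if a.mean() == 0:
        raise ValidationError("set A mean area is zero")
    me = 100.0 * b.mean() / a.mean()
    ratios = b / a.mean()
    me_cv = 100.0 * float(np.std(ratios, ddof=1) / np.mean(ratios))
    ok = abs(me - 100.0) <= tol.me_deviation_limit_pct and me_cv <= tol.me_cv_limit_pct
    return float(me), float(me_cv), bool(ok)


def stability_assess(
    day0_areas: Sequence[float],
    t_areas: Sequence[float],
    limit_pct: float = 20.0,
) -> tuple[float, float, bool]:
    """Percent loss of mean peak area versus day zero, with the RSD of the
    re-injection set; stable while |loss| stays within the bias limit."""
    d0 = np.asarray(day0_areas, dtype=float)
    dt = np.asarray(t_areas, dtype=float)
    if d0.size < 2 or dt.size < 2:
        raise ValidationError("need at least two replicates per time point")
    if d0.mean() == 0:
        raise ValidationError("day-zero mean area is zero")
    loss = 100.0 * (dt.mean() - d0.mean()) / d0.mean()
    rsd = 100.0 * float(np.std(dt, ddof=1) / dt.mean())
    return float(loss), rsd, bool(abs(loss) <= limit_pct)


def dilution_integrity(
    measured_diluted: float,
    nominal: float,
    df: float,
    limit_pct: float = 20.0,
) -> tuple[float, bool]:
    """Bias of a dilution control after correcting for the dilution factor."""
    if df <= 1:
        raise ValidationError("dilution factor must exceed 1")
    if nominal <= 0:
        raise ValidationError("nominal concentration must be positive")
    bias = 100.0 * (df * measured_diluted - nominal) / nominal
    return float(bias), bool(abs(bias) <= limit_pct)


# -- fixture summaries -----------------------------------------------------


@dataclass(frozen=True)
class BiasPrecisionSummary:
    min_bias_pct: float
    max_bias_pct: float
    max_within_cv_by_level: dict[float, float]
    max_between_cv_by_level: dict[float, float]


def summarize_bias_precision(table: pd.DataFrame) -> BiasPrecisionSummary:
    """Min/max grand bias and per-level precision maxima of a replicate
    summary table (columns as in the packaged bias/precision fixture)."""
    by_level = table.groupby("nominal_ng_ml")
    return BiasPrecisionSummary(
        min_bias_pct=float(table["bias_pct"].min()),
        max_bias_pct=float(table["bias_pct"].max()),
        max_within_cv_by_level={
            float(k): float(v) for k, v in by_level["within_run_cv"].max().items()
        },
        max_between_cv_by_level={
            float(k): float(v) for k, v in by_level["between_run_cv"].max().items()
        },
    )


def summarize_stability(table: pd.DataFrame, limit_pct: float = 20.0) -> pd.DataFrame:
    """Stable/unstable verdict per analyte and time point from a stability
    summary table (columns as in the packaged stability fixture)."""
    loss_cols = [c for c in table.columns if c.startswith("loss_")]
    out = table[["analyte"]].copy()
    for col in loss_cols:
        out[col.replace("loss_", "stable_")] = table[col].abs() <= limit_pct
    out["all_stable"] = out.drop(columns="analyte").all(axis=1)
    return out


# -- simulated bias/precision experiment ----------------------------------


def run_bias_precision_study(
    method: MrmMethod,
    params: SimulationParams,
    *,
    analytes: Sequence[str] | None = None,
    mode: str = "anova",
) -> pd.DataFrame:
    """Simulate the full QC experiment (runs x replicates x QC levels, each
    run with its own calibration curve) and summarise bias and precision.

    Returns one row per analyte x QC level with grand mean, bias %, pooled
    within-run CV, between-run CV and the pass verdict at the configured
    bias/CV limit.
    """
    cfg = method.config
    tol = cfg.tolerances
    targets = list(analytes) if analytes is not None else method.quantifiable_analytes
    is_rec = method.internal_standard

    measured: dict[tuple[str, float], np.ndarray] = {
        (a, lvl): np.zeros((cfg.runs, cfg.replicates_per_run))
        for a in targets
        for lvl in cfg.qc_levels
    }
    for run in range(cfg.runs):
        slots = make_calibration_slots(method, run_index=run, start_order=0)
        qc = make_qc_slots(method, run_index=run, start_order=len(slots))
        design = BatchDesign(slots=slots + qc, seed=params.seed)
        chroms = simulate_batch(design, method, params, channels="quantifier")
        areas = _quantifier_areas(chroms, method, targets, is_rec)
        fits = {}
        for analyte in targets:
            levels = cfg.levels_for(method.role_of(analyte))
            pts = []
            for i, level in enumerate(levels):
                sid = f"CAL{i + 1}-R{run}"
                pts.append((level, compute_par(areas[sid][analyte], areas[sid]["__is__"])))
            fits[analyte] = fit_calibration(
                pts, analyte=analyte, r2_min=tol.r2_min
            )
        for level in cfg.qc_levels:
            for rep in range(cfg.replicates_per_run):
                sid = f"QC{level:g}-R{run}-{rep + 1}"
                for analyte in targets:
                    par = compute_par(areas[sid][analyte], areas[sid]["__is__"])
                    res = back_calculate(par, fits[analyte])
                    measured[(analyte, level)][run, rep] = res.concentration

    rows = []
    for (analyte, level), data in measured.items():
        table = ReplicateTable(analyte, level, data)
        prec = precision(table, mode=mode)
        b = bias_pct(data.ravel(), level)
        rows.append(
            {
                "analyte": analyte,
                "qc_level": level,
                "grand_mean": float(data.mean()),
                "bias_pct": b,
                "within_run_cv": prec.within_run_cv_pct,
                "between_run_cv": prec.between_run_cv_pct,
                "passed": (
                    abs(b) <= tol.bias_cv_limit_pct
                    and prec.within_run_cv_pct <= tol.bias_cv_limit_pct
                    and prec.between_run_cv_pct <= tol.bias_cv_limit_pct
                ),
            }
        )
    return pd.DataFrame(rows)


def _quantifier_areas(
    chroms: Mapping[str, list[Chromatogram]],
    method: MrmMethod,
    targets: Sequence[str],
    is_rec,
) -> dict[str, dict[str, float]]:
    """Integrate quantifier and IS peaks for every sample in a batch."""
    tol = method.config.tolerances
    wanted = {(a, method.quantifier_for(a).product_mz): a for a in targets}
    wanted[(is_rec.analyte, is_rec.product_mz)] = "__is__"
    rt = {a: method.quantifier_for(a).rt_min for a in targets}
    rt["__is__"] = is_rec.rt_min
    out: dict[str, dict[str, float]] = {}
    for sid, traces in chroms.items():
        areas: dict[str, float] = {}
        for chrom in traces:
            key = (chrom.analyte, chrom.product_mz)
            if key not in wanted:
                continue
            name = wanted[key]
            peak = detect_peak(chrom, rt[name], tol.rt_window_min)
            areas[name] = peak.area if peak.found else 0.0
        out[sid] = areas
    return out
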
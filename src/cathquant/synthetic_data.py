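"""Synthetic MRM chromatogram batches with a realistic error structure.

No instrument data accompany the published panel, so this module generates
traces carrying the statistical structure the validation design assumes:

* proportional response — quantifier peak area = response factor x
  concentration, with the qualifier channel scaled by the analyte's
  expected ion ratio before noise;
* multiplicative, mean-one lognormal within-run variation per injection and
  a shared lognormal between-run factor per run;
* an optional per-sample matrix-effect multiplier applied to analyte
  channels only (the internal standard is unaffected, so set-A/set-B
  comparisons remain meaningful);
* optional carryover, adding a fraction of the previous injection's peak
  area on the same channel to the next injection;
* additive Gaussian baseline noise on every trace point.

Peaks are pure Gaussians (sigma 0.03 min by default).  The default
response factors are taken from the packaged calibration-slope table so
that simulated peak-area ratios reproduce the published slopes; the
absolute scale (internal-standard area) and the baseline noise level are
package choices, documented in the methods note.

Randomness follows a strict contract: one master seed, with child streams
derived per (sample, analyte, channel), so neither insertion order nor the
set of simulated channels changes any individual trace.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .method_model import KIND_QUALIFIER, MrmMethod, ROLE_IS, ROLE_SCREEN, TransitionRecord
from .peaks import Chromatogram

SAMPLE_KINDS = frozenset(
    {
        "calibrator",
        "zero",
        "blank",
        "qc",
        "unknown",
        "me_setA",
        "me_setB",
        "stability",
        "dilution_control",
    }
)

#: Nominal internal-standard peak area (intensity*min) at 500 ng/mL.
DEFAULT_IS_AREA = 20000.0
#: Qualifier/quantifier ratio used for channels with no published ratio
#: (metabolite sub-method and screen qualifiers).
DEFAULT_SYNTHETIC_ION_RATIO = 0.5
#: Response factor for the qualitative screen channels (area per ng/mL).
DEFAULT_SCREEN_RESPONSE = 1000.0


class SimulationError(ValueError):
    pass


@dataclass
class SimulationParams:
    """Noise model and response factors for batch simulation."""

    response_factors: dict[str, float]
    ion_ratios: dict[str, float] = field(default_factory=dict)
    peak_sigma_min: float = 0.03
    baseline_noise_sd: float = 600.0
    within_run_cv: float = 0.05
    between_run_cv: float = 0.03
    me_multipliers: dict[str, float] = field(default_factory=dict)
    carryover_fraction: float = 0.0
    sampling_interval_min: float = 0.01
    trace_halfwidth_min: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if any(v <= 0 for v in self.response_factors.values()):
            raise SimulationError("response factors must be positive")
        if self.within_run_cv < 0 or self.between_run_cv < 0:
            raise SimulationError("noise CVs must be non-negative")
        if not (0 <= self.carryover_fraction < 1):
            raise SimulationError("carryover_fraction must lie in [0, 1)")
        if self.sampling_interval_min >= self.peak_sigma_min:
            raise SimulationError("sampling interval must be below the peak sigma")


def default_params(
    method: MrmMethod,
    *,
    screen: MrmMethod | None = None,
    is_area: float = DEFAULT_IS_AREA,
    seed: int = 0,
    **overrides,
) -> SimulationParams:
    """Build simulation parameters matching the packaged calibration slopes.

    Analyte response factors are ``slope x is_area`` so a noise-free batch
    reproduces the published peak-area-ratio slopes exactly; the internal
    standard's factor makes its area ``is_area`` at the spiking
    concentration.  Screen channels get a flat synthetic response factor.
    """
    from .fixtures import load_calibration_reference

    table = load_calibration_reference().set_index("analyte")
    rf: dict[str, float] = {}
    ratios: dict[str, float] = {}
    for analyte in method.quantifiable_analytes:
        rf[analyte] = float(table.loc[analyte, "slope"]) * is_area
        qual = method.qualifier_for(analyte)
        ratio = qual.expected_ion_ratio if qual is not None else None
        ratios[analyte] = ratio if ratio is not None else DEFAULT_SYNTHETIC_ION_RATIO
    is_rec = method.internal_standard
    rf[is_rec.analyte] = is_area / method.config.is_concentration
    if screen is not None:
        for analyte in screen.analytes({ROLE_SCREEN}):
            rf[analyte] = DEFAULT_SCREEN_RESPONSE
            ratios[analyte] = DEFAULT_SYNTHETIC_ION_RATIO
    return SimulationParams(response_factors=rf, ion_ratios=ratios, seed=seed, **overrides)


@dataclass(frozen=True)
class SampleSlot:
    """One injection in a batch."""

    sample_id: str
    sample_kind: str
    true_concentrations: Mapping[str, float] = field(default_factory=dict)
    dilution_factor: float = 1.0
    run_index: int = 0
    injection_order: int = 0
    reinjection_hour: int = 0

    def __post_init__(self) -> None:
        if self.sample_kind not in SAMPLE_KINDS:
            raise SimulationError(f"unknown sample kind {self.sample_kind!r}")
        if self.dilution_factor < 1:
            raise SimulationError("dilution_factor must be >= 1")
        if any(c < 0 for c in self.true_concentrations.values()):
            raise SimulationError("negative concentration")
        if self.sample_kind in {"blank", "zero"} and any(
            c > 0 for c in self.true_concentrations.values()
        ):
            raise SimulationError(f"{self.sample_kind} samples must contain no analyte")


@dataclass
class BatchDesign:
    slots: list[SampleSlot]
    seed: int = 0

    def by_kind(self, kind: str) -> list[SampleSlot]:
        return [s for s in self.slots if s.sample_kind == kind]

    @property
    def unknowns(self) -> list[SampleSlot]:
        return self.by_kind("unknown")


# -- RNG plumbing ----------------------------------------------------------


def _crc(text: str) -> int:
    return zlib.crc32(text.encode("utf-8"))


def _channel_rng(seed: int, sample_id: str, analyte: str, product_mz: float) -> np.random.Generator:
    entropy = [seed & 0x7FFFFFFF, _crc(sample_id), _crc(analyte), int(round(product_mz * 1000))]
    return np.random.default_rng(np.random.SeedSequence(entropy))


def _run_effect(seed: int, run_index: int, between_run_cv: float) -> float:
    if between_run_cv == 0:
        return 1.0
    rng = np.random.default_rng(np.random.SeedSequence([seed & 0x7FFFFFFF, 0x52554E, run_index]))
    return float(_mean_one_lognormal(rng, between_run_cv))


def _mean_one_lognormal(rng: np.random.Generator, cv: float) -> float:
    if cv == 0:
        return 1.0
    s2 = np.log1p(cv * cv)
    return float(np.exp(rng.normal(-0.5 * s2, np.sqrt(s2))))


# -- trace generation ------------------------------------------------------


def _gaussian_trace(
    rng: np.random.Generator,
    record: TransitionRecord,
    area: float,
    params: SimulationParams,
    sample_id: str,
) -> Chromatogram:
    hw, dt = params.trace_halfwidth_min, params.sampling_interval_min
    n = int(round(2 * hw / dt)) + 1
    t = record.rt_min - hw + dt * np.arange(n)
    y = np.zeros(n)
    if area > 0:
        sigma = params.peak_sigma_min
        height = area / (sigma * np.sqrt(2 * np.pi))
        y = height * np.exp(-0.5 * ((t - record.rt_min) / sigma) ** 2)
    if params.baseline_noise_sd > 0:
        y = y + rng.normal(0.0, params.baseline_noise_sd, size=n)
    return Chromatogram(sample_id, record.analyte, record.product_mz, t, y)


def _simulate_channel(
    record: TransitionRecord,
    true_conc: float,
    params: SimulationParams,
    run_effect: float,
    sample_id: str,
    me: float,
    carryover_area: float,
) -> tuple[Chromatogram, float]:
    if true_conc < 0:
        raise SimulationError("negative concentration")
    rng = _channel_rng(params.seed, sample_id, record.analyte, record.product_mz)
    rf = params.response_factors.get(record.analyte)
    if rf is None:
        raise SimulationError(f"no response factor for {record.analyte}")
    area = rf * true_conc * run_effect
    if record.role != ROLE_IS:
        area *= me
    if record.kind == KIND_QUALIFIER:
        ratio = record.expected_ion_ratio
        if ratio is None:
            ratio = params.ion_ratios.get(record.analyte, DEFAULT_SYNTHETIC_ION_RATIO)
        area *= ratio
    if area > 0:
        area *= _mean_one_lognormal(rng, params.within_run_cv)
    area += carryover_area
    chrom = _gaussian_trace(rng, record, area, params, sample_id)
    return chrom, area


def simulate_chromatogram(
    record: TransitionRecord,
    true_conc: float,
    params: SimulationParams,
    run_effect: float = 1.0,
    seed: int | None = None,
    *,
    sample_id: str = "sample",
    me_multiplier: float = 1.0,
    carryover_area: float = 0.0,
) -> Chromatogram:
    """Simulate a single MRM channel trace for one injection.

    Deterministic for a fixed seed; ``seed`` overrides ``params.seed`` when
    given.  Raises on negative concentration.
    """
    if seed is not None:
        params = SimulationParams(**{**params.__dict__, "seed": seed})
    chrom, _ = _simulate_channel(
        record, true_conc, params, run_effect, sample_id, me_multiplier, carryover_area
    )
    return chrom


def simulate_batch(
    design: BatchDesign,
    method: MrmMethod,
    params: SimulationParams,
    *,
    channels: str = "all",
) -> dict[str, list[Chromatogram]]:
    """Simulate every monitored channel for every injection of a batch.

    ``channels`` may be ``"all"`` or ``"quantifier"`` (quantifier + IS only,
    cheaper when qualifier traces are not needed).  The internal standard is
    spiked at the configured concentration into every non-blank sample;
    carryover propagates along ``injection_order`` per channel.
    """
    if channels not in {"all", "quantifier"}:
        raise SimulationError("channels must be 'all' or 'quantifier'")
    known = {r.analyte for r in method.transitions}
    for slot in design.slots:
        missing = set(slot.true_concentrations) - known
        if missing:
            raise SimulationError(f"{slot.sample_id}: analytes not in method: {sorted(missing)}")

    records = [
        r
        for r in method.transitions
        if channels == "all" or r.kind != KIND_QUALIFIER or r.role == ROLE_IS
    ]
    run_effects = {
        ri: _run_effect(params.seed, ri, params.between_run_cv)
        for ri in {s.run_index for s in design.slots}
    }
    prev_area: dict[tuple[str, float], float] = {}
    out: dict[str, list[Chromatogram]] = {}
    for slot in sorted(design.slots, key=lambda s: s.injection_order):
        me = params.me_multipliers.get(slot.sample_id, 1.0)
        chroms: list[Chromatogram] = []
        for rec in records:
            if rec.role == ROLE_IS:
                conc = 0.0 if slot.sample_kind == "blank" else method.config.is_concentration
            else:
                conc = slot.true_concentrations.get(rec.analyte, 0.0) / slot.dilution_factor
            key = (rec.analyte, rec.product_mz)
            carry = params.carryover_fraction * prev_area.get(key, 0.0)
            chrom, area = _simulate_channel(
                rec, conc, params, run_effects[slot.run_index], slot.sample_id, me, carry
            )
            prev_area[key] = area
            chroms.append(chrom)
        out[slot.sample_id] = chroms
    return out


# -- study designs ---------------------------------------------------------


def make_calibration_slots(
    method: MrmMethod,
    *,
    run_index: int = 0,
    start_order: int = 0,
    include_zero_blank: bool = True,
) -> list[SampleSlot]:
    """Calibrator slots covering every configured level once, plus zero/blank.

    Each calibrator carries all analytes at the level of its slot; parents
    and metabolites follow their respective level lists (which differ in
    the seventh level).
    """
    cfg = method.config
    slots: list[SampleSlot] = []
    order = start_order
    n_levels = len(cfg.calibration_levels)
    for i in range(n_levels):
        concs = {
            a: float(cfg.levels_for(method.role_of(a))[i])
            for a in method.quantifiable_analytes
        }
        slots.append(
            SampleSlot(
                sample_id=f"CAL{i + 1}-R{run_index}",
                sample_kind="calibrator",
                true_concentrations=concs,
                run_index=run_index,
                injection_order=order,
            )
        )
        order += 1
    if include_zero_blank:
        slots.append(
            SampleSlot(
                sample_id=f"ZERO-R{run_index}",
                sample_kind="zero",
                run_index=run_index,
                injection_order=order,
            )
        )
        slots.append(
            SampleSlot(
                sample_id=f"BLANK-R{run_index}",
                sample_kind="blank",
                run_index=run_index,
                injection_order=order + 1,
            )
        )
    return slots


def make_qc_slots(
    method: MrmMethod,
    *,
    run_index: int,
    start_order: int,
    replicates: int | None = None,
) -> list[SampleSlot]:
    """QC slots at every configured level, ``replicates`` injections each."""
    cfg = method.config
    reps = replicates if replicates is not None else cfg.replicates_per_run
    slots = []
    order = start_order
    for level in cfg.qc_levels:
        for rep in range(reps):
            concs = {a: float(level) for a in method.quantifiable_analytes}
            slots.append(
                SampleSlot(
                    sample_id=f"QC{level:g}-R{run_index}-{rep + 1}",
                    sample_kind="qc",
                    true_concentrations=concs,
                    run_index=run_index,
                    injection_order=order,
                )
            )
            order += 1
    return slots


#: Ground truth for the three positive case samples (ng/mL); the
#: dihydro-mephedrone level in sample 49 sits above five times the upper
#: limit of quantification so it stays censored even after a 1:5 dilution.
STUDY_TRUTH: dict[str, dict[str, float]] = {
    "S19": {"Dihydro-mephedrone": 172.0, "Methamphetamine": 20.0},
    "S34": {
        "N-ethylpentylone": 52.0,
        "Dihydro-N-ethylpentylone": 1378.0,
        "Methamphetamine": 2000.0,
    },
    "S49": {
        "Mephedrone": 1537.0,
        "Dihydro-mephedrone": 7500.0,
        "Methamphetamine": 2000.0,
        "MDMA": 30.0,
    },
}


def make_study_batch(seed: int = 0) -> BatchDesign:
    """The 52-unknown case-sample batch: three positives, 49 target-free.

    Samples S19, S34 and S49 carry the reported concentrations of the three
    positive case samples (plus their qualitative stimulant findings); all
    other samples contain no target analyte.
    """
    slots = []
    for i in range(1, 53):
        sid = f"S{i:02d}"
        slots.append(
            SampleSlot(
                sample_id=sid,
                sample_kind="unknown",
                true_concentrations=dict(STUDY_TRUTH.get(sid, {})),
                run_index=0,
                injection_order=i,
            )
        )
    return BatchDesign(slots=slots, seed=seed)


# -- CSV interchange -------------------------------------------------------


def write_chromatograms(chroms: Iterable[Chromatogram], path) -> None:
    """Long-format CSV: sample_id, analyte, product_mz, time_min, intensity."""
    frames = [
        pd.DataFrame(
            {
                "sample_id": c.sample_id,
                "analyte": c.analyte,
                "product_mz": c.product_mz,
                "time_min": c.times,
                "intensity": c.intensities,
            }
        )
        for c in chroms
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_chromatograms(path) -> list[Chromatogram]:
    df = pd.read_csv(path)
    out = []
    for (sid, analyte, mz), grp in df.groupby(
        ["sample_id", "analyte", "product_mz"], sort=False
    ):
        out.append(
            Chromatogram(
                str(sid),
                str(analyte),
                float(mz),
                grp["time_min"].to_numpy(),
                grp["intensity"].to_numpy(),
            )
        )
    return out


def write_manifest(design: BatchDesign, path) -> None:
    rows = []
    for s in design.slots:
        row = {
            "sample_id": s.sample_id,
            "sample_kind": s.sample_kind,
            "dilution_factor": s.dilution_factor,
            "run_index": s.run_index,
            "injection_order": s.injection_order,
            "reinjection_hour": s.reinjection_hour,
        }
        for analyte, conc in s.true_concentrations.items():
            row[f"conc:{analyte}"] = conc
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_manifest(path, seed: int = 0) -> BatchDesign:
    df = pd.read_csv(path)
    slots = []
    conc_cols = [c for c in df.columns if c.startswith("conc:")]
    for _, row in df.iterrows():
        concs = {
            c[len("conc:") :]: float(row[c]) for c in conc_cols if pd.notna(row[c])
        }
        slots.append(
            SampleSlot(
                sample_id=str(row["sample_id"]),
                sample_kind=str(row["sample_kind"]),
                true_concentrations=concs,
                dilution_factor=float(row["dilution_factor"]),
                run_index=int(row["run_index"]),
                injection_order=int(row["injection_order"]),
                reinjection_hour=int(row["reinjection_hour"]),
            )
        )
    return BatchDesign(slots=slots, seed=seed)
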
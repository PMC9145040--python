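"""Data model and I/O for a targeted MRM quantification method.

A method is a transition table (one row per monitored precursor -> product
channel), a set of confirmation/validation tolerances, and a batch
configuration (calibration levels, QC levels, run layout).  This module is
the single source of truth for every constant the rest of the pipeline
consumes: simulation, peak picking, calibration, the validation battery and
identity confirmation all read their parameters from here.

Units are fixed throughout the package: concentrations in ng/mL, time in
minutes, m/z in Thomson, peak areas in arbitrary intensity*minutes.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from typing import Iterable, Sequence

ROLE_PARENT = "parent"
ROLE_METABOLITE = "metabolite"
ROLE_IS = "internal_standard"
ROLE_SCREEN = "qualitative_screen"
ROLES = frozenset({ROLE_PARENT, ROLE_METABOLITE, ROLE_IS, ROLE_SCREEN})

KIND_QUANTIFIER = "quantifier"
KIND_QUALIFIER = "qualifier"
KINDS = frozenset({KIND_QUANTIFIER, KIND_QUALIFIER})

#: Relative ion-ratio tolerance bands as ``(upper_bound, tolerance_pct)``
#: pairs partitioning (0, 1]: a deviation of up to ``tolerance_pct`` percent
#: from the expected qualifier/quantifier ratio is accepted within the band
#: whose upper bound is the first one >= the expected ratio.  Wider windows
#: for weaker relative ions follow standard forensic confirmation practice.
DEFAULT_ION_RATIO_BANDS: tuple[tuple[float, float], ...] = (
    (0.10, 50.0),
    (0.20, 30.0),
    (0.50, 25.0),
    (1.00, 20.0),
)


class MethodError(ValueError):
    """Raised when a transition table violates the method invariants."""


@dataclass(frozen=True)
class TransitionRecord:
    """One monitored MRM channel (a single row of the transition table).

    ``expected_ion_ratio`` is the qualifier/quantifier peak-area ratio in
    (0, 1]; it is only meaningful for analytes monitored with two
    transitions.  ``confirmation_only`` marks metabolite qualifier channels
    that belong to the confirmatory sub-method and are never used for
    quantification.
    """

    analyte: str
    role: str
    rt_min: float
    precursor_mz: float
    product_mz: float
    kind: str
    cone_voltage: float
    collision_energy: float
    dwell_time: float
    expected_ion_ratio: float | None = None
    confirmation_only: bool = False

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise MethodError(f"unknown role {self.role!r} for {self.analyte}")
        if self.kind not in KINDS:
            raise MethodError(f"unknown transition kind {self.kind!r} for {self.analyte}")
        if not self.rt_min > 0:
            raise MethodError(f"{self.analyte}: retention time must be positive")
        if not (self.precursor_mz > self.product_mz > 0):
            raise MethodError(
                f"{self.analyte}: need precursor m/z > product m/z > 0, got "
                f"{self.precursor_mz} -> {self.product_mz}"
            )
        if not self.dwell_time > 0:
            raise MethodError(f"{self.analyte}: dwell time must be positive")
        if self.expected_ion_ratio is not None and not (0 < self.expected_ion_ratio <= 1):
            raise MethodError(
                f"{self.analyte}: ion ratio {self.expected_ion_ratio} outside (0, 1]"
            )


@dataclass(frozen=True)
class ToleranceSet:
    """Acceptance tolerances for confirmation and validation.

    Defaults follow common forensic-toxicology method-validation criteria:
    relative retention time within +/-2.5 %, bias and precision within
    +/-20 %, matrix-effect deviation <= 25 % with CV <= 15 %, S/N >= 3 for
    detection and >= 10 for quantification, calibration R^2 >= 0.990.
    """

    rrt_tol_pct: float = 2.5
    ion_ratio_bands: tuple[tuple[float, float], ...] = DEFAULT_ION_RATIO_BANDS
    bias_cv_limit_pct: float = 20.0
    me_deviation_limit_pct: float = 25.0
    me_cv_limit_pct: float = 15.0
    sn_lod: float = 3.0
    sn_loq: float = 10.0
    r2_min: float = 0.990
    rt_window_min: float = 0.15

    def __post_init__(self) -> None:
        for name in (
            "rrt_tol_pct",
            "bias_cv_limit_pct",
            "me_deviation_limit_pct",
            "me_cv_limit_pct",
            "sn_lod",
            "sn_loq",
            "r2_min",
            "rt_window_min",
        ):
            if not getattr(self, name) > 0:
                raise MethodError(f"tolerance {name} must be strictly positive")
        uppers = [u for u, _ in self.ion_ratio_bands]
        if uppers != sorted(uppers) or uppers[-1] != 1.0 or min(uppers) <= 0:
            raise MethodError("ion_ratio_bands must partition (0, 1] with increasing bounds")
        if any(t <= 0 for _, t in self.ion_ratio_bands):
            raise MethodError("ion_ratio_bands tolerances must be strictly positive")


def ion_ratio_tolerance(
    expected_ratio: float,
    bands: Sequence[tuple[float, float]] = DEFAULT_ION_RATIO_BANDS,
) -> float:
    """Permitted relative ion-ratio deviation (%) for an expected ratio.

    A step function, non-increasing in ``expected_ratio``: weaker relative
    qualifier ions are granted wider windows.
    """
    if not (0 < expected_ratio <= 1):
        raise MethodError(f"expected ion ratio {expected_ratio} outside (0, 1]")
    for upper, tol in bands:
        if expected_ratio <= upper:
            return tol
    raise MethodError("ion_ratio_bands do not cover (0, 1]")  # pragma: no cover


#: Non-zero calibrator concentrations (ng/mL).  Metabolites swap the seventh
#: level from 500 to 750 ng/mL.
PARENT_LEVELS: tuple[float, ...] = (1, 5, 10, 20, 50, 150, 500, 1000)
METABOLITE_LEVELS: tuple[float, ...] = (1, 5, 10, 20, 50, 150, 750, 1000)


@dataclass(frozen=True)
class MethodConfig:
    """Batch/run configuration: calibration design, QC design, tolerances."""

    calibration_levels: tuple[float, ...] = PARENT_LEVELS
    metabolite_calibration_levels: tuple[float, ...] = METABOLITE_LEVELS
    qc_levels: tuple[float, ...] = (30.0, 400.0, 800.0)
    is_concentration: float = 500.0
    runs: int = 5
    replicates_per_run: int = 3
    tolerances: ToleranceSet = field(default_factory=ToleranceSet)
    # Chromatographic gradient / source settings: carried verbatim, never
    # interpreted by any computation.
    lc_metadata: str = ""

    def __post_init__(self) -> None:
        for levels in (self.calibration_levels, self.metabolite_calibration_levels):
            if list(levels) != sorted(levels) or len(set(levels)) != len(levels):
                raise MethodError("calibration levels must be strictly increasing")
        if self.runs < 1 or self.replicates_per_run < 1:
            raise MethodError("runs and replicates_per_run must be >= 1")

    @property
    def loq(self) -> float:
        """Lowest calibrator = assigned limit of quantification."""
        return min(self.calibration_levels)

    @property
    def uloq(self) -> float:
        return max(self.calibration_levels)

    def levels_for(self, role: str) -> tuple[float, ...]:
        if role == ROLE_METABOLITE:
            return self.metabolite_calibration_levels
        return self.calibration_levels


@dataclass
class MrmMethod:
    """A validated transition table plus its batch configuration."""

    transitions: list[TransitionRecord]
    config: MethodConfig = field(default_factory=MethodConfig)

    def __post_init__(self) -> None:
        _validate_transitions(self.transitions)

    # -- lookups -----------------------------------------------------------
    def analytes(self, roles: Iterable[str] | None = None) -> list[str]:
        """Analyte names in table order, optionally filtered by role."""
        wanted = set(roles) if roles is not None else None
        seen: list[str] = []
        for rec in self.transitions:
            if wanted is not None and rec.role not in wanted:
                continue
            if rec.analyte not in seen:
                seen.append(rec.analyte)
        return seen

    @property
    def quantifiable_analytes(self) -> list[str]:
        return self.analytes({ROLE_PARENT, ROLE_METABOLITE})

    @property
    def internal_standard(self) -> TransitionRecord:
        return next(r for r in self.transitions if r.role == ROLE_IS)

    def quantifier_for(self, analyte: str) -> TransitionRecord:
        return next(
            r
            for r in self.transitions
            if r.analyte == analyte and r.kind == KIND_QUANTIFIER
        )

    def qualifier_for(self, analyte: str) -> TransitionRecord | None:
        return next(
            (
                r
                for r in self.transitions
                if r.analyte == analyte and r.kind == KIND_QUALIFIER
            ),
            None,
        )

    def role_of(self, analyte: str) -> str:
        return self.quantifier_for(analyte).role


def _validate_transitions(records: Sequence[TransitionRecord]) -> None:
    if not records:
        raise MethodError("no transitions")
    seen: set[tuple[str, float]] = set()
    for rec in records:
        key = (rec.analyte, rec.product_mz)
        if key in seen:
            raise MethodError(f"duplicate transition {rec.analyte} -> {rec.product_mz}")
        seen.add(key)
    by_analyte: dict[str, list[TransitionRecord]] = {}
    for rec in records:
        by_analyte.setdefault(rec.analyte, []).append(rec)
    for analyte, recs in by_analyte.items():
        n_quant = sum(r.kind == KIND_QUANTIFIER for r in recs)
        if n_quant != 1:
            raise MethodError(
                f"{analyte}: expected exactly one quantifier transition, found {n_quant}"
            )
    n_is = sum(r.role == ROLE_IS for r in records)
    if n_is == 0:
        raise MethodError("no internal standard")
    if n_is > 1:
        raise MethodError("more than one internal standard")


# -- CSV I/O ---------------------------------------------------------------

CSV_COLUMNS = (
    "analyte",
    "role",
    "rt_min",
    "precursor_mz",
    "product_mz",
    "kind",
    "cone_v",
    "ce_ev",
    "dwell_s",
    "ion_ratio",
)


def read_method(source, config: MethodConfig | None = None) -> MrmMethod:
    """Read a transition-table CSV and validate it into an :class:`MrmMethod`.

    ``source`` is a path or an open text handle.  The CSV must carry the
    header ``analyte,role,rt_min,precursor_mz,product_mz,kind,cone_v,ce_ev,
    dwell_s,ion_ratio`` (ion_ratio may be empty).  Metabolite qualifier rows
    are flagged confirmation-only: they belong to the confirmatory
    sub-method and are never quantified.
    """
    if hasattr(source, "read"):
        rows = list(csv.DictReader(source))
    else:
        with open(source, newline="", encoding="utf-8") as fh:
            rows = list(csv.DictReader(fh))
    if not rows:
        raise MethodError("no transitions")
    records = []
    for row in rows:
        ratio_txt = (row.get("ion_ratio") or "").strip()
        role = row["role"].strip()
        kind = row["kind"].strip()
        records.append(
            TransitionRecord(
                analyte=row["analyte"].strip(),
                role=role,
                rt_min=float(row["rt_min"]),
                precursor_mz=float(row["precursor_mz"]),
                product_mz=float(row["product_mz"]),
                kind=kind,
                cone_voltage=float(row["cone_v"]),
                collision_energy=float(row["ce_ev"]),
                dwell_time=float(row["dwell_s"]),
                expected_ion_ratio=float(ratio_txt) if ratio_txt else None,
                confirmation_only=(role == ROLE_METABOLITE and kind == KIND_QUALIFIER),
            )
        )
    # an ion ratio only makes sense when two transitions are monitored
    count: dict[str, int] = {}
    for rec in records:
        count[rec.analyte] = count.get(rec.analyte, 0) + 1
    for rec in records:
        if rec.expected_ion_ratio is not None and count[rec.analyte] < 2:
            raise MethodError(
                f"{rec.analyte}: ion ratio given but only one transition monitored"
            )
    return MrmMethod(records, config or MethodConfig())


def write_method(method: MrmMethod, target) -> None:
    """Write the transition table back to CSV (inverse of :func:`read_method`)."""

    def _write(fh) -> None:
        writer = csv.writer(fh)
        writer.writerow(CSV_COLUMNS)
        for rec in method.transitions:
            writer.writerow(
                [
                    rec.analyte,
                    rec.role,
                    format(rec.rt_min, "g"),
                    format(rec.precursor_mz, "g"),
                    format(rec.product_mz, "g"),
                    rec.kind,
                    format(rec.cone_voltage, "g"),
                    format(rec.collision_energy, "g"),
                    format(rec.dwell_time, "g"),
                    "" if rec.expected_ion_ratio is None else format(rec.expected_ion_ratio, "g"),
                ]
            )

    if hasattr(target, "write"):
        _write(target)
    else:
        with open(target, "w", newline="", encoding="utf-8") as fh:
            _write(fh)


def merge_methods(primary: MrmMethod, extra: MrmMethod) -> MrmMethod:
    """Combine two methods sharing at most one internal standard.

    Used to append the qualitative stimulant-screen channels to the
    quantitative panel; duplicate channels (e.g. the shared IS) are dropped.
    """
    seen = {(r.analyte, r.product_mz) for r in primary.transitions}
    combined = list(primary.transitions)
    for rec in extra.transitions:
        if (rec.analyte, rec.product_mz) in seen:
            continue
        if rec.role == ROLE_IS and any(r.role == ROLE_IS for r in combined):
            continue
        combined.append(rec)
    return MrmMethod(combined, primary.config)
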
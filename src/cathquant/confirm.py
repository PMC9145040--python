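"""Forensic identity confirmation and the qualitative stimulant screen.

A target finding above the LOQ is confirmed only when all criteria hold:
both monitored product ions give peaks; the relative retention time (RRT,
analyte over internal standard) matches the reference within +/-2.5 %; and
the qualifier/quantifier area ratio matches the expected ratio within the
band tolerance for that ratio.  Metabolites are confirmed through the
confirmatory sub-method's qualifier channel.

Reference RRT and ion ratios are preferably established from spiked
calibrator/QC injections of the same batch; the transition table's static
values serve as fallback.

The qualitative screen calls classical stimulants (methamphetamine, MDMA)
detected when both product-ion channels show coincident peaks above three
times the noise, graded +, ++ or +++ by quantifier peak area.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

from .method_model import MrmMethod, ToleranceSet, ion_ratio_tolerance
from .peaks import Chromatogram, Peak, detect_peak
from .quant import QuantResult

#: Quantifier-area thresholds for the semiquantitative +/++/+++ grades.
#: The source tables print the grades without thresholds, so these are
#: package defaults expressed on the simulated-area scale.
DEFAULT_GRADE_THRESHOLDS: tuple[float, float] = (1e5, 1e6)
#: Maximum apex-time mismatch between the two screen channels (minutes).
SCREEN_COELUTION_TOL_MIN = 0.05


class ConfirmError(ValueError):
    pass


def compute_rrt(rt_analyte: float, rt_is: float) -> float:
    """Relative retention time: analyte apex over internal-standard apex."""
    if rt_analyte <= 0 or rt_is <= 0:
        raise ConfirmError("retention times must be positive")
    return rt_analyte / rt_is


def check_ion_ratio(
    qualifier_area: float,
    quantifier_area: float,
    expected_ratio: float,
    bands: Sequence[tuple[float, float]] | None = None,
) -> tuple[float, float, bool]:
    """Measured ion ratio (less intense over more intense peak area), its
    relative deviation from the expected ratio, and the band verdict."""
    if quantifier_area <= 0:
        raise ConfirmError("quantifier area must be positive")
    lo, hi = sorted((abs(qualifier_area), abs(quantifier_area)))
    measured = lo / hi if hi > 0 else 0.0
    dev_pct = 100.0 * abs(measured - expected_ratio) / expected_ratio
    tol = (
        ion_ratio_tolerance(expected_ratio, bands)
        if bands is not None
        else ion_ratio_tolerance(expected_ratio)
    )
    return measured, dev_pct, dev_pct <= tol


@dataclass(frozen=True)
class ConfirmationResult:
    analyte: str
    both_ions_present: bool
    rrt_measured: float | None
    rrt_reference: float
    rrt_dev_pct: float | None
    ion_ratio_measured: float | None
    ion_ratio_dev_pct: float | None
    confirmed: bool


def confirm_identity(
    quant: QuantResult,
    quantifier_peak: Peak,
    qualifier_peak: Peak | None,
    is_peak: Peak,
    *,
    expected_ratio: float,
    rrt_reference: float,
    tolerances: ToleranceSet,
    loq: float,
) -> ConfirmationResult:
    """Apply the full confirmation conjunction to one quantified analyte.

    ``expected_ratio`` and ``rrt_reference`` should come from spiked
    calibrator/QC injections of the same batch where available.  A
    concentration at or below the LOQ is never confirmed; censored
    above-range results count as exceeding the LOQ.
    """
    if not quantifier_peak.found:
        raise ConfirmError("quantifier peak not found; nothing to confirm")
    if rrt_reference <= 0:
        raise ConfirmError("reference RRT unavailable")

    both = bool(qualifier_peak is not None and qualifier_peak.found)
    rrt_measured = compute_rrt(quantifier_peak.apex_time, is_peak.apex_time)
    rrt_dev = 100.0 * abs(rrt_measured - rrt_reference) / rrt_reference
    rrt_ok = rrt_dev <= tolerances.rrt_tol_pct

    ratio_measured = ratio_dev = None
    ratio_ok = False
    if both:
        ratio_measured, ratio_dev, ratio_ok = check_ion_ratio(
            qualifier_peak.area,
            quantifier_peak.area,
            expected_ratio,
            tolerances.ion_ratio_bands,
        )

    above_loq = quant.quantifiable and (
        quant.censored or quant.concentration > loq
    )
    confirmed = both and rrt_ok and ratio_ok and above_loq
    return ConfirmationResult(
        analyte=quant.analyte,
        both_ions_present=both,
        rrt_measured=rrt_measured,
        rrt_reference=rrt_reference,
        rrt_dev_pct=rrt_dev,
        ion_ratio_measured=ratio_measured,
        ion_ratio_dev_pct=ratio_dev,
        confirmed=bool(confirmed),
    )


def qualitative_screen(
    chroms: Mapping[str, tuple[Chromatogram, Chromatogram]],
    screen: MrmMethod,
    *,
    grade_thresholds: tuple[float, float] = DEFAULT_GRADE_THRESHOLDS,
) -> dict[str, str]:
    """Grade screened stimulants from their two product-ion channels.

    ``chroms`` maps analyte -> (quantifier trace, qualifier trace).  An
    analyte is called detected when both channels show found peaks at a
    common retention time; the grade is + below the first area threshold,
    +++ above the second, ++ in between.  Undetected analytes are absent
    from the returned map.
    """
    low, high = grade_thresholds
    tol = screen.config.tolerances
    out: dict[str, str] = {}
    for analyte, (quant_chrom, qual_chrom) in chroms.items():
        rec = screen.quantifier_for(analyte)
        p_quant = detect_peak(quant_chrom, rec.rt_min, tol.rt_window_min)
        p_qual = detect_peak(qual_chrom, rec.rt_min, tol.rt_window_min)
        if not (p_quant.found and p_qual.found):
            continue
        if abs(p_quant.apex_time - p_qual.apex_time) > SCREEN_COELUTION_TOL_MIN:
            continue
        if p_quant.area >= high:
            out[analyte] = "+++"
        elif p_quant.area > low:
            out[analyte] = "++"
        else:
            out[analyte] = "+"
    return out
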
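"""Loaders for the packaged reference tables.

The package ships plain-CSV transcriptions of the published method tables:
the MRM transition panel, per-analyte calibration parameters (slope,
intercept, R^2, LOD), the 5-run x 3-replicate bias/precision summary, the
processed-sample stability summary, and the case-sample findings.  The
qualitative stimulant-screen transition set is synthetic in part: the
literature gives its mass transitions but no retention times or voltages,
so those fields hold invented placeholder values used only by the
simulator.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .method_model import MethodConfig, MrmMethod, read_method

_PKG = "cathquant"


def _fixture(name: str):
    return resources.files(_PKG).joinpath("fixtures").joinpath(name)


def load_method(config: MethodConfig | None = None) -> MrmMethod:
    """The 26-analyte quantitative panel plus the MDPV-d8 internal standard."""
    with _fixture("table1_transitions.csv").open("r", encoding="utf-8") as fh:
        return read_method(fh, config)


def load_screen_method(config: MethodConfig | None = None) -> MrmMethod:
    """Qualitative methamphetamine/MDMA screen channels (synthetic Rt values)."""
    with _fixture("screen_transitions.csv").open("r", encoding="utf-8") as fh:
        return read_method(fh, config)


def load_calibration_reference() -> pd.DataFrame:
    """Per-analyte calibration slope/intercept/R^2 and LOD/LOQ reference values."""
    with _fixture("table2_calibration.csv").open("r", encoding="utf-8") as fh:
        return pd.read_csv(fh)


def load_bias_precision() -> pd.DataFrame:
    """Replicate bias/precision summary (5 runs x 3 replicates, 3 QC levels)."""
    with _fixture("table3_bias_precision.csv").open("r", encoding="utf-8") as fh:
        return pd.read_csv(fh)


def load_stability() -> pd.DataFrame:
    """Processed-sample stability (% loss and RSD at 24/48/72 h, two QC levels)."""
    with _fixture("table4_stability.csv").open("r", encoding="utf-8") as fh:
        return pd.read_csv(fh)


def load_study_findings() -> pd.DataFrame:
    """Reported findings for the three positive case samples."""
    with _fixture("table5_findings.csv").open("r", encoding="utf-8") as fh:
        return pd.read_csv(fh)
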
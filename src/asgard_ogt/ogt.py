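"""OGT inference: calibration correlation, proxy conversion, lifestyle classes.

The optimal GDP-binding temperature of EF-1A/EF-Tu correlates strongly with
the organism's optimal growth temperature (OGT) across prokaryotes, so the
fitted binding optimum is taken directly as the OGT proxy — no regression
adjustment by default. A Pearson correlation over organisms with known OGT
quantifies the calibration; thermal lifestyle is classified by configurable
thresholds (mesophile < 45 deg C <= moderate thermophile < 80 deg C <=
hyperthermophile).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy import stats

from .bootstrap import BootstrapResult

MESOPHILE_MAX = 45.0
MODERATE_THERMOPHILE_MAX = 80.0

LIFESTYLES = ("mesophile", "moderate_thermophile", "hyperthermophile")

_TEMP_RANGE = (-5.0, 120.0)


@dataclass(frozen=True)
class CalibrationPoint:
    """One organism with known OGT and measured binding optimum (deg C)."""

    organism: str
    ogt: float
    binding_optimum: float

    def __post_init__(self) -> None:
        for name in ("ogt", "binding_optimum"):
            v = getattr(self, name)
            if not np.isfinite(v) or not _TEMP_RANGE[0] <= v <= _TEMP_RANGE[1]:
                raise ValueError(f"{name}={v} outside the plausible range {_TEMP_RANGE}")


@dataclass(frozen=True)
class CalibrationResult:
    """Pearson correlation between OGT and binding optimum."""

    r: float
    n: int

    def __post_init__(self) -> None:
        if abs(self.r) > 1.0 + 1e-12:
            raise ValueError("|r| cannot exceed 1")
        if self.n < 3:
            raise ValueError("calibration needs at least 3 points")


@dataclass(frozen=True)
class OgtEstimate:
    """OGT point estimate with CI and thermal lifestyle for one tree node."""

    label: str
    ogt: float
    ci_lower: float
    ci_upper: float
    lifestyle: str

    def __post_init__(self) -> None:
        if self.lifestyle not in LIFESTYLES:
            raise ValueError(f"lifestyle must be one of {LIFESTYLES}")
        # Note: ci_lower <= ogt <= ci_upper is NOT enforced — percentile
        # bootstrap intervals need not contain the full-data point estimate.


def pearson_r(points: Sequence[CalibrationPoint]) -> CalibrationResult:
    """Product-moment correlation of (ogt, binding_optimum) pairs."""
    if len(points) < 3:
        raise ValueError("need at least 3 calibration points")
    x = np.array([p.ogt for p in points], dtype=float)
    y = np.array([p.binding_optimum for p in points], dtype=float)
    if np.var(x) == 0 or np.var(y) == 0:
        raise ValueError("calibration coordinates must both have nonzero variance")
    r = stats.pearsonr(x, y).statistic
    return CalibrationResult(r=float(r), n=len(points))


def linear_calibration(points: Sequence[CalibrationPoint]) -> Tuple[float, float]:
    """Least-squares line mapping binding optimum -> OGT: returns (slope, intercept).

    Optional alternative to the identity proxy; off by default in the pipeline.
    """
    if len(points) < 3:
        raise ValueError("need at least 3 calibration points")
    x = np.array([p.binding_optimum for p in points], dtype=float)
    y = np.array([p.ogt for p in points], dtype=float)
    res = stats.linregress(x, y)
    return float(res.slope), float(res.intercept)


def classify_lifestyle(
    ogt: float,
    mesophile_max: float = MESOPHILE_MAX,
    moderate_max: float = MODERATE_THERMOPHILE_MAX,
) -> str:
    """Step classification: mesophile < mesophile_max <= moderate < moderate_max <= hyper."""
    if not np.isfinite(ogt):
        raise ValueError("ogt must be finite")
    if ogt < mesophile_max:
        return "mesophile"
    if ogt < moderate_max:
        return "moderate_thermophile"
    return "hyperthermophile"


def infer_ogt(
    label: str,
    peak: BootstrapResult,
    calibration: Optional[Tuple[float, float]] = None,
    mesophile_max: float = MESOPHILE_MAX,
    moderate_max: float = MODERATE_THERMOPHILE_MAX,
) -> OgtEstimate:
    """OGT estimate from a bootstrapped binding optimum.

    By default the binding optimum is used as the OGT unchanged (identity
    proxy) and the bootstrap CI is carried through. When ``calibration`` is a
    (slope, intercept) pair from :func:`linear_calibration`, the point and the
    interval bounds are mapped through that line instead.
    """
    def conv(t: float) -> float:
        if calibration is None:
            return t
        slope, intercept = calibration
        return slope * t + intercept

    ogt = conv(peak.point_estimate)
    lo, hi = sorted((conv(peak.ci_lower), conv(peak.ci_upper)))
    return OgtEstimate(
        label=label,
        ogt=ogt,
        ci_lower=lo,
        ci_upper=hi,
        lifestyle=classify_lifestyle(ogt, mesophile_max, moderate_max),
    )


def read_calibration_table(path: Union[str, Path]) -> list[CalibrationPoint]:
    """Read a TSV/CSV calibration table: organism, ogt_C, binding_optimum_C."""
    sep = "\t" if str(path).endswith((".tsv", ".tab", ".txt")) else ","
    df = pd.read_csv(path, sep=sep)
    required = {"organism", "ogt_C", "binding_optimum_C"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"calibration table missing columns: {sorted(missing)}")
    return [
        CalibrationPoint(str(r.organism), float(r.ogt_C), float(r.binding_optimum_C))
        for r in df.itertuples()
    ]


# Calibration pairs as printed in the study's statistical methods
# (organism, known OGT, measured binding optimum), deg C.
METHODS_CALIBRATION = (
    CalibrationPoint("MK-D1", 20.0, 19.9),
    CalibrationPoint("S_cerevisiae", 28.0, 32.2),
    CalibrationPoint("H_sapiens", 37.0, 33.5),
    CalibrationPoint("E_coli", 37.0, 43.4),
)

# The same four organisms with the binding optima reported in the results
# narrative (these differ from the methods table for three organisms).
RESULTS_CALIBRATION = (
    CalibrationPoint("MK-D1", 20.0, 20.5),
    CalibrationPoint("S_cerevisiae", 28.0, 34.6),
    CalibrationPoint("H_sapiens", 37.0, 40.1),
    CalibrationPoint("E_coli", 37.0, 40.2),
)
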
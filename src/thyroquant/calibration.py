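"""Isotope-dilution calibration: 1/x-weighted regression, back-calculation,
lower limits of quantification and detection.

Calibration plots the analyte/internal-standard peak-area ratio against
the nominal spiked concentration and fits a straight line by weighted
least squares with weights ``w_i = 1/x_i`` (or equal weights).  The 1/x
weighting matters because MRM area noise is predominantly proportional:
an unweighted fit lets the highest calibrators dominate and produces
gross relative errors at the bottom of a range spanning three to four
decades, whereas 1/x weighting keeps relative errors roughly uniform.

The weighted coefficient of determination is defined as
``r2 = 1 - SSE_w / SST_w`` with the weighted mean in the total sum of
squares; with equal weights this reduces exactly to the ordinary
Pearson r2.

LLOQ is the lowest calibrator level whose precision and accuracy are
within 20% and whose signal-to-noise exceeds 10:1; LLOD the lowest level
with S/N above 6:1.  Both are reported as not-available when endogenous
background analyte in the blank matrix sits at or above the candidate
level.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "CalibrationPoint",
    "CalibrationCurve",
    "BackCalcResult",
    "LevelStats",
    "Tolerances",
    "weighted_linear_fit",
    "back_calculate",
    "determine_limits",
    "flag_background",
    "calibration_level_stats",
]


class SingularFitError(ValueError):
    """Calibration cannot be fitted (all x equal, or zero slope inverse)."""


@dataclass(frozen=True)
class CalibrationPoint:
    """One calibrator observation: nominal conc (nM) and area ratio."""

    nominal_conc: float
    area_ratio: float
    replicate_id: int = 1
    s_n: float = math.inf

    def __post_init__(self) -> None:
        if self.nominal_conc <= 0:
            raise ValueError("nominal_conc must be positive")
        if self.area_ratio < 0:
            raise ValueError("area_ratio must be >= 0")


@dataclass(frozen=True)
class CalibrationCurve:
    analyte: str
    slope: float
    intercept: float
    r_squared: float
    weighting: str  # "1/x" | "none"
    range_nm: tuple[float, float]
    lloq: float | None = None
    llod: float | None = None
    background_flag: float | None = None

    def __post_init__(self) -> None:
        if not (-1e-12 <= self.r_squared <= 1 + 1e-12):
            raise ValueError("r_squared must be in [0, 1]")
        if self.lloq is not None and self.llod is not None and self.lloq < self.llod:
            raise ValueError("LLOQ must be >= LLOD")


@dataclass(frozen=True)
class BackCalcResult:
    """Back-calculated concentration with quality flags."""

    conc_nm: float
    clipped: bool = False       # negative raw value reported as 0
    extrapolated: bool = False  # outside the fitted range

    def __float__(self) -> float:
        return self.conc_nm


def weighted_linear_fit(
    points: list[CalibrationPoint] | pd.DataFrame,
    weighting: str = "1/x",
    analyte: str = "",
) -> CalibrationCurve:
    """Fit area ratio vs concentration by (1/x-)weighted least squares.

    ``points`` may be a list of :class:`CalibrationPoint` or a DataFrame
    with ``nominal_conc`` and ``area_ratio`` columns.  Requires at least
    three distinct concentrations.
    """
    if weighting not in ("1/x", "none"):
        raise ValueError(f"unknown weighting {weighting!r}")
    if isinstance(points, pd.DataFrame):
        x = points["nominal_conc"].to_numpy(dtype=float)
        y = points["area_ratio"].to_numpy(dtype=float)
    else:
        x = np.array([p.nominal_conc for p in points], dtype=float)
        y = np.array([p.area_ratio for p in points], dtype=float)
    if np.unique(x).size < 3:
        raise SingularFitError(
            f"need >= 3 distinct concentrations, got {np.unique(x).size}"
        )
    w = 1.0 / x if weighting == "1/x" else np.ones_like(x)
    model = sm.WLS(y, sm.add_constant(x), weights=w).fit()
    intercept, slope = float(model.params[0]), float(model.params[1])

    resid = y - (intercept + slope * x)
    sse = float(np.sum(w * resid**2))
    ybar_w = float(np.sum(w * y) / np.sum(w))
    sst = float(np.sum(w * (y - ybar_w) ** 2))
    r2 = 1.0 - sse / sst if sst > 0 else 1.0
    return CalibrationCurve(
        analyte=analyte,
        slope=slope,
        intercept=intercept,
        r_squared=min(max(r2, 0.0), 1.0),
        weighting=weighting,
        range_nm=(float(np.min(x)), float(np.max(x))),
    )


def back_calculate(curve: CalibrationCurve, area_ratio: float) -> BackCalcResult:
    """Invert the calibration line: ``(ratio - intercept) / slope``.

    Negative raw concentrations are reported as 0 with ``clipped=True``;
    values outside the fitted range are flagged ``extrapolated``.
    """
    if curve.slope == 0:
        raise SingularFitError("slope is zero; cannot back-calculate")
    raw = (area_ratio - curve.intercept) / curve.slope
    clipped = raw < 0
    conc = max(raw, 0.0)
    lo, hi = curve.range_nm
    extrapolated = not (lo <= conc <= hi)
    return BackCalcResult(conc, clipped=clipped, extrapolated=extrapolated)


@dataclass(frozen=True)
class LevelStats:
    """Per-calibrator-level diagnostics feeding the LLOQ/LLOD decision."""

    nominal_conc: float
    cv_pct: float
    accuracy_pct: float
    s_n: float


@dataclass(frozen=True)
class Tolerances:
    """Acceptance tolerances for the lower limits."""

    max_dev_pct: float = 20.0  # on both CV and |accuracy - 100|
    lloq_sn: float = 10.0
    llod_sn: float = 6.0


def determine_limits(
    level_stats: list[LevelStats],
    tolerances: Tolerances = Tolerances(),
    background_conc: float | None = None,
) -> tuple[float | None, float | None]:
    """(LLOQ, LLOD) from per-level diagnostics.

    LLOQ: lowest level with CV and accuracy deviation within
    ``max_dev_pct`` and S/N above ``lloq_sn``.  LLOD: lowest level with
    S/N above ``llod_sn``.  Either is ``None`` when no level passes, or
    when endogenous background sits at or above the candidate level
    (quantification of a spiked amount on top of comparable background
    is unreliable).
    """
    if not level_stats:
        raise ValueError("level_stats must be non-empty")
    stats = sorted(level_stats, key=lambda s: s.nominal_conc)

    lloq = None
    for s in stats:
        if (s.cv_pct <= tolerances.max_dev_pct
                and abs(s.accuracy_pct - 100.0) <= tolerances.max_dev_pct
                and s.s_n > tolerances.lloq_sn):
            lloq = s.nominal_conc
            break
    llod = None
    for s in stats:
        if s.s_n > tolerances.llod_sn:
            llod = s.nominal_conc
            break
    if background_conc is not None:
        if lloq is not None and background_conc >= lloq:
            lloq = None
        if llod is not None and background_conc >= llod:
            llod = None
    return lloq, llod


def flag_background(
    blank_concs: list[float] | np.ndarray, llod_candidate: float = 0.0
) -> float | None:
    """Mean blank concentration when it exceeds the LLOD candidate.

    Returns ``None`` for clean blanks — the analyte then has no
    endogenous background and the lower limits stand as determined.
    """
    blanks = np.asarray(blank_concs, dtype=float)
    if blanks.size == 0:
        raise ValueError("need at least one blank")
    mean = float(np.mean(blanks))
    return mean if mean > llod_candidate else None


def calibration_level_stats(
    points: list[CalibrationPoint] | pd.DataFrame,
    curve: CalibrationCurve,
) -> list[LevelStats]:
    """Back-calculate every calibrator and summarise per level.

    CV is only defined with replicates; single-replicate levels report
    CV 0.  S/N per level is the minimum over replicates (worst case).
    """
    if isinstance(points, pd.DataFrame):
        df = points[["nominal_conc", "area_ratio"]].copy()
        df["s_n"] = points["s_n"] if "s_n" in points else math.inf
    else:
        df = pd.DataFrame({
            "nominal_conc": [p.nominal_conc for p in points],
            "area_ratio": [p.area_ratio for p in points],
            "s_n": [p.s_n for p in points],
        })
    df["conc"] = [back_calculate(curve, r).conc_nm for r in df["area_ratio"]]
    out = []
    for nominal, grp in df.groupby("nominal_conc", sort=True):
        mean = float(grp["conc"].mean())
        cv = (100.0 * float(grp["conc"].std(ddof=1)) / mean
              if len(grp) > 1 and mean != 0 else 0.0)
        acc = 100.0 * mean / nominal
        out.append(LevelStats(
            nominal_conc=float(nominal),
            cv_pct=cv,
            accuracy_pct=acc,
            s_n=float(grp["s_n"].min()),
        ))
    return out
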
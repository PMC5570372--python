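"""Bioanalytical method-validation statistics and report tables.

Implements the standard quantities a targeted-MS validation reports:

* accuracy: mean back-calculated concentration as a percentage of the
  nominal spiked concentration;
* precision: percentage coefficient of variation, inter-day (one mean
  per day pooled across days) and intra-day (replicates within a day);
* the three-way spiking design of Matuszewski et al. for matrix effect
  (ME), relative recovery (RE) and process efficiency (PE)::

      ME = 100 * post-extraction-spiked area / solvent-spiked area
      RE = 100 * pre-extraction-spiked area / post-extraction-spiked area
      PE = 100 * pre-extraction-spiked area / solvent-spiked area
         = ME * RE / 100   (exactly, on expectation values)

QC levels below a curve's LLOQ are rendered ``<LLOQ`` rather than
reported numerically.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from io import StringIO

import numpy as np
import pandas as pd

from .calibration import CalibrationCurve, back_calculate

__all__ = [
    "QcLevel",
    "TripletAreas",
    "ValidationReport",
    "accuracy_pct",
    "precision_cv",
    "matrix_effect_pct",
    "relative_recovery_pct",
    "process_efficiency_pct",
    "triplet_stats",
    "build_validation_report",
    "render_qc_table",
    "parse_qc_table",
]


@dataclass(frozen=True)
class QcLevel:
    """A spiked quality-control level (LQAL / MQAL / HQAL)."""

    label: str
    nominal_conc: float

    def __post_init__(self) -> None:
        if self.nominal_conc <= 0:
            raise ValueError("nominal_conc must be positive")


@dataclass(frozen=True)
class TripletAreas:
    """Mean areas (with sds) for the three-way spiking design."""

    pre_spike_area: float
    post_spike_area: float
    solvent_area: float
    pre_sd: float = 0.0
    post_sd: float = 0.0
    solvent_sd: float = 0.0

    def __post_init__(self) -> None:
        if min(self.pre_spike_area, self.post_spike_area, self.solvent_area) <= 0:
            raise ValueError("all triplet areas must be positive")


def accuracy_pct(mean_measured: float, nominal: float) -> float:
    """``100 * mean measured / nominal`` (full precision; tables round to int)."""
    if nominal <= 0:
        raise ValueError("nominal must be positive")
    return 100.0 * mean_measured / nominal


def precision_cv(values) -> float:
    """Percentage coefficient of variation: ``100 * sample sd / mean``."""
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise ValueError("CV needs at least two values")
    mean = float(arr.mean())
    if mean == 0:
        raise ValueError("CV undefined for zero mean")
    return 100.0 * float(arr.std(ddof=1)) / mean


def matrix_effect_pct(t: TripletAreas) -> float:
    """ME: ion suppression/enhancement by co-extracted matrix components."""
    return 100.0 * t.post_spike_area / t.solvent_area


def relative_recovery_pct(t: TripletAreas) -> float:
    """RE: fraction of analyte surviving the extraction itself."""
    return 100.0 * t.pre_spike_area / t.post_spike_area


def process_efficiency_pct(t: TripletAreas) -> float:
    """PE: overall yield of extraction plus ionisation; equals ME*RE/100."""
    return 100.0 * t.pre_spike_area / t.solvent_area


def triplet_stats(sample) -> TripletAreas:
    """Collapse replicate triplet areas (e.g. a synthetic
    :class:`~thyroquant.synthdata.TripletSample`) to mean TripletAreas."""
    return TripletAreas(
        pre_spike_area=float(np.mean(sample.pre_spike_areas)),
        post_spike_area=float(np.mean(sample.post_spike_areas)),
        solvent_area=float(np.mean(sample.solvent_areas)),
        pre_sd=float(np.std(sample.pre_spike_areas, ddof=1)),
        post_sd=float(np.std(sample.post_spike_areas, ddof=1)),
        solvent_sd=float(np.std(sample.solvent_areas, ddof=1)),
    )


@dataclass
class ValidationReport:
    """Accuracy/precision per analyte x QC level, plus ME/PE/RE.

    ``inter_day`` pools one mean per day (n = number of days);
    ``intra_day`` uses the replicates of a single day.  ``triplets``
    holds ME/PE/RE per analyte.  ``inter_day`` is ``None`` for
    single-batch designs.
    """

    inter_day: pd.DataFrame | None
    intra_day: pd.DataFrame
    triplets: pd.DataFrame | None
    n_days: int
    replicates_per_day: int


def _qc_stats(concs_by_unit: list[float], nominal: float) -> tuple[float, float, float]:
    mean = float(np.mean(concs_by_unit))
    cv = precision_cv(concs_by_unit) if len(concs_by_unit) > 1 else 0.0
    return mean, cv, accuracy_pct(mean, nominal)


def build_validation_report(
    qc_measurements: pd.DataFrame,
    curves: dict[str, CalibrationCurve],
    triplets: dict[str, TripletAreas] | None = None,
    intra_day_day: int | None = None,
) -> ValidationReport:
    """Assemble the validation tables from measured QC area ratios.

    ``qc_measurements`` needs columns ``compound, level_label,
    nominal_conc, day, replicate, area_ratio``.  Rows whose compound has
    no calibration curve are quarantined (dropped with a count), not
    fatal.  Levels whose nominal concentration lies below the analyte's
    LLOQ are emitted with ``below_lloq=True`` and no numeric statistics.
    """
    required = {"compound", "level_label", "nominal_conc", "day", "replicate",
                "area_ratio"}
    missing = required - set(qc_measurements.columns)
    if missing:
        raise ValueError(f"qc_measurements missing columns {sorted(missing)}")
    df = qc_measurements[qc_measurements["compound"].isin(curves)].copy()
    df["conc"] = [
        back_calculate(curves[c], r).conc_nm
        for c, r in zip(df["compound"], df["area_ratio"])
    ]
    days = sorted(df["day"].unique())
    n_days = len(days)
    if intra_day_day is None:
        intra_day_day = days[0]

    inter_rows, intra_rows = [], []
    for (comp, label), grp in df.groupby(["compound", "level_label"], sort=True):
        nominal = float(grp["nominal_conc"].iloc[0])
        curve = curves[comp]
        below = curve.lloq is None or nominal < curve.lloq
        base = dict(compound=comp, level_label=label, nominal_conc=nominal,
                    below_lloq=below)
        if n_days > 1:
            day_means = grp.groupby("day")["conc"].mean().to_numpy()
            if below:
                inter_rows.append(dict(base, mean_conc=math.nan, cv_pct=math.nan,
                                       accuracy_pct=math.nan, n=len(day_means)))
            else:
                m, cv, acc = _qc_stats(list(day_means), nominal)
                inter_rows.append(dict(base, mean_conc=m, cv_pct=cv,
                                       accuracy_pct=acc, n=len(day_means)))
        one_day = grp[grp["day"] == intra_day_day]["conc"].to_numpy()
        if below or one_day.size == 0:
            intra_rows.append(dict(base, mean_conc=math.nan, cv_pct=math.nan,
                                   accuracy_pct=math.nan, n=int(one_day.size)))
        else:
            m, cv, acc = _qc_stats(list(one_day), nominal)
            intra_rows.append(dict(base, mean_conc=m, cv_pct=cv,
                                   accuracy_pct=acc, n=int(one_day.size)))

    inter = pd.DataFrame(inter_rows) if inter_rows else None
    intra = pd.DataFrame(intra_rows)

    trip_df = None
    if triplets:
        trip_df = pd.DataFrame([
            dict(compound=name,
                 me_pct=matrix_effect_pct(t),
                 re_pct=relative_recovery_pct(t),
                 pe_pct=process_efficiency_pct(t))
            for name, t in sorted(triplets.items())
        ])
    reps = (df.groupby(["compound", "level_label", "day"])["replicate"]
            .nunique().max() if len(df) else 0)
    return ValidationReport(
        inter_day=inter,
        intra_day=intra,
        triplets=trip_df,
        n_days=n_days,
        replicates_per_day=int(reps),
    )


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def _fmt_conc(v: float) -> str:
    # one decimal above 1 nM, two decimals below (0.10-style)
    return f"{v:.1f}" if v >= 1.0 else f"{v:.2f}"


def render_qc_table(table: pd.DataFrame) -> str:
    """Render an accuracy/precision table as CSV text.

    Mean concentrations keep 1-2 decimals, CV one decimal, accuracy an
    integer percentage; below-LLOQ levels render as ``<LLOQ``.  Full
    precision stays in the DataFrame — rendering is display-only.
    """
    rows = []
    for _, r in table.iterrows():
        if r["below_lloq"] or (isinstance(r["mean_conc"], float) and math.isnan(r["mean_conc"])):
            rows.append(dict(compound=r["compound"], level_label=r["level_label"],
                             nominal_conc=r["nominal_conc"], mean_conc="<LLOQ",
                             cv_pct="", accuracy_pct=""))
        else:
            rows.append(dict(compound=r["compound"], level_label=r["level_label"],
                             nominal_conc=r["nominal_conc"],
                             mean_conc=_fmt_conc(r["mean_conc"]),
                             cv_pct=f"{r['cv_pct']:.1f}",
                             accuracy_pct=f"{r['accuracy_pct']:.0f}"))
    return pd.DataFrame(rows).to_csv(index=False)


def parse_qc_table(text: str) -> pd.DataFrame:
    """Parse a rendered QC table back into a DataFrame.

    Round-trips with :func:`render_qc_table` at display precision:
    ``parse(render(t))`` equals the rendered values, with ``<LLOQ`` rows
    restored as ``below_lloq=True``.
    """
    df = pd.read_csv(StringIO(text), dtype={"mean_conc": str})
    df["below_lloq"] = df["mean_conc"] == "<LLOQ"
    for col in ("mean_conc", "cv_pct", "accuracy_pct"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    return df
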
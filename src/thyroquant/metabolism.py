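"""Metabolite identity confirmation and compartmental mass balance.

When cultured cells are incubated with a parent compound, putative
metabolites detected in cell lysates or supernatants must be confirmed
before they enter the bookkeeping.  Confirmation requires both a
retention-time match and a quantifier/qualifier area ratio (MRM_qc)
within a tolerance (default +/-20%) of the ratio measured for a neat
standard.  An undefined ratio — qualifier absent — can never confirm.

Confirmed amounts are converted from concentration to absolute pmol
(1 nM = 1 pmol/mL, times the compartment volume: 0.4 mL lysate,
1.5 mL supernatant by default) and expressed as percentages of the
incubated amount.  Per-time totals sum the unrounded percentages over
both compartments for all detected compounds; no recovery correction is
applied, which is why totals typically close in the 66-84% range rather
than at 100%.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from .peaks import Peak, quantifier_qualifier_ratio
from .registry import Compound

__all__ = [
    "IdentityResult",
    "MassBalanceRow",
    "MassBalanceTable",
    "confirm_identity",
    "conc_to_pmol",
    "mass_balance",
    "timecourse_summary",
    "render_mass_balance",
]


@dataclass(frozen=True)
class IdentityResult:
    """Outcome of a retention-time + ion-ratio identity check."""

    compound: str
    rt_expected_min: float
    rt_found_min: float
    rt_dev_min: float
    qc_ratio_dev_pct: float  # signed; nan when the ratio is undefined
    confirmed: bool
    context: str = "cell_lysate"
    incubation_min: float | None = None


def confirm_identity(
    peak_q: Peak | None,
    peak_c: Peak | None,
    compound: Compound,
    tolerance_pct: float = 20.0,
    rt_window_min: float = 0.1,
    context: str = "cell_lysate",
    incubation_min: float | None = None,
) -> IdentityResult:
    """Confirm or reject a metabolite identity.

    Confirmed iff the observed quantifier/qualifier ratio deviates from
    the compound's expected ratio by at most ``tolerance_pct`` (signed
    deviation ``100*(observed/expected - 1)``) *and* the apex retention
    time is within ``rt_window_min`` of the expected value.  A missing
    quantifier peak or an undefined ratio is an unconfirmed result, not
    an error.
    """
    if compound.expected_qc_ratio <= 0:
        raise ValueError("compound needs a positive expected_qc_ratio")
    rt_found = peak_q.apex_rt_min if peak_q is not None else math.nan
    rt_dev = rt_found - compound.expected_rt_min
    ratio = quantifier_qualifier_ratio(peak_q, peak_c)
    if math.isnan(ratio):
        dev = math.nan
        ok = False
    else:
        dev = 100.0 * (ratio / compound.expected_qc_ratio - 1.0)
        ok = abs(dev) <= tolerance_pct and abs(rt_dev) <= rt_window_min
    return IdentityResult(
        compound=compound.name,
        rt_expected_min=compound.expected_rt_min,
        rt_found_min=rt_found,
        rt_dev_min=rt_dev,
        qc_ratio_dev_pct=dev,
        confirmed=ok,
        context=context,
        incubation_min=incubation_min,
    )


def conc_to_pmol(conc_nm: float, volume_ml: float) -> float:
    """Absolute amount from concentration: ``conc * volume`` (1 nM = 1 pmol/mL)."""
    if volume_ml <= 0:
        raise ValueError("volume_ml must be positive")
    if conc_nm < 0:
        raise ValueError("conc must be >= 0")
    return conc_nm * volume_ml


@dataclass(frozen=True)
class MassBalanceRow:
    incubation_compound: str
    incubated_pmol: float
    time_min: float
    compartment: str
    compound: str
    amount_pmol: float | None  # None encodes "nd" (not detected)
    percent_of_incubated: float | None

    @property
    def detected(self) -> bool:
        return self.amount_pmol is not None


@dataclass
class MassBalanceTable:
    """Rows plus per-(incubation compound, time) totals.

    Totals sum the *unrounded* percentages of every detected compound
    over both compartments; display rounding happens last.
    """

    rows: list[MassBalanceRow]
    totals: dict[tuple[str, float], float]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(r) | {"detected": r.detected} for r in self.rows])


def mass_balance(
    amounts: pd.DataFrame,
    incubated_pmol: float,
    incubation_compound: str,
) -> MassBalanceTable:
    """Build the mass-balance table from per-compartment amounts.

    ``amounts`` needs columns ``time_min, compartment, compound,
    amount_pmol`` and optionally ``detected`` (defaults to True for
    non-null amounts; not-detected rows contribute zero to totals but
    are kept, distinct from true zeros).  Percentages are not adjusted
    for extraction recovery.
    """
    if incubated_pmol <= 0:
        raise ValueError("incubated_pmol must be positive")
    df = amounts.copy()
    if "detected" not in df.columns:
        df["detected"] = df["amount_pmol"].notna()
    rows: list[MassBalanceRow] = []
    totals: dict[tuple[str, float], float] = {}
    for _, r in df.iterrows():
        detected = bool(r["detected"]) and not pd.isna(r["amount_pmol"])
        amount = float(r["amount_pmol"]) if detected else None
        pct = 100.0 * amount / incubated_pmol if detected else None
        rows.append(MassBalanceRow(
            incubation_compound=incubation_compound,
            incubated_pmol=incubated_pmol,
            time_min=float(r["time_min"]),
            compartment=str(r["compartment"]),
            compound=str(r["compound"]),
            amount_pmol=amount,
            percent_of_incubated=pct,
        ))
        key = (incubation_compound, float(r["time_min"]))
        totals[key] = totals.get(key, 0.0) + (pct or 0.0)
    return MassBalanceTable(rows=rows, totals=totals)


# display rounding mirrors the conventional table layout: pmol to
# integers, percentages >= 1% to integers, smaller ones to 1-2 decimals,
# totals rounded last
def _fmt_pct(pct: float) -> str:
    if pct >= 1.0:
        return f"{pct:.0f}%"
    if pct >= 0.095:
        return f"{pct:.1f}%"
    return f"{pct:.2f}%"


def render_mass_balance(table: MassBalanceTable) -> pd.DataFrame:
    """Display-rounded mass-balance table (strings), totals rounded last."""
    recs = []
    for r in table.rows:
        if not r.detected:
            amount, pct = "nd", "(0%)"
        else:
            amount = f"{r.amount_pmol:.0f}" if r.amount_pmol >= 1 else f"{r.amount_pmol:.1f}"
            pct = f"({_fmt_pct(r.percent_of_incubated)})"
        recs.append(dict(
            incubation_compound=r.incubation_compound,
            time_min=r.time_min, compartment=r.compartment,
            compound=r.compound, amount_pmol=amount, percent=pct,
            total_pct=f"{table.totals[(r.incubation_compound, r.time_min)]:.0f}%",
        ))
    return pd.DataFrame(recs)


def timecourse_summary(
    balance: MassBalanceTable | pd.DataFrame,
    flat_threshold: float = 0.10,
) -> pd.DataFrame:
    """Classify each compound/compartment trend across time points.

    A series is ``increasing``/``decreasing`` when the relative change
    from first to last detected amount exceeds ``flat_threshold`` (and
    the series is monotone in that direction up to the threshold),
    otherwise ``flat``.  Not-detected time points count as zero amount.

    Returns columns ``compound, compartment, trend, detected_at`` where
    ``detected_at`` lists the times the compound was detected.
    """
    df = balance.to_frame() if isinstance(balance, MassBalanceTable) else balance.copy()
    if df["time_min"].nunique() < 2:
        raise ValueError("need at least two time points")
    out = []
    for (comp, compartment), grp in df.groupby(["compound", "compartment"], sort=True):
        grp = grp.sort_values("time_min")
        amounts = grp["amount_pmol"].astype(float).fillna(0.0).to_numpy()
        times = grp["time_min"].to_numpy()
        first, last = amounts[0], amounts[-1]
        if first == 0 and last == 0:
            trend = "flat"
        elif first == 0:
            trend = "increasing"
        else:
            rel = (last - first) / first
            if rel > flat_threshold:
                trend = "increasing"
            elif rel < -flat_threshold:
                trend = "decreasing"
            else:
                trend = "flat"
        detected_at = [float(t) for t, a in zip(times, grp["amount_pmol"])
                       if not pd.isna(a)]
        out.append(dict(compound=comp, compartment=compartment, trend=trend,
                        detected_at=detected_at))
    return pd.DataFrame(out)
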
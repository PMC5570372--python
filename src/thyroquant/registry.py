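"""Compound panel and MRM transition registry.

Targeted LC-MS/MS quantification of thyroid hormone metabolites (THM)
monitors each compound through two multiple-reaction-monitoring (MRM)
transitions: a *quantifier* (the more intense product ion, used for
quantification) and a *qualifier* (used to confirm identity through the
quantifier/qualifier area ratio).  The registry holds, per compound, the
precursor/product m/z values, source/collision voltages, the expected
retention time, the family (thyronine TN, thyronamine TAM, thyroacetic
acid TAc), the iodination state, and the stable-isotope-labelled internal
standard (IS) assigned for isotope-dilution quantification.

Registry files are plain CSV with columns::

    name, family, iodine_count, rt_min, polarity, q1_mz, q3_quant_mz,
    q3_qual_mz, dp_v, ce_v, cxp_v, dwell_ms, internal_standard,
    is_labeled, expected_qc_ratio

``ce_v`` and ``cxp_v`` accept either a single value (applied to both
transitions) or a ``quant|qual`` pair, since collision energies usually
differ between the two product ions.

The default panel ships the four negative-ion thyroacetic-acid entries
with their published instrument parameters verbatim, and *placeholder*
positive-ion entries for the thyronine/thyronamine panel: retention times
are real, but the m/z values are synthetic stand-ins (simple mass
arithmetic) that the user must replace with their instrument's tuned
values before analysing real data.  Placeholder entries carry
``user_supplied=True``.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator

__all__ = [
    "MrmTransition",
    "Compound",
    "AcquisitionSettings",
    "CompoundRegistry",
    "RegistrySchemaError",
    "RegistryReferenceError",
    "AssignmentError",
    "load_registry",
    "write_registry",
    "default_registry",
    "assign_internal_standard",
]

FAMILIES = ("TN", "TAM", "TAc")
ROLES = ("quantifier", "qualifier")


class RegistrySchemaError(ValueError):
    """Registry file malformed: missing columns, bad values, wrong transitions."""


class RegistryReferenceError(ValueError):
    """A compound references an internal standard absent from the registry."""


class AssignmentError(ValueError):
    """No labelled internal standard can be assigned to an analyte."""


@dataclass(frozen=True)
class MrmTransition:
    """One precursor -> product MRM transition with instrument parameters."""

    precursor_mz: float
    product_mz: float
    declustering_potential: float
    collision_energy: float
    collision_exit_potential: float
    polarity: str  # "positive" | "negative"
    role: str  # "quantifier" | "qualifier"
    dwell_ms: float = 10.0

    def __post_init__(self) -> None:
        if not (self.precursor_mz > self.product_mz > 0):
            raise ValueError(
                f"require precursor_mz > product_mz > 0, got "
                f"{self.precursor_mz} -> {self.product_mz}"
            )
        if self.dwell_ms <= 0:
            raise ValueError("dwell_ms must be positive")
        if self.polarity not in ("positive", "negative"):
            raise ValueError(f"unknown polarity {self.polarity!r}")
        if self.role not in ROLES:
            raise ValueError(f"unknown transition role {self.role!r}")


@dataclass(frozen=True)
class Compound:
    """A panel member: analyte or stable-isotope-labelled internal standard."""

    name: str
    family: str
    iodine_count: int
    expected_rt_min: float
    transitions: tuple[MrmTransition, MrmTransition]
    internal_standard: str | None = None
    is_labeled: bool = False
    expected_qc_ratio: float = 3.0
    user_supplied: bool = False  # True for placeholder m/z entries

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        if not (0 <= self.iodine_count <= 4):
            raise ValueError("iodine_count must be in 0..4")
        if self.expected_rt_min <= 0:
            raise ValueError("expected_rt_min must be positive")
        roles = sorted(t.role for t in self.transitions)
        if roles != ["qualifier", "quantifier"]:
            raise RegistrySchemaError(
                f"{self.name}: need exactly one quantifier and one qualifier"
            )
        if self.expected_qc_ratio <= 0:
            raise ValueError("expected_qc_ratio must be positive")

    @property
    def quantifier(self) -> MrmTransition:
        return next(t for t in self.transitions if t.role == "quantifier")

    @property
    def qualifier(self) -> MrmTransition:
        return next(t for t in self.transitions if t.role == "qualifier")


@dataclass(frozen=True)
class AcquisitionSettings:
    """MS acquisition geometry: duty cycle and peak-sampling requirement.

    The duty cycle is the total time of one sweep over all scheduled
    transitions (both polarities); it fixes the chromatographic sampling
    interval and therefore the number of data points across a peak.
    """

    duty_cycle_sec: float = 0.73
    min_points_per_peak: int = 15
    polarity_switching: bool = True

    def __post_init__(self) -> None:
        if self.duty_cycle_sec <= 0:
            raise ValueError("duty_cycle_sec must be positive")
        if self.min_points_per_peak < 1:
            raise ValueError("min_points_per_peak must be >= 1")


class CompoundRegistry:
    """Ordered, name-indexed collection of :class:`Compound` entries."""

    def __init__(self, compounds: list[Compound]):
        self._by_name: dict[str, Compound] = {}
        for c in compounds:
            if c.name in self._by_name:
                raise RegistrySchemaError(f"duplicate compound name {c.name!r}")
            self._by_name[c.name] = c
        self._check_references()

    def _check_references(self) -> None:
        for c in self._by_name.values():
            if c.internal_standard is None:
                continue
            target = self._by_name.get(c.internal_standard)
            if target is None:
                raise RegistryReferenceError(
                    f"{c.name}: internal standard {c.internal_standard!r} "
                    "not in registry"
                )
            if not target.is_labeled:
                raise RegistryReferenceError(
                    f"{c.name}: internal standard {c.internal_standard!r} "
                    "is not a labelled compound"
                )

    def __getitem__(self, name: str) -> Compound:
        return self._by_name[name]

    def __contains__(self, name: str) -> bool:
        return name in self._by_name

    def __iter__(self) -> Iterator[Compound]:
        return iter(self._by_name.values())

    def __len__(self) -> int:
        return len(self._by_name)

    @property
    def names(self) -> list[str]:
        return list(self._by_name)

    def analytes(self) -> list[Compound]:
        """Unlabelled panel members (the quantified analytes)."""
        return [c for c in self if not c.is_labeled]

    def labeled(self) -> list[Compound]:
        """Stable-isotope-labelled internal standards."""
        return [c for c in self if c.is_labeled]


# ---------------------------------------------------------------------------
# default panel
# ---------------------------------------------------------------------------

# Negative-ion thyroacetic-acid entries with published instrument
# parameters: (name, family, iodine, rt_min, Q1, Pro1, Pro2, DP,
#              CE_quant, CE_qual, CXP_quant, CXP_qual, IS, labeled)
_NEGATIVE_PANEL = [
    ("2H4-T0Ac", "TAc", 0, 4.71, 247.0, 203.1, 105.9, -15, -14, -26, -9, -5, None, True),
    ("2H4-T1Ac", "TAc", 1, 5.15, 372.9, 329.0, 126.8, -5, -8, -16, -15, -13, None, True),
    ("T0Ac", "TAc", 0, 4.72, 243.0, 198.9, 106.0, -10, -12, -24, -9, -5, "2H4-T0Ac", False),
    ("3-T1Ac", "TAc", 1, 5.16, 369.0, 324.9, 126.7, -15, -8, -26, -13, -19, "2H4-T1Ac", False),
]

# Positive-ion panel: retention times are real; m/z values are synthetic
# placeholders (thyronine skeleton ~274 Da + 125.9 per iodine; TAM -44,
# label +6/+4) the user must replace with tuned instrument values.
# (name, family, iodine, rt_min, IS, labeled)
_POSITIVE_PANEL = [
    ("T0", "TN", 0, 4.12, None, False),
    ("3-T1", "TN", 1, 4.54, None, False),
    ("3'-T1", "TN", 1, 4.80, None, False),
    ("3,5-T2", "TN", 2, 4.60, None, False),
    ("3,3'-T2", "TN", 2, 5.16, "13C6-3,3'-T2", False),
    ("3',5'-T2", "TN", 2, 5.35, None, False),
    ("T3", "TN", 3, 5.01, "13C6-T3", False),
    ("rT3", "TN", 3, 5.64, "13C6-rT3", False),
    ("T4", "TN", 4, 5.36, "13C6-T4", False),
    ("T0AM", "TAM", 0, 4.65, None, False),
    ("3-T1AM", "TAM", 1, 5.30, "2H4-3-T1AM", False),
    ("3,5-T2AM", "TAM", 2, 5.34, None, False),
    ("T3AM", "TAM", 3, 5.97, None, False),
    ("rT3AM", "TAM", 3, 7.10, None, False),
    ("T4AM", "TAM", 4, 6.56, None, False),
    ("13C6-3,3'-T2", "TN", 2, 5.16, None, True),
    ("13C6-T3", "TN", 3, 5.01, None, True),
    ("13C6-rT3", "TN", 3, 5.64, None, True),
    ("13C6-T4", "TN", 4, 5.36, None, True),
    ("2H4-3-T1AM", "TAM", 1, 5.30, None, True),
]


def _placeholder_mz(family: str, iodine: int, labeled: bool, name: str) -> float:
    """Synthetic precursor m/z for placeholder positive-ion entries."""
    base = 274.1  # protonated thyronine skeleton stand-in
    if family == "TAM":
        base -= 44.0  # decarboxylated
    mz = base + 125.9 * iodine
    if labeled:
        mz += 6.0 if name.startswith("13C6") else 4.0
    return round(mz, 1)


def default_registry() -> CompoundRegistry:
    """The built-in THM panel.

    Thyroacetic-acid entries carry real negative-ion parameters; the
    thyronine/thyronamine entries are ``user_supplied`` placeholders with
    synthetic m/z values (see module docstring).
    """
    compounds: list[Compound] = []
    for (name, fam, iod, rt, q1, pro1, pro2, dp, ce_q, ce_c, cxp_q, cxp_c,
         is_name, labeled) in _NEGATIVE_PANEL:
        trans = (
            MrmTransition(q1, pro1, dp, ce_q, cxp_q, "negative", "quantifier"),
            MrmTransition(q1, pro2, dp, ce_c, cxp_c, "negative", "qualifier"),
        )
        compounds.append(Compound(name, fam, iod, rt, trans,
                                  internal_standard=is_name, is_labeled=labeled))
    for name, fam, iod, rt, is_name, labeled in _POSITIVE_PANEL:
        q1 = _placeholder_mz(fam, iod, labeled, name)
        trans = (
            MrmTransition(q1, round(q1 - 17.0, 1), 60.0, 30.0, 10.0,
                          "positive", "quantifier"),
            MrmTransition(q1, round(q1 - 63.0, 1), 60.0, 40.0, 10.0,
                          "positive", "qualifier"),
        )
        compounds.append(Compound(name, fam, iod, rt, trans,
                                  internal_standard=is_name, is_labeled=labeled,
                                  user_supplied=True))
    return CompoundRegistry(compounds)


# ---------------------------------------------------------------------------
# CSV round-trip
# ---------------------------------------------------------------------------

_COLUMNS = [
    "name", "family", "iodine_count", "rt_min", "polarity", "q1_mz",
    "q3_quant_mz", "q3_qual_mz", "dp_v", "ce_v", "cxp_v", "dwell_ms",
    "internal_standard", "is_labeled", "expected_qc_ratio",
]


def _fmt_pair(a: float, b: float) -> str:
    fa, fb = (repr(v) if v != int(v) else str(int(v)) for v in (a, b))
    return fa if a == b else f"{fa}|{fb}"


def _parse_pair(text: str) -> tuple[float, float]:
    parts = text.split("|")
    if len(parts) == 1:
        v = float(parts[0])
        return v, v
    return float(parts[0]), float(parts[1])


def write_registry(registry: CompoundRegistry, path: str | Path) -> None:
    """Write the registry as CSV, preserving all numeric fields exactly."""
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=_COLUMNS)
        writer.writeheader()
        for c in registry:
            q, cq = c.quantifier, c.qualifier
            writer.writerow({
                "name": c.name,
                "family": c.family,
                "iodine_count": c.iodine_count,
                "rt_min": repr(c.expected_rt_min),
                "polarity": q.polarity,
                "q1_mz": repr(q.precursor_mz),
                "q3_quant_mz": repr(q.product_mz),
                "q3_qual_mz": repr(cq.product_mz),
                "dp_v": repr(q.declustering_potential),
                "ce_v": _fmt_pair(q.collision_energy, cq.collision_energy),
                "cxp_v": _fmt_pair(q.collision_exit_potential,
                                   cq.collision_exit_potential),
                "dwell_ms": repr(q.dwell_ms),
                "internal_standard": c.internal_standard or "",
                "is_labeled": int(c.is_labeled),
                "expected_qc_ratio": repr(c.expected_qc_ratio),
            })


def load_registry(path: str | Path) -> CompoundRegistry:
    """Load a compound registry from CSV.

    Raises
    ------
    RegistrySchemaError
        On missing columns, empty files or malformed rows.
    RegistryReferenceError
        When an ``internal_standard`` names a compound that is absent or
        not labelled.
    """
    path = Path(path)
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or not set(_COLUMNS) <= set(reader.fieldnames):
            raise RegistrySchemaError(
                f"{path}: expected columns {_COLUMNS}, got {reader.fieldnames}"
            )
        compounds = []
        for row in reader:
            try:
                ce_q, ce_c = _parse_pair(row["ce_v"])
                cxp_q, cxp_c = _parse_pair(row["cxp_v"])
                q1 = float(row["q1_mz"])
                dp = float(row["dp_v"])
                dwell = float(row["dwell_ms"])
                trans = (
                    MrmTransition(q1, float(row["q3_quant_mz"]), dp, ce_q,
                                  cxp_q, row["polarity"], "quantifier", dwell),
                    MrmTransition(q1, float(row["q3_qual_mz"]), dp, ce_c,
                                  cxp_c, row["polarity"], "qualifier", dwell),
                )
                compounds.append(Compound(
                    name=row["name"],
                    family=row["family"],
                    iodine_count=int(row["iodine_count"]),
                    expected_rt_min=float(row["rt_min"]),
                    transitions=trans,
                    internal_standard=row["internal_standard"] or None,
                    is_labeled=bool(int(row["is_labeled"])),
                    expected_qc_ratio=float(row["expected_qc_ratio"]),
                ))
            except (KeyError, ValueError) as exc:
                if isinstance(exc, RegistryReferenceError):
                    raise
                raise RegistrySchemaError(f"{path}: bad row {row!r}: {exc}") from exc
    if not compounds:
        raise RegistrySchemaError(f"{path}: registry file contains no compounds")
    return CompoundRegistry(compounds)


# ---------------------------------------------------------------------------
# internal-standard assignment
# ---------------------------------------------------------------------------

_LABEL_PREFIXES = ("13C6-", "2H4-")

#: Default family-level fallback when no structurally identical labelled
#: analog exists: thyronines fall back to the closest-iodine 13C6 analog,
#: thyronamines to 2H4-3-T1AM, thyroacetic acids to the closest 2H4 analog.
DEFAULT_FALLBACK = {"TAM": "2H4-3-T1AM"}


def _identical_labeled(analyte: Compound, registry: CompoundRegistry) -> Compound | None:
    for prefix in _LABEL_PREFIXES:
        cand = prefix + analyte.name
        if cand in registry and registry[cand].is_labeled:
            return registry[cand]
    return None


def assign_internal_standard(
    analyte: Compound,
    registry: CompoundRegistry,
    fallback: dict[str, str] | None = None,
) -> Compound:
    """Resolve the internal standard for an analyte.

    Preference order: (1) the registry's explicit assignment; (2) the
    structurally identical labelled analog (``13C6-X`` / ``2H4-X``);
    (3) a family-level fallback — for thyronines the labelled analog
    closest in iodine count (ties broken by retention-time proximity),
    for other families the ``fallback`` map entry.  Never returns an
    unlabelled compound.
    """
    if analyte.is_labeled:
        raise AssignmentError(f"{analyte.name} is itself a labelled standard")
    fallback = DEFAULT_FALLBACK if fallback is None else fallback

    if analyte.internal_standard is not None:
        return registry[analyte.internal_standard]
    ident = _identical_labeled(analyte, registry)
    if ident is not None:
        return ident

    labeled_same_family = [c for c in registry.labeled() if c.family == analyte.family]
    if analyte.family in fallback:
        name = fallback[analyte.family]
        if name not in registry or not registry[name].is_labeled:
            raise AssignmentError(
                f"fallback IS {name!r} for family {analyte.family} not available"
            )
        return registry[name]
    if labeled_same_family:
        return min(
            labeled_same_family,
            key=lambda c: (abs(c.iodine_count - analyte.iodine_count),
                           abs(c.expected_rt_min - analyte.expected_rt_min)),
        )
    raise AssignmentError(
        f"no labelled internal standard available for {analyte.name}"
    )


def resolve_all_internal_standards(
    registry: CompoundRegistry, fallback: dict[str, str] | None = None
) -> dict[str, str]:
    """Map every analyte name to its resolved internal-standard name."""
    return {
        c.name: assign_internal_standard(c, registry, fallback).name
        for c in registry.analytes()
    }
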
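"""Bundled reference datasets.

Small CSVs shipped with the package, taken from a published validation
of this assay family; they serve as worked inputs for the mass-balance
and matrix-effect arithmetic and as cross-checks in the test suite.

* ``hepg2_triplet_reference`` / ``pccl3_triplet_reference``: reported
  mean process efficiency (PE), matrix effect (ME) and relative
  recovery (RE) percentages, with sds, per compound (and per spiked
  level for the hepatocyte matrix).  Levels that fell below the LLOQ
  are absent.
* ``pccl3_timecourse_pmol``: absolute pmol amounts of parent compounds
  and their metabolites in cell lysates (0.4 mL) and supernatants
  (1.5 mL) after incubating thyrocytes with ~500 nM of a mono-iodinated
  parent for 5/10/30 min, together with the incubated amount.
  Not-detected entries have an empty amount and ``detected=0``.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = [
    "hepg2_triplet_reference",
    "pccl3_triplet_reference",
    "pccl3_timecourse_pmol",
]


def _read(name: str) -> pd.DataFrame:
    ref = resources.files("thyroquant") / "data" / name
    with resources.as_file(ref) as path:
        return pd.read_csv(path)


def hepg2_triplet_reference() -> pd.DataFrame:
    """PE/ME/RE means for the hepatocyte (Hep G2) lysate matrix."""
    return _read("hepg2_triplet_reference.csv")


def pccl3_triplet_reference() -> pd.DataFrame:
    """PE/ME/RE means for the thyrocyte (PCCL3) lysate matrix at 1 nM."""
    return _read("pccl3_triplet_reference.csv")


def pccl3_timecourse_pmol() -> pd.DataFrame:
    """Compartmental pmol amounts from the thyrocyte incubation study."""
    return _read("pccl3_timecourse_pmol.csv")
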
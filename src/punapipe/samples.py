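"""Human-bone sample records and CSV interchange.

An :class:`IsotopeSample` holds one individual's osteological attributes and
bone isotope chemistry: either raw instrument values (carbonate delta-18O on
the VPDB scale, apatite delta-13C) or already-corrected values (drinking-water
delta-18O on the VSMOW scale, diet delta-13C), or both.  The packaged fixture
``data/smp_burials.csv`` holds the 16 published burials from the Soro Mik'aya
Patjxa site (3860 m a.s.l., Andean Altiplano) with corrected values; open-ended
"50+" ages are encoded as the interval [50, 70].
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import numpy as np
import pandas as pd

__all__ = [
    "IsotopeSample",
    "read_samples_csv",
    "write_samples_csv",
    "load_reference_burials",
]

_SEX_IN = {"f": "female", "m": "male", "ind": "indeterminate",
           "female": "female", "male": "male", "indeterminate": "indeterminate"}
_SEX_OUT = {"female": "f", "male": "m", "indeterminate": "ind"}

#: plausibility bounds for any per-mil value handled by the package
PERMIL_BOUNDS = (-50.0, 50.0)


@dataclass
class IsotopeSample:
    """One individual: identifiers, demographic attributes, bone chemistry.

    Per-mil fields may be ``None`` when not measured; at least one of the raw
    or corrected value must be present for any isotope system actually used.
    """

    burial_id: str
    bone_element: str = ""
    d18O_carbonate_vpdb: Optional[float] = None
    d18O_mw_vsmow: Optional[float] = None
    d13C_apatite_vpdb: Optional[float] = None
    d13C_diet_vpdb: Optional[float] = None
    sex: str = "indeterminate"
    age_min_years: Optional[float] = None
    age_max_years: Optional[float] = None
    #: provenance notes, e.g. which correction chain produced a corrected value
    notes: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.sex not in ("female", "male", "indeterminate"):
            raise ValueError(f"unknown sex category: {self.sex!r}")
        lo, hi = PERMIL_BOUNDS
        for name in ("d18O_carbonate_vpdb", "d18O_mw_vsmow",
                     "d13C_apatite_vpdb", "d13C_diet_vpdb"):
            v = getattr(self, name)
            if v is not None and not (lo <= v <= hi):
                raise ValueError(f"{name}={v} outside plausible per-mil range {PERMIL_BOUNDS}")
        if (self.age_min_years is not None and self.age_max_years is not None
                and self.age_min_years > self.age_max_years):
            raise ValueError(
                f"burial {self.burial_id}: age_min {self.age_min_years} > age_max {self.age_max_years}")

    @property
    def has_age(self) -> bool:
        return self.age_min_years is not None and self.age_max_years is not None


def read_samples_csv(path) -> list[IsotopeSample]:
    """Read the sample-table CSV (header required, UTF-8, decimal point).

    Expected columns: ``burial_id, bone_element, d18O_mw_vsmow,
    d13C_diet_vpdb, sex, age_min, age_max`` with sex coded f/m/ind.  Empty
    cells become ``None``.
    """
    df = pd.read_csv(path, dtype={"burial_id": str})
    required = {"burial_id", "sex", "age_min", "age_max"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"sample CSV missing columns: {sorted(missing)}")

    def _num(row, col):
        if col not in df.columns or pd.isna(row[col]):
            return None
        return float(row[col])

    samples = []
    for _, row in df.iterrows():
        sex_code = str(row["sex"]).strip().lower()
        if sex_code not in _SEX_IN:
            raise ValueError(f"burial {row['burial_id']}: unknown sex code {row['sex']!r}")
        samples.append(IsotopeSample(
            burial_id=str(row["burial_id"]),
            bone_element=str(row.get("bone_element", "") or ""),
            d18O_mw_vsmow=_num(row, "d18O_mw_vsmow"),
            d13C_diet_vpdb=_num(row, "d13C_diet_vpdb"),
            d18O_carbonate_vpdb=_num(row, "d18O_carbonate_vpdb"),
            d13C_apatite_vpdb=_num(row, "d13C_apatite_vpdb"),
            sex=_SEX_IN[sex_code],
            age_min_years=_num(row, "age_min"),
            age_max_years=_num(row, "age_max"),
        ))
    return samples


def write_samples_csv(samples: Iterable[IsotopeSample], path) -> None:
    """Write samples in the interchange layout accepted by :func:`read_samples_csv`."""
    rows = []
    for s in samples:
        rows.append({
            "burial_id": s.burial_id,
            "bone_element": s.bone_element,
            "d18O_mw_vsmow": s.d18O_mw_vsmow,
            "d13C_diet_vpdb": s.d13C_diet_vpdb,
            "sex": _SEX_OUT[s.sex],
            "age_min": s.age_min_years,
            "age_max": s.age_max_years,
        })
    pd.DataFrame(rows).to_csv(path, index=False)


def load_reference_burials() -> list[IsotopeSample]:
    """The packaged 16-burial table (corrected values, sex, age intervals)."""
    with importlib.resources.as_file(
            importlib.resources.files("punapipe.data") / "smp_burials.csv") as p:
        return read_samples_csv(Path(p))
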
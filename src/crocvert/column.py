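"""Specimen containers, predictor computation, and measurement-table I/O.

A :class:`SpecimenColumn` holds one individual's centrum-length (CL)
record: up to 35 per-position measurements (mm) with neurocentral suture
states, plus specimen metadata and optional snout-vent (SVL) and total
length (TL) records.

The canonical interchange format is a long CSV, one row per
(specimen, position), headers::

    specimen_id, species, position, cl_mm, suture
    [, svl_mm, tl_mm, sex, provenance]

Suture vocabulary (case-insensitive): open, partial / partially_closed,
closed / fully_closed, unknown.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd

from . import axial
from .axial import AXIAL_INDEX, POSITIONS, REGIONS, SERIES, check_position
from .errors import (
    DuplicateMeasurementError,
    InvalidMeasurementError,
    MissingPredictorError,
)


class SutureState(Enum):
    """State of the neurocentral suture at one position.

    PARTIAL and CLOSED both mean "closure has begun" and are merged by
    every maturity rule; the distinction is preserved only for records.
    """

    OPEN = "open"
    PARTIAL = "partial"
    CLOSED = "closed"
    UNKNOWN = "unknown"

    @property
    def closure_begun(self) -> bool:
        return self in (SutureState.PARTIAL, SutureState.CLOSED)


_SUTURE_ALIASES = {
    "open": SutureState.OPEN,
    "fully_open": SutureState.OPEN,
    "partial": SutureState.PARTIAL,
    "partially_closed": SutureState.PARTIAL,
    "closed": SutureState.CLOSED,
    "fully_closed": SutureState.CLOSED,
    "unknown": SutureState.UNKNOWN,
    "": SutureState.UNKNOWN,
}


def parse_suture(text) -> SutureState:
    if isinstance(text, SutureState):
        return text
    if text is None or (isinstance(text, float) and np.isnan(text)):
        return SutureState.UNKNOWN
    key = str(text).strip().lower().replace(" ", "_").replace("-", "_")
    try:
        return _SUTURE_ALIASES[key]
    except KeyError:
        raise InvalidMeasurementError(f"unknown suture state {text!r}") from None


@dataclass(frozen=True)
class CentrumMeasurement:
    """One centrum length (mm, condyle excluded) with its suture state."""

    position: str
    centrum_length_mm: float
    suture: SutureState = SutureState.UNKNOWN
    imputed: bool = False

    def __post_init__(self):
        check_position(self.position)
        if not (self.centrum_length_mm > 0):
            raise InvalidMeasurementError(
                f"non-positive centrum length {self.centrum_length_mm!r} "
                f"at {self.position}"
            )
        if self.imputed and self.suture is not SutureState.UNKNOWN:
            object.__setattr__(self, "suture", SutureState.UNKNOWN)


@dataclass(frozen=True)
class PredictorValue:
    """A region mean or series sum of centrum lengths (mm).

    ``complete`` is False when any member position is absent or imputed,
    letting callers decide whether partially supported predictors are
    acceptable.
    """

    predictor_id: str
    value_mm: float
    complete: bool


@dataclass
class SpecimenColumn:
    """One individual's axial column record."""

    specimen_id: str
    species: str
    sex: str = "UNKNOWN"
    provenance: str = "UNKNOWN"
    svl_mm: Optional[float] = None
    tl_mm: Optional[float] = None
    measurements: dict[str, CentrumMeasurement] = field(default_factory=dict)

    def __post_init__(self):
        for pos, m in self.measurements.items():
            check_position(pos)
            if m.position != pos:
                raise InvalidMeasurementError(
                    f"measurement keyed {pos} has position {m.position}"
                )
        if self.svl_mm is not None and self.tl_mm is not None:
            if not self.tl_mm > self.svl_mm:
                raise InvalidMeasurementError(
                    f"{self.specimen_id}: TL ({self.tl_mm} mm) must exceed "
                    f"SVL ({self.svl_mm} mm)"
                )

    @property
    def genus(self) -> str:
        """First whitespace-delimited token of the species name."""
        return self.species.split()[0] if self.species.split() else self.species

    def cl(self, position: str) -> Optional[float]:
        m = self.measurements.get(position)
        return None if m is None else m.centrum_length_mm

    def suture(self, position: str) -> SutureState:
        m = self.measurements.get(position)
        return SutureState.UNKNOWN if m is None else m.suture

    def present_positions(self) -> list[str]:
        """Positions with a CL (measured or imputed), craniocaudal order."""
        return [p for p in POSITIONS if p in self.measurements]

    def measured_positions(self) -> list[str]:
        return [
            p for p in POSITIONS
            if p in self.measurements and not self.measurements[p].imputed
        ]

    def missing_positions(self) -> list[str]:
        return [p for p in POSITIONS if p not in self.measurements]

    def is_complete(self, series: str = "C2-Ca10sum") -> bool:
        """True when every member of ``series`` has a *measured* CL."""
        return all(
            p in self.measurements and not self.measurements[p].imputed
            for p in SERIES[series]
        )

    def with_measurement(self, m: CentrumMeasurement) -> "SpecimenColumn":
        new = dict(self.measurements)
        new[m.position] = m
        return replace(self, measurements=new)


# ---------------------------------------------------------------------------
# Predictors


def region_mean(column: SpecimenColumn, region: str) -> PredictorValue:
    """Arithmetic mean CL over a region's member positions.

    Any member may be absent (``complete`` reflects it); at least one is
    required.
    """
    rid = axial.normalize_predictor_id(region)
    members = REGIONS[rid]
    vals = [column.cl(p) for p in members if p in column.measurements]
    if not vals:
        raise MissingPredictorError(
            f"{column.specimen_id}: no member of region {rid} is present",
            missing=members,
        )
    complete = all(
        p in column.measurements and not column.measurements[p].imputed
        for p in members
    )
    return PredictorValue(rid, float(np.mean(vals)), complete)


def series_sum(column: SpecimenColumn, series: str) -> PredictorValue:
    """Sum of CLs over a series; every member must be present.

    Incomplete series are refused (impute first) because a partial sum
    is biased low, unlike a partial mean.
    """
    sid = axial.normalize_predictor_id(series)
    members = SERIES[sid]
    absent = [p for p in members if p not in column.measurements]
    if absent:
        raise MissingPredictorError(
            f"{column.specimen_id}: series {sid} missing positions "
            f"{', '.join(absent)}",
            missing=absent,
        )
    complete = all(not column.measurements[p].imputed for p in members)
    total = float(sum(column.cl(p) for p in members))
    return PredictorValue(sid, total, complete)


def predictor_value(column: SpecimenColumn, predictor_id: str) -> PredictorValue:
    """Dispatch to :func:`region_mean` or :func:`series_sum` by id."""
    pid = axial.normalize_predictor_id(predictor_id)
    if pid in REGIONS:
        return region_mean(column, pid)
    return series_sum(column, pid)


def normalized_profile(columns: Iterable[SpecimenColumn]) -> pd.DataFrame:
    """Size-normalized CL profiles for individuals with complete columns.

    Each individual's CLs are divided by (its C2-Ca10 sum / the grand
    mean of those sums), so the mean normalized sum equals the grand
    mean of raw sums and profiles are comparable across body sizes.
    Returns a DataFrame indexed by position (craniocaudal order), one
    column per specimen.  Individuals with incomplete series are
    excluded with a warning.
    """
    usable, sums = [], []
    for col in columns:
        try:
            sums.append(series_sum(col, "C2-Ca10sum").value_mm)
            usable.append(col)
        except MissingPredictorError:
            warnings.warn(
                f"{col.specimen_id}: incomplete C2-Ca10 series; excluded "
                f"from normalized profile",
                stacklevel=2,
            )
    if not usable:
        raise MissingPredictorError("no individual has a complete C2-Ca10 series")
    grand_mean = float(np.mean(sums))
    data = {
        col.specimen_id: [col.cl(p) / (s / grand_mean) for p in POSITIONS]
        for col, s in zip(usable, sums)
    }
    return pd.DataFrame(data, index=list(POSITIONS))


# ---------------------------------------------------------------------------
# CSV I/O

REQUIRED_HEADERS = ("specimen_id", "species", "position", "cl_mm", "suture")
OPTIONAL_HEADERS = ("svl_mm", "tl_mm", "sex", "provenance")


def read_column_table(path, delimiter: str = ",") -> list[SpecimenColumn]:
    """Read specimen columns from a long-format delimited table.

    One row per (specimen, position); duplicate keys, unknown position
    labels, and non-positive CLs are hard errors naming the offending
    row.
    """
    df = pd.read_csv(path, sep=delimiter, dtype={"specimen_id": str, "species": str})
    missing = [h for h in REQUIRED_HEADERS if h not in df.columns]
    if missing:
        raise InvalidMeasurementError(
            f"{path}: missing required headers: {', '.join(missing)}"
        )
    specimens: dict[str, SpecimenColumn] = {}
    seen: set[tuple[str, str]] = set()
    for i, row in df.iterrows():
        sid = str(row["specimen_id"]).strip()
        pos = str(row["position"]).strip()
        check_position(pos)
        key = (sid, pos)
        if key in seen:
            raise DuplicateMeasurementError(
                f"{path} row {i + 2}: duplicate measurement for specimen "
                f"{sid!r} at position {pos!r}"
            )
        seen.add(key)
        cl = float(row["cl_mm"])
        if not cl > 0:
            raise InvalidMeasurementError(
                f"{path} row {i + 2}: non-positive CL {cl} for {sid} at {pos}"
            )
        imputed = bool(row.get("imputed", False)) if "imputed" in df.columns else False
        meas = CentrumMeasurement(pos, cl, parse_suture(row["suture"]), imputed)
        if sid not in specimens:
            def _opt(name):
                if name in df.columns and pd.notna(row.get(name)):
                    return float(row[name])
                return None

            def _meta(name, default="UNKNOWN"):
                if name in df.columns and pd.notna(row.get(name)):
                    return str(row[name]).strip().upper()
                return default

            specimens[sid] = SpecimenColumn(
                specimen_id=sid,
                species=str(row["species"]).strip(),
                sex=_meta("sex"),
                provenance=_meta("provenance"),
                svl_mm=_opt("svl_mm"),
                tl_mm=_opt("tl_mm"),
            )
        specimens[sid].measurements[pos] = meas
    return list(specimens.values())


def write_column_table(columns: Iterable[SpecimenColumn], path, delimiter: str = ",") -> None:
    """Write columns back to the canonical long CSV (6-decimal CLs)."""
    rows = []
    for col in columns:
        for pos in col.present_positions():
            m = col.measurements[pos]
            rows.append(
                {
                    "specimen_id": col.specimen_id,
                    "species": col.species,
                    "position": pos,
                    "cl_mm": round(m.centrum_length_mm, 6),
                    "suture": m.suture.value,
                    "imputed": m.imputed,
                    "svl_mm": None if col.svl_mm is None else round(col.svl_mm, 6),
                    "tl_mm": None if col.tl_mm is None else round(col.tl_mm, 6),
                    "sex": col.sex,
                    "provenance": col.provenance,
                }
            )
    pd.DataFrame(rows).to_csv(path, sep=delimiter, index=False)
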
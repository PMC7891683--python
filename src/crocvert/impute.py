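"""Proportional imputation of missing centrum lengths.

A missing CL at position *p* is estimated as

    CL(p) = CL_av(p) * (CL_sum.ind / CL_sum.av)

where CL_av is the per-position mean over conspecific (fallback:
congeneric) individuals with *complete* C2-Ca10 series, CL_sum.ind is
the sum of the individual's available CLs, and CL_sum.av is the sum of
the reference means over those same available positions.  The rule
rescales the reference profile to the individual's overall size; it is
exact when the individual is a uniform multiple of the reference.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Optional

import numpy as np

from .axial import POSITIONS
from .column import CentrumMeasurement, SpecimenColumn, SutureState
from .errors import MissingPredictorError, NoReferenceError


@dataclass(frozen=True)
class ReferenceProfile:
    """Per-position mean CLs of complete-series individuals of one taxon."""

    taxon: str
    level: str  # "SPECIES" | "GENUS"
    mean_cl_mm: Mapping[str, float]
    n_reference: int

    def __post_init__(self):
        if self.n_reference < 1:
            raise NoReferenceError(f"{self.taxon}: empty reference profile")

    def to_json(self, path) -> None:
        doc = {
            "taxon": self.taxon,
            "level": self.level,
            "mean_cl_mm": {p: self.mean_cl_mm[p] for p in POSITIONS},
            "n_reference": self.n_reference,
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(doc, fh, indent=2)
            fh.write("\n")

    @classmethod
    def from_json(cls, path) -> "ReferenceProfile":
        with open(path, encoding="utf-8") as fh:
            doc = json.load(fh)
        return cls(doc["taxon"], doc["level"], doc["mean_cl_mm"], doc["n_reference"])


def build_reference(
    columns: Iterable[SpecimenColumn], taxon: str, level: str = "SPECIES"
) -> ReferenceProfile:
    """Average the complete-series columns of ``taxon`` position-wise.

    ``level`` selects whether ``taxon`` is matched against the species
    name or the genus (first name token).
    """
    level = level.upper()
    if level not in ("SPECIES", "GENUS"):
        raise ValueError(f"level must be SPECIES or GENUS, got {level!r}")
    members = [
        c
        for c in columns
        if (c.species if level == "SPECIES" else c.genus) == taxon
        and c.is_complete("C2-Ca10sum")
    ]
    if not members:
        raise NoReferenceError(
            f"no complete-series individual of {level.lower()} {taxon!r}"
        )
    means = {
        p: float(np.mean([c.cl(p) for c in members])) for p in POSITIONS
    }
    return ReferenceProfile(taxon, level, means, len(members))


def find_reference(
    columns: Iterable[SpecimenColumn],
    column: SpecimenColumn,
    exclude_self: bool = True,
) -> ReferenceProfile:
    """Species-level reference, falling back to genus; no cross-genus use.

    The target individual itself never contributes to its reference.
    """
    pool = [
        c for c in columns if not (exclude_self and c.specimen_id == column.specimen_id)
    ]
    try:
        return build_reference(pool, column.species, "SPECIES")
    except NoReferenceError:
        try:
            return build_reference(pool, column.genus, "GENUS")
        except NoReferenceError:
            raise NoReferenceError(
                f"{column.specimen_id}: no complete-series conspecific "
                f"({column.species}) or congeneric ({column.genus}) reference; "
                f"use region means from the preserved vertebrae instead"
            ) from None


def impute_missing(
    column: SpecimenColumn,
    ref: ReferenceProfile,
    positions: Optional[Iterable[str]] = None,
) -> SpecimenColumn:
    """Fill missing positions by proportional scaling of ``ref``.

    ``positions`` restricts which absent positions are filled (default:
    all of them).  Measured values are untouched; imputed measurements
    carry ``imputed=True`` and suture UNKNOWN.  Imputing an already-
    complete column is a no-op.
    """
    present = column.present_positions()
    if not present:
        raise MissingPredictorError(
            f"{column.specimen_id}: no measured CL to anchor imputation"
        )
    missing = column.missing_positions()
    if positions is not None:
        wanted = set(positions)
        already = wanted & set(present)
        if already:
            raise ValueError(
                f"{column.specimen_id}: positions already measured: "
                f"{', '.join(sorted(already))}"
            )
        missing = [p for p in missing if p in wanted]
    if not missing:
        return column
    lacking = [p for p in present + missing if p not in ref.mean_cl_mm]
    if lacking:
        raise NoReferenceError(
            f"{column.specimen_id}: reference {ref.taxon!r} lacks positions "
            f"{', '.join(lacking)}"
        )
    sum_ind = sum(column.cl(p) for p in present)
    sum_av = sum(ref.mean_cl_mm[p] for p in present)
    scale = sum_ind / sum_av
    new = dict(column.measurements)
    for p in missing:
        new[p] = CentrumMeasurement(
            p, ref.mean_cl_mm[p] * scale, SutureState.UNKNOWN, imputed=True
        )
    return replace(column, measurements=new)


def impute_all(columns: list[SpecimenColumn]) -> list[SpecimenColumn]:
    """Impute every column against references built from the others.

    Columns without any usable reference are returned unchanged.
    """
    out = []
    for col in columns:
        if not col.missing_positions():
            out.append(col)
            continue
        try:
            ref = find_reference(columns, col)
            out.append(impute_missing(col, ref))
        except NoReferenceError:
            out.append(col)
    return out
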
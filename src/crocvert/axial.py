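"""Axial column nomenclature for crown-group crocodylians.

Crown crocodylians share a conserved precaudal vertebral formula (9
cervical, 15 dorsal, 2 sacral).  The measured column runs from the axis
(C2, the first position with a measurable centrum; the atlas C1 is not
modeled) to the 10th caudal, giving 35 positions in craniocaudal order:

    C2..C9 (8), D1..D15 (15), S1..S2 (2), Ca1..Ca10 (10)

Positions C2..S2 (axial indices 1..25) are *precaudal*; Ca1..Ca10
(indices 26..35) are *caudal*.  The distinction drives the maturity
logic: neurocentral sutures close sequentially from distal caudals
toward the axis, and closure of any precaudal suture marks osteological
maturity.

The 10-region / 4-series predictor scheme groups positions by ease of
identification and homogeneity of centrum length; region predictors are
*means* of member centrum lengths, series predictors are *sums*.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from functools import total_ordering

from .errors import UnknownPositionError

CERVICALS: tuple[str, ...] = tuple(f"C{i}" for i in range(2, 10))
DORSALS: tuple[str, ...] = tuple(f"D{i}" for i in range(1, 16))
SACRALS: tuple[str, ...] = ("S1", "S2")
CAUDALS: tuple[str, ...] = tuple(f"Ca{i}" for i in range(1, 11))

#: All measured positions, craniocaudal order (C2 first, Ca10 last).
POSITIONS: tuple[str, ...] = CERVICALS + DORSALS + SACRALS + CAUDALS
N_POSITIONS = len(POSITIONS)  # 35

#: 1-based axial index (C2 = 1 .. Ca10 = 35).
AXIAL_INDEX: dict[str, int] = {lab: i + 1 for i, lab in enumerate(POSITIONS)}

#: Number of precaudal positions (C2..S2).
N_PRECAUDAL = len(CERVICALS) + len(DORSALS) + len(SACRALS)  # 25


def is_valid_position(label: str) -> bool:
    return label in AXIAL_INDEX


def check_position(label: str) -> str:
    if label not in AXIAL_INDEX:
        raise UnknownPositionError(
            f"unknown vertebral position label {label!r}; expected one of C2..C9, "
            f"D1..D15, S1, S2, Ca1..Ca10"
        )
    return label


def is_precaudal(label: str) -> bool:
    return AXIAL_INDEX[check_position(label)] <= N_PRECAUDAL


def is_caudal(label: str) -> bool:
    return AXIAL_INDEX[check_position(label)] > N_PRECAUDAL


def is_sacral(label: str) -> bool:
    return label in SACRALS


@total_ordering
@dataclass(frozen=True)
class VertebralPosition:
    """A single axial position, ordered craniocaudally."""

    label: str

    def __post_init__(self):
        check_position(self.label)

    @property
    def axial_index(self) -> int:
        return AXIAL_INDEX[self.label]

    @property
    def precaudal(self) -> bool:
        return self.axial_index <= N_PRECAUDAL

    def __lt__(self, other: "VertebralPosition") -> bool:
        return self.axial_index < other.axial_index


def _span(start: str, stop: str) -> tuple[str, ...]:
    i, j = AXIAL_INDEX[start] - 1, AXIAL_INDEX[stop]
    return POSITIONS[i:j]


#: The 10 regions (predictor = mean CL of members).  Names follow the
#: published regression tables ("ave" marks multi-vertebra regions).
REGIONS: dict[str, tuple[str, ...]] = {
    "C2": ("C2",),
    "C3-7ave": _span("C3", "C7"),
    "C8-D2ave": _span("C8", "D2"),
    "D3-10ave": _span("D3", "D10"),
    "D11-14ave": _span("D11", "D14"),
    "D15": ("D15",),
    "S1-2ave": ("S1", "S2"),
    "Ca1": ("Ca1",),
    "Ca2-4ave": _span("Ca2", "Ca4"),
    "Ca5-10ave": _span("Ca5", "Ca10"),
}

#: The 4 series (predictor = sum of member CLs); all contiguous ranges.
SERIES: dict[str, tuple[str, ...]] = {
    "C2-9sum": _span("C2", "C9"),
    "D1-15sum": _span("D1", "D15"),
    "C2-D15sum": _span("C2", "D15"),
    "C2-Ca10sum": _span("C2", "Ca10"),
}

#: Regions with >= 2 member vertebrae (the 7 used for deviation stats).
MULTI_REGIONS: tuple[str, ...] = tuple(n for n, m in REGIONS.items() if len(m) > 1)

_DASHES = "–—−"  # en dash, em dash, minus


def normalize_predictor_id(name: str) -> str:
    """Map a predictor name to its canonical id.

    Accepts en dashes, missing "ave" suffixes on multi-vertebra regions
    (as printed in the species-maximum regression table, e.g. "S1-2"),
    and surrounding whitespace.
    """
    s = name.strip()
    for d in _DASHES:
        s = s.replace(d, "-")
    if s in REGIONS or s in SERIES:
        return s
    if not s.endswith(("ave", "sum")) and s + "ave" in REGIONS:
        return s + "ave"
    raise KeyError(f"unknown predictor id {name!r}")


def region_scheme_document() -> dict:
    """Static JSON-serializable description of the region/series scheme."""
    return {
        "positions": list(POSITIONS),
        "precaudal": list(POSITIONS[:N_PRECAUDAL]),
        "caudal": list(POSITIONS[N_PRECAUDAL:]),
        "regions": {k: list(v) for k, v in REGIONS.items()},
        "series": {k: list(v) for k, v in SERIES.items()},
        "region_statistic": "mean",
        "series_statistic": "sum",
    }


def export_region_scheme(path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(region_scheme_document(), fh, indent=2)
        fh.write("\n")
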
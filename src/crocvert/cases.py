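"""Reconstruction of fossil case specimens from the packaged case table.

The shipped fossil cases record each specimen's suture evidence
(anteriormost closed position, or the open positions when nothing is
closed), the predictor its preservation supports, and its absolute TL.
The raw centrum lengths of these specimens are not distributed, so a
case column is rebuilt by inverting the TL model at the recorded TL to
recover the predictor value, then spreading it uniformly over the
predictor's member positions.  Suture states follow the caudal-to-
cranial closure sequence around the recorded front.  The result feeds
the ordinary pipeline (maturity assessment, bound estimation) unchanged.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .axial import AXIAL_INDEX, REGIONS, SERIES, normalize_predictor_id
from .column import CentrumMeasurement, SpecimenColumn, SutureState


def column_from_case(row, predictor_value_mm: float) -> SpecimenColumn:
    """Build a specimen column for one fossil-case table row.

    ``predictor_value_mm`` is the region mean or series sum implied by
    the case's absolute TL (callers invert the matching TL model).
    """
    pid = normalize_predictor_id(row["predictor_id"])
    if pid in REGIONS:
        members = REGIONS[pid]
        per_member = float(predictor_value_mm)
    else:
        members = SERIES[pid]
        per_member = float(predictor_value_mm) / len(members)
    front = row.get("anteriormost_closed")
    has_front = isinstance(front, str) and front.strip()
    raw_open = row.get("open_positions")
    open_list = (
        [p.strip() for p in str(raw_open).split(";") if p.strip()]
        if isinstance(raw_open, str) and str(raw_open).strip()
        else []
    )
    measurements: dict[str, CentrumMeasurement] = {}
    if not has_front:
        # nothing closed: only the recorded open positions are preserved
        for p in open_list or members:
            measurements[p] = CentrumMeasurement(p, per_member, SutureState.OPEN)
    else:
        front_idx = AXIAL_INDEX[front.strip()]
        preserved = list(members)
        for extra in open_list + [front.strip()]:
            if extra not in preserved:
                preserved.append(extra)
        for p in preserved:
            state = (
                SutureState.CLOSED
                if AXIAL_INDEX[p] >= front_idx
                else SutureState.OPEN
            )
            measurements[p] = CentrumMeasurement(p, per_member, state)
    return SpecimenColumn(
        specimen_id=str(row["specimen_id"]),
        species=str(row["taxon"]),
        measurements=measurements,
    )
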
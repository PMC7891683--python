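"""Osteological maturity from neurocentral suture closure.

Neurocentral sutures close sequentially from distal caudal vertebrae
toward the axis during growth, and in extant crocodylians closure of
*precaudal* sutures begins only after sexual maturity.  A specimen with
any partially/fully closed precaudal suture is therefore osteologically
mature, and its centrum lengths bound the species maximum TL from
*above* (it could not have been smaller than the smallest mature
individual of its species).  Conversely, positive evidence that the
closure front has not reached the precaudals — an open sacral, or an
open caudal which implies open sacrals under the sequence — bounds the
maximum TL from *below*.  An isolated open dorsal or cervical is
uninformative (the front may sit anywhere behind it): INDETERMINATE.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Iterable, Optional

import numpy as np
import pandas as pd

from .axial import AXIAL_INDEX, MULTI_REGIONS, N_PRECAUDAL, POSITIONS, REGIONS
from .column import SpecimenColumn, SutureState
from .errors import NoAssessmentError, NoMatureIndividualError

#: TL gap cutoff for the smallest-mature species selection.
GAP_CUTOFF = 0.30


@dataclass(frozen=True)
class MaturityAssessment:
    specimen_id: str
    anteriormost_closed: Optional[str]
    osteologically_mature: str  # YES | NO | INDETERMINATE
    bound_type: str  # UPPER | LOWER | NONE
    sequence_violation: bool = False


@dataclass(frozen=True)
class SmallestMatureSelection:
    species: str
    specimen_id: str
    tl_mm: float
    qualifies: bool
    nearest_open_tl_mm: Optional[float]
    relative_gap: Optional[float]


def closure_sequence_violated(column: SpecimenColumn) -> bool:
    """True when some position has begun closing while a strictly more
    caudal observed position is still open (violating the caudal-to-
    cranial closure sequence)."""
    last_open_idx = -1
    for pos in reversed(POSITIONS):  # caudal to cranial
        st = column.suture(pos)
        if st is SutureState.UNKNOWN:
            continue
        idx = AXIAL_INDEX[pos]
        if st is SutureState.OPEN:
            last_open_idx = max(last_open_idx, idx)
        elif st.closure_begun and idx < last_open_idx:
            return True
    return False


def assess_maturity(column: SpecimenColumn) -> MaturityAssessment:
    """Classify osteological maturity and the max-TL bound direction.

    YES (UPPER bound) when any precaudal suture has begun closing; NO
    (LOWER bound) when all observed precaudals are open *and* an open
    sacral or open caudal shows the closure front has not reached them;
    otherwise INDETERMINATE (no bound).  Bound direction is a function
    of suture states only, never of size.
    """
    observed = {
        p: column.suture(p)
        for p in column.measurements
        if column.suture(p) is not SutureState.UNKNOWN
    }
    if not observed:
        raise NoAssessmentError(
            f"{column.specimen_id}: every suture state is unknown"
        )
    violation = closure_sequence_violated(column)
    if violation:
        warnings.warn(
            f"{column.specimen_id}: suture states violate the caudal-to-"
            f"cranial closure sequence; classifying by the precaudal rule",
            stacklevel=2,
        )
    closed = [p for p, s in observed.items() if s.closure_begun]
    anteriormost = min(closed, key=AXIAL_INDEX.get) if closed else None
    if anteriormost is not None and AXIAL_INDEX[anteriormost] <= N_PRECAUDAL:
        verdict, bound = "YES", "UPPER"
    else:
        open_sacral_or_caudal = any(
            s is SutureState.OPEN and AXIAL_INDEX[p] > AXIAL_INDEX["D15"]
            for p, s in observed.items()
        )
        precaudals_all_open = all(
            s is SutureState.OPEN
            for p, s in observed.items()
            if AXIAL_INDEX[p] <= N_PRECAUDAL
        )
        if precaudals_all_open and open_sacral_or_caudal:
            verdict, bound = "NO", "LOWER"
        else:
            verdict, bound = "INDETERMINATE", "NONE"
    return MaturityAssessment(
        specimen_id=column.specimen_id,
        anteriormost_closed=anteriormost,
        osteologically_mature=verdict,
        bound_type=bound,
        sequence_violation=violation,
    )


def _fully_open_precaudal(column: SpecimenColumn) -> bool:
    states = [
        column.suture(p)
        for p in column.measurements
        if AXIAL_INDEX[p] <= N_PRECAUDAL
        and column.suture(p) is not SutureState.UNKNOWN
    ]
    return bool(states) and all(s is SutureState.OPEN for s in states)


def select_smallest_mature(
    columns: Iterable[SpecimenColumn],
    tl_provider: Callable[[SpecimenColumn], float],
) -> SmallestMatureSelection:
    """Pick a species' smallest osteologically mature individual.

    ``columns`` are the individuals of a single species; ``tl_provider``
    supplies a TL (measured or estimated) per individual.  The selection
    qualifies for species-level modeling when the relative TL gap to the
    nearest-sized fully-open-precaudal individual is below 30% of the
    mature individual's TL.
    """
    columns = list(columns)
    if not columns:
        raise NoMatureIndividualError("empty species sample")
    species = columns[0].species
    mature = [c for c in columns if assess_maturity(c).osteologically_mature == "YES"]
    if not mature:
        raise NoMatureIndividualError(f"{species}: no osteologically mature individual")
    open_ind = [c for c in columns if _fully_open_precaudal(c)]
    smallest = min(mature, key=tl_provider)
    tl_m = float(tl_provider(smallest))
    if not open_ind:
        return SmallestMatureSelection(
            species, smallest.specimen_id, tl_m, False, None, None
        )
    nearest = min(open_ind, key=lambda c: abs(tl_provider(c) - tl_m))
    tl_o = float(tl_provider(nearest))
    gap = abs(tl_m - tl_o) / tl_m
    return SmallestMatureSelection(
        species, smallest.specimen_id, tl_m, gap < GAP_CUTOFF, tl_o, gap
    )


def maturity_ratio_summary(records: pd.DataFrame) -> tuple[float, float]:
    """Mean ratios of smallest-mature TL to male and female mature TLs.

    The male mean uses only rows whose male TL comes from the
    literature (``male_source == "literature"``); the female mean uses
    all rows.  Expects the species-reference column layout.
    """
    lit = records[records["male_source"].str.lower() == "literature"]
    male_mean = float(
        (lit["smallest_mature_tl_m"] / lit["male_mature_tl_m"]).mean()
    )
    female_mean = float(
        (records["smallest_mature_tl_m"] / records["female_mature_tl_m"]).mean()
    )
    return male_mean, female_mean


def male_tl_from_female(female_tl_mm: float, reference: pd.DataFrame) -> float:
    """Estimate a male mature TL from the female one.

    Multiplies by the mean male/female mature-TL ratio over reference
    rows whose male TL is literature-sourced.
    """
    lit = reference[reference["male_source"].str.lower() == "literature"]
    if lit.empty:
        raise ValueError("no literature-sourced male TLs in the reference rows")
    ratio = float((lit["male_mature_tl_m"] / lit["female_mature_tl_m"]).mean())
    return female_tl_mm * ratio


def region_deviation_stats(columns: Iterable[SpecimenColumn]) -> pd.DataFrame:
    """Mean % deviation of extreme CLs from the region mean.

    For every multi-vertebra region and individual with >= 2 member CLs:
    100*(mean - min)/mean and 100*(max - mean)/mean, averaged over
    individuals.  Quantifies the error committed when a single vertebra
    of uncertain position stands in for its region average.
    """
    columns = list(columns)
    rows = {}
    for region in MULTI_REGIONS:
        members = REGIONS[region]
        mins, maxs = [], []
        for col in columns:
            vals = [col.cl(p) for p in members if p in col.measurements]
            if len(vals) < 2:
                continue
            vals = np.asarray(vals, float)
            m = vals.mean()
            mins.append(100.0 * (m - vals.min()) / m)
            maxs.append(100.0 * (vals.max() - m) / m)
        if mins:
            rows[region] = {
                "min_deviation_pct": float(np.mean(mins)),
                "max_deviation_pct": float(np.mean(maxs)),
                "n_individuals": len(mins),
            }
    return pd.DataFrame.from_dict(rows, orient="index")
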
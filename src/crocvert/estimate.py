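"""End-to-end body-length estimators for fragmentary specimens.

Given a specimen's centrum lengths and suture states, this module picks
the best available predictor (preferring long series sums over single-
region means), evaluates the matching SVL/TL power laws for the absolute
lengths, and — when the suture evidence supports a bound direction —
evaluates the species-maximum-TL power law to bound the species maximum
size from above or below.  Two specimens can then be compared: if one
specimen's maximum-TL *upper* bound falls below another's absolute TL,
they cannot be conspecific.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np

from . import axial
from .column import SpecimenColumn, predictor_value
from .errors import BoundUnavailableError, MissingPredictorError
from .maturity import MaturityAssessment
from .registry import ModelRegistry
from .sma import bootstrap_prediction, predict

#: Series are preferred in this order; a series requires every member
#: position (imputation counts), else the best-populated region mean.
SERIES_PRIORITY = ("C2-D15sum", "D1-15sum", "C2-9sum")


@dataclass(frozen=True)
class LengthEstimate:
    specimen_id: str
    quantity: str  # SVL | TL | MAXTL_UPPER | MAXTL_LOWER
    value_mm: float
    ci: Optional[tuple[float, float]]
    predictor_id: str
    model_source: str

    @property
    def value_m(self) -> float:
        return self.value_mm / 1000.0


@dataclass(frozen=True)
class DiscriminationResult:
    verdict: str  # DISTINCT | COMPATIBLE
    ci_overlap: Optional[bool]  # caveat flag; None when either CI missing


def choose_predictor(
    column: SpecimenColumn, registry: Optional[ModelRegistry] = None
) -> str:
    """Select the predictor for a (possibly fragmentary) specimen.

    Priority: C2-D15sum > D1-15sum > C2-9sum (each requires all member
    positions, measured or imputed), then the region mean with the most
    *measured* members; ties break toward the region whose TL model has
    the higher published R^2.
    """
    present = set(column.present_positions())
    if not present:
        raise MissingPredictorError(f"{column.specimen_id}: nothing measured")
    for sid in SERIES_PRIORITY:
        if all(p in present for p in axial.SERIES[sid]):
            return sid
    measured = set(column.measured_positions())
    candidates = []
    for rid, members in axial.REGIONS.items():
        count = sum(1 for p in members if p in measured)
        if count:
            candidates.append((rid, count))
    if not candidates:
        # only imputed values exist; fall back to presence
        for rid, members in axial.REGIONS.items():
            count = sum(1 for p in members if p in present)
            if count:
                candidates.append((rid, count))
    best_count = max(c for _, c in candidates)
    tied = [rid for rid, c in candidates if c == best_count]
    if len(tied) == 1:
        return tied[0]
    if registry is None or not all(registry.has("TL", rid) for rid in tied):
        from .registry import load_published_models

        registry = load_published_models()
    return max(tied, key=lambda rid: registry.get("TL", rid).r_squared)


def _estimate_one(
    column: SpecimenColumn,
    response: str,
    quantity: str,
    pid: str,
    registry: ModelRegistry,
    n_boot: int,
    seed,
) -> LengthEstimate:
    pv = predictor_value(column, pid)
    model = registry.get(response, pid)
    value = predict(model, pv.value_mm)
    ci = None
    data = registry.training_data(response, pid)
    if data is not None and n_boot > 0:
        boot = bootstrap_prediction(
            data[0], data[1], pv.value_mm, n_reps=n_boot, seed=0 if seed is None else seed
        )
        ci = (boot.ci_low, boot.ci_high)
    return LengthEstimate(
        specimen_id=column.specimen_id,
        quantity=quantity,
        value_mm=float(value),
        ci=ci,
        predictor_id=pid,
        model_source=model.source,
    )


def estimate_absolute(
    column: SpecimenColumn,
    registry: ModelRegistry,
    n_boot: int = 0,
    seed: Optional[int] = None,
    predictor_id: Optional[str] = None,
) -> tuple[LengthEstimate, LengthEstimate]:
    """Absolute SVL and TL estimates for one specimen.

    Bootstrap CIs are attached only when the registry carries raw
    training data (fitted mode) and ``n_boot > 0``.
    """
    pid = (
        axial.normalize_predictor_id(predictor_id)
        if predictor_id
        else choose_predictor(column, registry)
    )
    svl = _estimate_one(column, "SVL", "SVL", pid, registry, n_boot, seed)
    tl = _estimate_one(column, "TL", "TL", pid, registry, n_boot, seed)
    return svl, tl


def estimate_max_tl(
    column: SpecimenColumn,
    assessment: MaturityAssessment,
    registry: ModelRegistry,
    n_boot: int = 0,
    seed: Optional[int] = None,
    predictor_id: Optional[str] = None,
) -> LengthEstimate:
    """Upper or lower bound on the species maximum TL.

    UPPER when the specimen is osteologically mature (its CLs are at
    least those of the species' smallest mature individual), LOWER when
    it is demonstrably immature.  Indeterminate maturity is refused.
    """
    if assessment.bound_type == "NONE":
        raise BoundUnavailableError(
            f"{column.specimen_id}: maturity is indeterminate (no closed "
            f"precaudal suture and no open sacral/caudal evidence), so the "
            f"species maximum TL cannot be bounded"
        )
    pid = (
        axial.normalize_predictor_id(predictor_id)
        if predictor_id
        else choose_predictor(column, registry)
    )
    quantity = "MAXTL_UPPER" if assessment.bound_type == "UPPER" else "MAXTL_LOWER"
    return _estimate_one(column, "MAXTL", quantity, pid, registry, n_boot, seed)


def discriminate_species(
    a: LengthEstimate, b: LengthEstimate
) -> DiscriminationResult:
    """Compare a MAXTL_UPPER bound (a) with an absolute TL (b).

    DISTINCT when a's maximum-TL upper bound is smaller than b's
    absolute TL — the two specimens cannot belong to one species.  When
    both carry CIs, their overlap is reported as a caveat flag.
    """
    if a.quantity != "MAXTL_UPPER":
        raise ValueError(f"first estimate must be MAXTL_UPPER, got {a.quantity}")
    if b.quantity != "TL":
        raise ValueError(f"second estimate must be TL, got {b.quantity}")
    if a.specimen_id == b.specimen_id:
        raise ValueError("estimates must come from different specimens")
    verdict = "DISTINCT" if a.value_mm < b.value_mm else "COMPATIBLE"
    overlap = None
    if a.ci is not None and b.ci is not None:
        overlap = a.ci[0] <= b.ci[1] and b.ci[0] <= a.ci[1]
    return DiscriminationResult(verdict=verdict, ci_overlap=overlap)


def svl_tl_convert(value_mm: float, coefficients: Optional[dict]) -> float:
    """Apply a user-supplied SVL<->TL conversion.

    ``coefficients`` is ``{"form": "linear", "a": ..., "b": ...}`` for
    a*x + b, or ``{"form": "power", "coefficient": ..., "exponent": ...}``
    for c*x^e.  No defaults are packaged; conversion coefficients must
    come from the literature appropriate to the taxon.
    """
    if not coefficients:
        raise ValueError(
            "no SVL-TL conversion coefficients supplied; provide literature "
            "values as {'form': 'linear'|'power', ...}"
        )
    form = coefficients.get("form")
    if form == "linear":
        return coefficients["a"] * value_mm + coefficients.get("b", 0.0)
    if form == "power":
        return coefficients["coefficient"] * value_mm ** coefficients["exponent"]
    raise ValueError(f"unknown conversion form {form!r}")


def species_max_tl_interval(
    estimates: Iterable[LengthEstimate],
) -> tuple[Optional[float], Optional[float], bool]:
    """Combine multiple specimens' bounds into one species interval.

    Returns (low, high, consistent): low = max of LOWER bounds, high =
    min of UPPER bounds (None when absent); ``consistent`` is False when
    the interval is empty.
    """
    lowers = [e.value_mm for e in estimates if e.quantity == "MAXTL_LOWER"]
    uppers = [e.value_mm for e in estimates if e.quantity == "MAXTL_UPPER"]
    low = max(lowers) if lowers else None
    high = min(uppers) if uppers else None
    consistent = not (low is not None and high is not None and low > high)
    return low, high, consistent
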
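"""Model registry: published coefficients and fitting from training data.

The package ships a transcription of published SMA coefficients for
extant crocodylians:

* ``SVL`` and ``TL`` against the 13 region/series predictors, fitted on
  30 individuals with body-length records;
* species maximum TL (``MAXTL``) against the same predictors measured on
  the smallest osteologically mature individual of each of 13 species;
* two whole-column power laws against the C2-Ca10 CL sum,
  SVL = 1.329 x^0.980 and TL = 2.504 x^0.983 (stored as original-scale
  coefficients so their elevations are exact log10 values).

Published coefficients are applied at their printed 3-decimal precision;
chained predictions can drift by up to ~0.5% relative to the source
values.  A :class:`ModelRegistry` can equally be *fitted* from a user or
synthetic training table, in which case the raw (x, y) pairs are kept so
prediction intervals can be bootstrapped.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from . import axial
from .column import SpecimenColumn, predictor_value
from .errors import InsufficientDataError, DegenerateFitError
from .sma import PowerLawModel, fit_sma

RESPONSES = ("SVL", "TL", "MAXTL")
#: The 13 predictors used by the published regressions (regions + series
#: except the whole-column sum, which only backs the two text equations).
TABLE_PREDICTORS: tuple[str, ...] = tuple(axial.REGIONS) + (
    "C2-9sum",
    "D1-15sum",
    "C2-D15sum",
)


def _data_path(name: str):
    return resources.files("crocvert").joinpath("data", name)


@dataclass
class ModelRegistry:
    """Lookup of power-law models keyed by (response, predictor_id).

    ``training`` optionally maps the same keys to the raw (x, y) arrays
    behind a fitted model, enabling bootstrap prediction intervals.
    """

    models: dict[tuple[str, str], PowerLawModel] = field(default_factory=dict)
    training: dict[tuple[str, str], tuple[np.ndarray, np.ndarray]] = field(
        default_factory=dict
    )

    def add(self, model: PowerLawModel, x=None, y=None) -> None:
        key = (model.response, model.predictor_id)
        self.models[key] = model
        if x is not None and y is not None:
            self.training[key] = (np.asarray(x, float), np.asarray(y, float))

    def get(self, response: str, predictor_id: str) -> PowerLawModel:
        key = (response.upper(), axial.normalize_predictor_id(predictor_id))
        try:
            return self.models[key]
        except KeyError:
            raise KeyError(
                f"no {key[0]} model for predictor {key[1]!r} in registry"
            ) from None

    def has(self, response: str, predictor_id: str) -> bool:
        try:
            self.get(response, predictor_id)
            return True
        except KeyError:
            return False

    def training_data(self, response: str, predictor_id: str):
        key = (response.upper(), axial.normalize_predictor_id(predictor_id))
        return self.training.get(key)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "response": m.response,
                "predictor_id": m.predictor_id,
                "elevation": m.elevation,
                "slope": m.slope,
                "r_squared": m.r_squared,
                "p_value": m.p_value,
                "slope_ci_low": m.slope_ci[0],
                "slope_ci_high": m.slope_ci[1],
                "n": m.n,
                "source": m.source,
            }
            for m in self.models.values()
        ]
        return pd.DataFrame(rows)


def load_published_models() -> ModelRegistry:
    """Load the packaged transcription of the published coefficients."""
    df = pd.read_csv(_data_path("published_models.csv"))
    reg = ModelRegistry()
    for _, row in df.iterrows():
        if pd.notna(row.get("coefficient")):
            elevation = float(np.log10(row["coefficient"]))
        else:
            elevation = float(row["elevation"])
        ci_low = row.get("slope_ci_low")
        ci_high = row.get("slope_ci_high")
        ci = (
            float(ci_low) if pd.notna(ci_low) else float("nan"),
            float(ci_high) if pd.notna(ci_high) else float("nan"),
        )
        r2 = float(row["r_squared"]) if pd.notna(row.get("r_squared")) else float("nan")
        reg.add(
            PowerLawModel(
                response=str(row["response"]),
                predictor_id=axial.normalize_predictor_id(row["predictor_id"]),
                elevation=elevation,
                slope=float(row["slope"]),
                r_squared=r2,
                p_value=float(row["p_value_max"]),
                slope_ci=ci,
                n=int(row["n"]),
                source="PUBLISHED",
            )
        )
    return reg


def fit_absolute_registry(
    columns: Iterable[SpecimenColumn],
    responses: tuple[str, ...] = ("SVL", "TL"),
    predictors: tuple[str, ...] = TABLE_PREDICTORS + ("C2-Ca10sum",),
    require_complete: bool = True,
) -> ModelRegistry:
    """Fit SVL/TL models from individuals carrying body-length records.

    For each predictor, individuals contribute when the predictor is
    computable (and complete, unless ``require_complete=False``) and the
    response is recorded.  Predictors with fewer than 3 usable rows are
    skipped with a warning.
    """
    columns = list(columns)
    reg = ModelRegistry()
    for response in responses:
        attr = "svl_mm" if response.upper() == "SVL" else "tl_mm"
        for pid in predictors:
            xs, ys = [], []
            for col in columns:
                yv = getattr(col, attr)
                if yv is None:
                    continue
                try:
                    pv = predictor_value(col, pid)
                except Exception:
                    continue
                if require_complete and not pv.complete:
                    continue
                xs.append(pv.value_mm)
                ys.append(yv)
            if len(xs) < 3:
                warnings.warn(
                    f"skipping {response}~{pid}: only {len(xs)} usable rows",
                    stacklevel=2,
                )
                continue
            try:
                model = fit_sma(xs, ys, response=response.upper(), predictor_id=pid)
            except (DegenerateFitError, InsufficientDataError) as err:
                warnings.warn(f"skipping {response}~{pid}: {err}", stacklevel=2)
                continue
            reg.add(model, xs, ys)
    return reg


def fit_max_tl_registry(
    smallest_mature_columns: Iterable[SpecimenColumn],
    species_max_tl_mm: dict[str, float],
    predictors: tuple[str, ...] = TABLE_PREDICTORS,
) -> ModelRegistry:
    """Fit species-level MAXTL models.

    ``smallest_mature_columns`` holds one column per species (its
    smallest osteologically mature individual); the response is the
    species maximum TL in mm.
    """
    cols = list(smallest_mature_columns)
    reg = ModelRegistry()
    for pid in predictors:
        xs, ys = [], []
        for col in cols:
            if col.species not in species_max_tl_mm:
                continue
            try:
                pv = predictor_value(col, pid)
            except Exception:
                continue
            xs.append(pv.value_mm)
            ys.append(species_max_tl_mm[col.species])
        if len(xs) < 3:
            warnings.warn(
                f"skipping MAXTL~{pid}: only {len(xs)} usable species",
                stacklevel=2,
            )
            continue
        try:
            model = fit_sma(xs, ys, response="MAXTL", predictor_id=pid)
        except (DegenerateFitError, InsufficientDataError) as err:
            warnings.warn(f"skipping MAXTL~{pid}: {err}", stacklevel=2)
            continue
        reg.add(model, xs, ys)
    return reg


def load_species_reference() -> pd.DataFrame:
    """Packaged per-species reference sizes (13 extant species).

    Columns: species, specimen_id, smallest_mature_svl_m,
    smallest_mature_tl_m, male_mature_tl_m, male_source
    (literature/estimated), female_mature_tl_m, max_tl_m.
    """
    return pd.read_csv(_data_path("species_reference.csv"))


def load_fossil_cases() -> pd.DataFrame:
    """Packaged fossil specimen cases (suture evidence + absolute TL)."""
    return pd.read_csv(_data_path("fossil_cases.csv"))


def load_vertebral_counts() -> pd.DataFrame:
    """Static survey of regional vertebral counts across crocodyliforms."""
    return pd.read_csv(_data_path("vertebral_counts.csv"))
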
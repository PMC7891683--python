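import numpy as np
import pytest

from crocvert.axial import POSITIONS
from crocvert.column import CentrumMeasurement, SpecimenColumn, SutureState
from crocvert.registry import load_published_models, load_species_reference
from crocvert.simulate import DEFAULT_PROFILE


def make_column(
    specimen_id="X1",
    species="Synthosuchus demo",
    scale=1000.0,
    positions=None,
    suture=SutureState.OPEN,
    svl_mm=None,
    tl_mm=None,
    cls=None,
):
    """Build a column from the default profile (ΣCL = ``scale`` mm).

    ``suture`` may be a state applied everywhere or a callable
    position -> state; ``cls`` overrides per-position CLs.
    """
    keep = set(positions) if positions is not None else set(POSITIONS)
    meas = {}
    for i, p in enumerate(POSITIONS):
        if p not in keep:
            continue
        cl = cls[p] if cls is not None else float(DEFAULT_PROFILE[i] * scale)
        st = suture(p) if callable(suture) else suture
        meas[p] = CentrumMeasurement(p, cl, st)
    return SpecimenColumn(
        specimen_id=specimen_id,
        species=species,
        svl_mm=svl_mm,
        tl_mm=tl_mm,
        measurements=meas,
    )


@pytest.fixture(scope="session")
def published_registry():
    return load_published_models()


@pytest.fixture(scope="session")
def species_reference():
    return load_species_reference()


@pytest.fixture()
def complete_column():
    return make_column()


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260927)
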
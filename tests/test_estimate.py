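"""Predictor choice, published-coefficient chains, bounds, discrimination."""

import numpy as np
import pytest

from crocvert.axial import POSITIONS, REGIONS, SERIES
from crocvert.column import SutureState
from crocvert.errors import BoundUnavailableError, MissingPredictorError
from crocvert.estimate import (
    LengthEstimate,
    choose_predictor,
    discriminate_species,
    estimate_absolute,
    estimate_max_tl,
    species_max_tl_interval,
    svl_tl_convert,
)
from crocvert.maturity import assess_maturity
from crocvert.registry import fit_absolute_registry
from crocvert.sma import inverse_predict
from crocvert.simulate import SyntheticWorldConfig, simulate_population

from conftest import make_column
from test_maturity import closure_front


class TestChoosePredictor:
    def test_complete_precaudal_column_uses_long_series(self):
        col = make_column()
        assert choose_predictor(col) == "C2-D15sum"

    def test_dorsals_only_uses_dorsal_series(self):
        col = make_column(positions=SERIES["D1-15sum"])
        assert choose_predictor(col) == "D1-15sum"

    def test_cervicals_only_uses_cervical_series(self):
        col = make_column(positions=SERIES["C2-9sum"])
        assert choose_predictor(col) == "C2-9sum"

    def test_mid_dorsals_only_uses_region_mean(self):
        col = make_column(positions=["D5", "D6", "D7"])
        assert choose_predictor(col) == "D3-10ave"

    def test_sacrals_only_uses_sacral_mean(self):
        col = make_column(positions=["S1", "S2"])
        assert choose_predictor(col) == "S1-2ave"

    def test_tie_broken_by_published_tl_r_squared(self, published_registry):
        # one vertebra each from two regions; D3-10ave (R2 .972) beats
        # C3-7ave (R2 .962)
        col = make_column(positions=["C5", "D5"])
        assert choose_predictor(col, published_registry) == "D3-10ave"

    def test_empty_column_refused(self):
        col = make_column(positions=["C2"])
        col.measurements.clear()
        with pytest.raises(MissingPredictorError):
            choose_predictor(col)


class TestPublishedChains:
    """Chained inverse/forward predictions through the shipped registry."""

    def _uniform_series_column(self, registry, response, series, value_mm, **kw):
        members = SERIES[series]
        per = value_mm / len(members)
        return make_column(
            positions=members, cls={p: per for p in members}, **kw
        )

    def test_porosus_svl_to_tl_chain(self, published_registry):
        # smallest mature C. porosus: SVL 1.82 m -> ΣCL -> TL 3.51 m
        x = inverse_predict(published_registry.get("SVL", "C2-Ca10sum"), 1820.0)
        col = self._uniform_series_column(
            published_registry, "TL", "C2-Ca10sum", x
        )
        svl, tl = estimate_absolute(
            col, published_registry, predictor_id="C2-Ca10sum"
        )
        assert round(tl.value_m, 2) == 3.51
        assert round(svl.value_m, 2) == 1.82
        assert tl.model_source == "PUBLISHED" and tl.ci is None

    def test_gavialis_svl_to_tl_chain(self, published_registry):
        x = inverse_predict(published_registry.get("SVL", "C2-Ca10sum"), 1640.0)
        col = self._uniform_series_column(published_registry, "TL", "C2-Ca10sum", x)
        _, tl = estimate_absolute(col, published_registry, predictor_id="C2-Ca10sum")
        assert round(tl.value_m, 2) == 3.16

    def test_toyotamaphimeia_upper_bound_chain(self, published_registry):
        # TL 6.32 m with closed axis -> max TL < 13.50 m via C2-D15 sum
        x = inverse_predict(published_registry.get("TL", "C2-D15sum"), 6320.0)
        col = make_column(
            positions=SERIES["C2-D15sum"],
            cls={p: x / 23 for p in SERIES["C2-D15sum"]},
            suture=closure_front("C2"),
        )
        bound = estimate_max_tl(col, assess_maturity(col), published_registry)
        assert bound.quantity == "MAXTL_UPPER"
        assert bound.value_m == pytest.approx(13.50, rel=0.01)

    def test_pachycheilosuchus_upper_bound_chain(self, published_registry):
        # dwarf form: TL 1.15 m, S1 closed, sacral mean predictor
        x = inverse_predict(published_registry.get("TL", "S1-2ave"), 1150.0)
        assert x == pytest.approx(16.12, abs=0.01)
        col = make_column(
            positions=["S1", "S2"],
            cls={"S1": x, "S2": x},
            suture=closure_front("S1"),
        )
        bound = estimate_max_tl(col, assess_maturity(col), published_registry)
        assert bound.value_m == pytest.approx(1.69, rel=0.01)

    def test_lower_bound_direction_for_immature_specimen(self, published_registry):
        col = make_column(suture=closure_front("Ca1"))
        bound = estimate_max_tl(col, assess_maturity(col), published_registry)
        assert bound.quantity == "MAXTL_LOWER"

    def test_indeterminate_specimen_refused(self, published_registry):
        col = make_column(positions=["D3"], suture=SutureState.OPEN)
        with pytest.raises(BoundUnavailableError, match="indeterminate"):
            estimate_max_tl(col, assess_maturity(col), published_registry)


class TestFittedChainConsistency:
    def test_every_predictor_agrees_on_noiseless_individual(self):
        """With exact generative structure all 13 predictors give the
        same TL (within the regional-variation budget of a few %)."""
        cfg = SyntheticWorldConfig(noise_cv=0.0, missingness_rate=0.0, seed=5)
        columns, _ = simulate_population(cfg)
        reg = fit_absolute_registry(columns[::2])
        probe = columns[1]
        estimates = []
        for pid in list(REGIONS) + ["C2-9sum", "D1-15sum", "C2-D15sum"]:
            _, tl = estimate_absolute(probe, reg, predictor_id=pid)
            estimates.append(tl.value_mm)
        spread = (max(estimates) - min(estimates)) / np.mean(estimates)
        assert spread < 0.06
        assert np.mean(estimates) == pytest.approx(probe.tl_mm, rel=0.01)

    def test_fitted_registry_attaches_bootstrap_ci(self):
        cfg = SyntheticWorldConfig(
            n_species=4, n_individuals=24, missingness_rate=0.0, seed=9
        )
        columns, _ = simulate_population(cfg)
        reg = fit_absolute_registry(columns)
        _, tl = estimate_absolute(columns[0], reg, n_boot=100, seed=3)
        assert tl.ci is not None and tl.ci[0] <= tl.value_mm <= tl.ci[1]


class TestDiscrimination:
    def _est(self, quantity, mm, sid="A", ci=None):
        return LengthEstimate(sid, quantity, mm, ci, "C2-D15sum", "PUBLISHED")

    def test_upper_bound_below_other_tl_distinguishes_species(self):
        a = self._est("MAXTL_UPPER", 3630.0, "A", ci=(3360.0, 3990.0))
        b = self._est("TL", 3870.0, "B", ci=(3710.0, 4000.0))
        res = discriminate_species(a, b)
        assert res.verdict == "DISTINCT"
        assert res.ci_overlap is True  # caveat: intervals overlap

    def test_equal_values_compatible(self):
        res = discriminate_species(
            self._est("MAXTL_UPPER", 2000.0, "A"), self._est("TL", 2000.0, "B")
        )
        assert res.verdict == "COMPATIBLE" and res.ci_overlap is None

    def test_large_upper_bound_compatible(self):
        res = discriminate_species(
            self._est("MAXTL_UPPER", 10000.0, "A"), self._est("TL", 2000.0, "B")
        )
        assert res.verdict == "COMPATIBLE"

    def test_wrong_quantities_rejected(self):
        with pytest.raises(ValueError):
            discriminate_species(
                self._est("TL", 1000.0, "A"), self._est("TL", 2000.0, "B")
            )


class TestConversionAndIntervals:
    def test_linear_conversion(self):
        assert svl_tl_convert(1000.0, {"form": "linear", "a": 2.0}) == 2000.0

    def test_identity_conversion(self):
        assert svl_tl_convert(123.0, {"form": "linear", "a": 1.0}) == 123.0

    def test_power_round_trip(self):
        fwd = {"form": "power", "coefficient": 2.1, "exponent": 1.02}
        inv = {"form": "power", "coefficient": 2.1 ** (-1 / 1.02), "exponent": 1 / 1.02}
        out = svl_tl_convert(svl_tl_convert(900.0, fwd), inv)
        assert out == pytest.approx(900.0, rel=1e-9)

    def test_missing_coefficients_refused(self):
        with pytest.raises(ValueError, match="literature"):
            svl_tl_convert(1000.0, None)

    def test_species_interval_combines_bounds(self):
        ests = [
            LengthEstimate("A", "MAXTL_LOWER", 7540.0, None, "C2-D15sum", "PUBLISHED"),
            LengthEstimate("B", "MAXTL_UPPER", 13500.0, None, "C2-D15sum", "PUBLISHED"),
        ]
        low, high, ok = species_max_tl_interval(ests)
        assert (low, high, ok) == (7540.0, 13500.0, True)

    def test_inconsistent_interval_flagged(self):
        ests = [
            LengthEstimate("A", "MAXTL_LOWER", 9000.0, None, "C2-D15sum", "PUBLISHED"),
            LengthEstimate("B", "MAXTL_UPPER", 5000.0, None, "C2-D15sum", "PUBLISHED"),
        ]
        assert species_max_tl_interval(ests)[2] is False
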
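"""Suture-based maturity classification, selection, and ratio summaries."""

import numpy as np
import pandas as pd
import pytest

from crocvert.axial import POSITIONS, AXIAL_INDEX
from crocvert.column import SutureState
from crocvert.errors import NoAssessmentError, NoMatureIndividualError
from crocvert.maturity import (
    assess_maturity,
    male_tl_from_female,
    maturity_ratio_summary,
    region_deviation_stats,
    select_smallest_mature,
)

from conftest import make_column


def closure_front(anteriormost):
    """States for a column whose closure front sits at ``anteriormost``:
    that position and everything caudal is closed, all else open."""
    front = AXIAL_INDEX[anteriormost]
    return lambda p: (
        SutureState.CLOSED if AXIAL_INDEX[p] >= front else SutureState.OPEN
    )


class TestAssessMaturity:
    def test_sacral_closure_gives_upper_bound(self):
        # B. wilsoni pattern: anteriormost closed suture at S1
        col = make_column(suture=closure_front("S1"))
        a = assess_maturity(col)
        assert a.anteriormost_closed == "S1"
        assert a.osteologically_mature == "YES"
        assert a.bound_type == "UPPER"

    def test_caudal_closure_with_open_precaudals_gives_lower_bound(self):
        # C. affinis pattern: Ca1 closed, every precaudal open
        col = make_column(suture=closure_front("Ca1"))
        a = assess_maturity(col)
        assert a.anteriormost_closed == "Ca1"
        assert a.osteologically_mature == "NO"
        assert a.bound_type == "LOWER"

    def test_isolated_open_dorsal_is_indeterminate(self):
        # Deinosuchus pattern: a single anterior dorsal, suture open
        col = make_column(positions=["D3"], suture=SutureState.OPEN)
        a = assess_maturity(col)
        assert a.osteologically_mature == "INDETERMINATE"
        assert a.bound_type == "NONE"
        assert a.anteriormost_closed is None

    def test_open_sacral_alone_is_positive_immaturity_evidence(self):
        col = make_column(positions=["D5", "S1"], suture=SutureState.OPEN)
        a = assess_maturity(col)
        assert a.osteologically_mature == "NO" and a.bound_type == "LOWER"

    def test_closed_caudal_without_sacral_evidence_is_indeterminate(self):
        states = {"D5": SutureState.OPEN, "Ca3": SutureState.CLOSED}
        col = make_column(positions=list(states), suture=lambda p: states[p])
        a = assess_maturity(col)
        assert a.osteologically_mature == "INDETERMINATE"

    def test_partial_counts_as_closure(self):
        states = {"S1": SutureState.PARTIAL, "Ca1": SutureState.CLOSED}
        col = make_column(positions=list(states), suture=lambda p: states[p])
        assert assess_maturity(col).osteologically_mature == "YES"

    def test_all_unknown_refused(self):
        col = make_column(suture=SutureState.UNKNOWN)
        with pytest.raises(NoAssessmentError):
            assess_maturity(col)

    def test_verdict_independent_of_size(self):
        small = make_column(scale=100.0, suture=closure_front("S1"))
        big = make_column(scale=5000.0, suture=closure_front("S1"))
        assert assess_maturity(small) == assess_maturity(big)

    def test_sequence_violation_flagged_but_classified(self):
        # D5 closed while the more caudal Ca3 is still open
        states = {"D5": SutureState.CLOSED, "Ca3": SutureState.OPEN}
        col = make_column(positions=list(states), suture=lambda p: states[p])
        with pytest.warns(UserWarning, match="sequence"):
            a = assess_maturity(col)
        assert a.sequence_violation
        assert a.osteologically_mature == "YES"


class TestSelectSmallestMature:
    @staticmethod
    def _species(mature_tls, open_tls):
        cols = []
        for i, tl in enumerate(mature_tls):
            cols.append(
                make_column(
                    specimen_id=f"M{i}", suture=closure_front("S1"), tl_mm=tl * 1000
                )
            )
        for i, tl in enumerate(open_tls):
            cols.append(
                make_column(
                    specimen_id=f"O{i}", suture=SutureState.OPEN, tl_mm=tl * 1000
                )
            )
        return cols

    def test_small_gap_qualifies(self):
        cols = self._species([2.6, 2.53], [2.4])
        sel = select_smallest_mature(cols, lambda c: c.tl_mm)
        assert sel.specimen_id == "M1"
        assert sel.tl_mm == pytest.approx(2530)
        assert sel.relative_gap == pytest.approx(0.051383, rel=1e-4)
        assert sel.qualifies

    def test_large_gap_disqualifies(self):
        sel = select_smallest_mature(
            self._species([3.0], [2.0]), lambda c: c.tl_mm
        )
        assert sel.relative_gap == pytest.approx(1.0 / 3.0)
        assert not sel.qualifies

    def test_species_without_mature_individual_skipped(self):
        with pytest.raises(NoMatureIndividualError):
            select_smallest_mature(self._species([], [2.0]), lambda c: c.tl_mm)


class TestRatioSummaries:
    def test_packaged_reference_reproduces_published_means(self, species_reference):
        male, female = maturity_ratio_summary(species_reference)
        assert round(male, 2) == 1.09
        assert round(female, 2) == 1.27

    def test_unit_ratios(self):
        df = pd.DataFrame(
            {
                "smallest_mature_tl_m": [1.0, 2.0],
                "male_mature_tl_m": [1.0, 2.0],
                "female_mature_tl_m": [1.0, 2.0],
                "male_source": ["literature", "literature"],
            }
        )
        assert maturity_ratio_summary(df) == (pytest.approx(1.0), pytest.approx(1.0))

    def test_single_literature_row(self):
        df = pd.DataFrame(
            {
                "smallest_mature_tl_m": [1.56],
                "male_mature_tl_m": [1.3],
                "female_mature_tl_m": [1.2],
                "male_source": ["literature"],
            }
        )
        male, female = maturity_ratio_summary(df)
        assert male == pytest.approx(1.2)
        assert female == pytest.approx(1.3)


class TestMaleFromFemale:
    @pytest.mark.parametrize(
        "female_m,expected_m",
        [(2.05, 2.38), (0.88, 1.02), (2.50, 2.90)],
    )
    def test_packaged_reference_estimates(
        self, species_reference, female_m, expected_m
    ):
        est = male_tl_from_female(female_m, species_reference)
        assert round(est, 2) == expected_m

    def test_single_reference_ratio(self):
        df = pd.DataFrame(
            {
                "male_mature_tl_m": [1.5],
                "female_mature_tl_m": [1.0],
                "male_source": ["literature"],
            }
        )
        assert male_tl_from_female(1.0, df) == pytest.approx(1.5)

    def test_empty_reference_refused(self):
        df = pd.DataFrame(
            {
                "male_mature_tl_m": [1.5],
                "female_mature_tl_m": [1.0],
                "male_source": ["estimated"],
            }
        )
        with pytest.raises(ValueError):
            male_tl_from_female(1.0, df)


class TestRegionDeviation:
    def test_constant_region_deviates_zero(self):
        cls = {p: 12.0 for p in ("S1", "S2")}
        col = make_column(positions=list(cls), cls=cls)
        stats = region_deviation_stats([col])
        assert stats.loc["S1-2ave", "min_deviation_pct"] == pytest.approx(0.0)
        assert stats.loc["S1-2ave", "max_deviation_pct"] == pytest.approx(0.0)

    def test_hand_worked_trio(self):
        cls = {"Ca2": 9.0, "Ca3": 10.0, "Ca4": 11.0}
        col = make_column(positions=list(cls), cls=cls)
        stats = region_deviation_stats([col])
        assert stats.loc["Ca2-4ave", "min_deviation_pct"] == pytest.approx(10.0)
        assert stats.loc["Ca2-4ave", "max_deviation_pct"] == pytest.approx(10.0)

    def test_only_multi_vertebra_regions_reported(self, complete_column):
        stats = region_deviation_stats([complete_column])
        assert set(stats.index) <= {
            "C3-7ave", "C8-D2ave", "D3-10ave", "D11-14ave", "S1-2ave",
            "Ca2-4ave", "Ca5-10ave",
        }
        assert len(stats) == 7
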
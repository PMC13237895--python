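"""CTI instrument: scoring, bands, weights, and inter-rater reliability."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from lhsdrive.cti import (BAND_NAMES, DOMAINS, DomainWeights, RaterSheet,
                          aggregate_raters, classify_cti_band, composite_cti,
                          default_weights, equity_forward_weights,
                          normalize_rating, reliability_report, score_sheets,
                          weighted_kappa)
from lhsdrive.errors import UndefinedStatisticError, ValidationError

from conftest import kappa_oracle


def sheet(ratings, rater="A", pid="P1", period="Q1"):
    return RaterSheet(pid, period, rater, tuple(ratings))


class TestScoring:
    @pytest.mark.parametrize("r,expected", [(4, 1.0), (0, 0.0), (3, 0.75),
                                            (1, 0.25), (2, 0.5)])
    def test_normalize_is_quarter_steps(self, r, expected):
        assert normalize_rating(r) == expected

    def test_normalize_rejects_out_of_rubric(self):
        with pytest.raises(ValidationError, match="P9.*D3.*C"):
            normalize_rating(5, project_id="P9", domain="D3", rater="C")

    def test_aggregate_is_mean_of_three_raters(self):
        trio = [sheet([0] * 8, "A"), sheet([2] * 8, "H"), sheet([4] * 8, "C")]
        scores = aggregate_raters(trio)
        assert scores == pytest.approx((0.5,) * 8)  # (0 + .5 + 1)/3

    def test_aggregate_unanimity_and_constant(self):
        assert aggregate_raters([sheet([4] * 8, r) for r in "AHC"]) == (1.0,) * 8
        assert aggregate_raters([sheet([2] * 8, r) for r in "AHC"]) == (0.5,) * 8

    @pytest.mark.parametrize("bad", [
        [sheet([1] * 8, "A"), sheet([1] * 8, "A"), sheet([1] * 8, "C")],  # dup
        [sheet([1] * 8, "A"), sheet([1] * 8, "H")],                       # missing
        [sheet([1] * 8, "A"), sheet([1] * 8, "H"),
         sheet([1] * 8, "C", pid="P2")],                                  # mixed
    ])
    def test_aggregate_rejects_bad_trios(self, bad):
        with pytest.raises(ValidationError):
            aggregate_raters(bad)

    def test_composite_weighted_sum_worked_example(self):
        # unanimous ratings (4,3,2,3,4,2,3,1) under default weights
        trio = [sheet([4, 3, 2, 3, 4, 2, 3, 1], r) for r in "AHC"]
        cti = composite_cti(aggregate_raters(trio), default_weights())
        assert cti == pytest.approx(0.71)

    def test_composite_endpoints(self):
        w = default_weights()
        assert composite_cti((1.0,) * 8, w) == pytest.approx(1.0)
        assert composite_cti((0.0,) * 8, w) == 0.0

    def test_weights_must_sum_to_one(self):
        with pytest.raises(ValidationError, match="sum to 1"):
            DomainWeights((0.2,) * 8)

    @given(st.lists(st.integers(0, 4), min_size=8, max_size=8),
           st.integers(0, 7))
    def test_composite_monotone_in_every_rating(self, ratings, d):
        """Raising any single rating never lowers the composite."""
        if ratings[d] == 4:
            ratings = ratings.copy()
            ratings[d] = 3
        bumped = ratings.copy()
        bumped[d] += 1
        w = default_weights()
        lo = composite_cti(aggregate_raters([sheet(ratings, r) for r in "AHC"]), w)
        hi = composite_cti(aggregate_raters(
            [sheet(bumped if r == "A" else ratings, r) for r in "AHC"]), w)
        assert hi >= lo
        assert 0.0 <= lo <= 1.0 and 0.0 <= hi <= 1.0


class TestWeights:
    def test_equity_forward_values(self):
        w = equity_forward_weights().as_mapping()
        assert w == pytest.approx({"D1": 0.16, "D2": 0.075, "D3": 0.09,
                                   "D4": 0.075, "D5": 0.16, "D6": 0.12,
                                   "D7": 0.12, "D8": 0.20})

    def test_presets_sum_to_one(self):
        assert sum(default_weights().w) == pytest.approx(1.0, abs=1e-9)
        assert sum(equity_forward_weights().w) == pytest.approx(1.0, abs=1e-9)


class TestBands:
    @pytest.mark.parametrize("cti,band", [
        (0.0, "Transactional"), (0.25, "Advisory"), (0.4999, "Advisory"),
        (0.5, "Collaborative"), (0.7, "SharedGovernance"),
        (0.85, "CommunityAnchored"), (1.0, "CommunityAnchored"),
    ])
    def test_cut_points(self, cti, band):
        assert classify_cti_band(cti) == band

    def test_out_of_range_rejected(self):
        for bad in (-0.01, 1.01):
            with pytest.raises(ValidationError):
                classify_cti_band(bad)

    @given(st.floats(0.0, 1.0, allow_nan=False))
    def test_partition_no_gaps_no_overlaps(self, x):
        labels = [b for b in BAND_NAMES if b == classify_cti_band(x)]
        assert len(labels) == 1


class TestKappa:
    def test_perfect_agreement(self):
        assert weighted_kappa([0, 1, 2, 3, 4], [0, 1, 2, 3, 4]) == pytest.approx(1.0)

    def test_perfect_disagreement_quadratic(self):
        k = weighted_kappa([0, 4, 0, 4], [4, 0, 4, 0], "quadratic")
        assert k == pytest.approx(-1.0)
        assert k == pytest.approx(kappa_oracle([0, 4, 0, 4], [4, 0, 4, 0]))

    def test_constant_raters_signaled_undefined(self):
        with pytest.raises(UndefinedStatisticError):
            weighted_kappa([2, 2, 2], [2, 2, 2])

    @pytest.mark.parametrize("scheme", ["linear", "quadratic"])
    def test_matches_contingency_oracle_on_random_inputs(self, scheme, rng):
        """Implementation agrees with the direct O(k^2) summation
        oracle to 1e-12 across random small rating vectors."""
        for _ in range(200):
            n = rng.integers(2, 30)
            x = rng.integers(0, 5, size=n)
            y = rng.integers(0, 5, size=n)
            expected = kappa_oracle(x, y, scheme)
            if expected is None:
                with pytest.raises(UndefinedStatisticError):
                    weighted_kappa(x, y, scheme)
            else:
                assert weighted_kappa(x, y, scheme) == pytest.approx(
                    expected, abs=1e-12)


class TestReliabilityReport:
    def test_identical_raters_all_ones_no_flags(self, rng):
        sheets = []
        for p in range(4):
            ratings = tuple(int(r) for r in rng.integers(0, 5, size=8))
            for r in "AHC":
                sheets.append(sheet(ratings, r, pid=f"P{p}"))
        rep = reliability_report(sheets)
        assert rep.flags == []
        finite = [v for v in rep.kappas.values() if np.isfinite(v)]
        assert finite and all(v == pytest.approx(1.0) for v in finite)
        assert rep.below_target() == []

    def test_spread_of_two_flags_domain(self):
        base = [1] * 8
        trio = [sheet(base, "A"), sheet(base, "H"), sheet(base, "C")]
        spread = [sheet([0] + base[1:], "A", pid="P2"),
                  sheet([4] + base[1:], "H", pid="P2"),
                  sheet([2] + base[1:], "C", pid="P2")]
        rep = reliability_report(trio + spread)
        assert ("P2", "D1") in rep.flags
        assert all(f[0] != "P1" for f in rep.flags)

    def test_below_target_marked(self):
        # two raters who systematically disagree across projects
        sheets = []
        rng = np.random.default_rng(5)
        for p in range(12):
            a = rng.integers(0, 5, size=8)
            b = (4 - a) % 5  # adversarial
            sheets.append(sheet(tuple(int(x) for x in a), "A", pid=f"P{p}"))
            sheets.append(sheet(tuple(int(x) for x in b), "H", pid=f"P{p}"))
        rep = reliability_report(sheets, threshold=0.75)
        assert rep.below_target()  # at least one pair/domain under target

    def test_single_rater_rejected(self):
        with pytest.raises(ValidationError):
            reliability_report([sheet([1] * 8, "A")])


def test_score_sheets_orders_and_bands():
    trio = lambda pid, vals: [sheet(vals, r, pid=pid) for r in "AHC"]
    results = score_sheets(trio("B", [4] * 8) + trio("A", [0] * 8))
    assert [r.project_id for r in results] == ["A", "B"]
    assert results[0].band == "Transactional"
    assert results[1].band == "CommunityAnchored"
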
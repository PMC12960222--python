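"""Quasi-case-control enrichment: Haldane OR, CI strength mapping,
prevalence intervals, pairwise Fisher/BH, and ancestry-matched PS4."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from ddx41kit.cohort import Diagnosis
from ddx41kit.enrichment import (
    AncestryPolicy,
    ContingencyTable,
    OrResult,
    haldane_or,
    pairwise_fisher_bh,
    prevalence_ci,
    strength_from_lower_ci,
    variant_ps4,
)
from ddx41kit.evidence import Strength

from conftest import make_case, missense


class TestHaldaneOr:
    def test_published_germline_somatic_association(self):
        r = haldane_or(ContingencyTable(800, 538, 139, 32499))
        assert round(r.or_point) == 346
        # printed CI 282-428 as a sanity corridor (within 2% on both bounds)
        assert r.ci_low == pytest.approx(282, rel=0.02)
        assert r.ci_high == pytest.approx(428, rel=0.02)

    def test_symmetric_table_is_unity(self):
        assert haldane_or(ContingencyTable(10, 10, 10, 10)).or_point == 1.0

    def test_zero_cell_closed_form(self):
        r = haldane_or(ContingencyTable(5, 0, 1, 99))
        assert r.or_point == pytest.approx((5.5 * 99.5) / (0.5 * 1.5), rel=1e-12)
        assert r.or_point == pytest.approx(729.7, abs=0.05)

    def test_on_zero_mode_leaves_positive_tables_uncorrected(self):
        r = haldane_or(ContingencyTable(20, 10, 5, 40), correction="on_zero")
        assert r.or_point == pytest.approx((20 * 40) / (10 * 5))

    def test_none_mode_fails_on_zero_denominator_cell(self):
        with pytest.raises(ZeroDivisionError):
            haldane_or(ContingencyTable(5, 0, 1, 99), correction="none")

    def test_invalid_table_rejected(self):
        with pytest.raises(ValueError):
            ContingencyTable(0, 0, 5, 5)

    @settings(derandomize=True, deadline=None, max_examples=100)
    @given(
        a=st.integers(0, 50), b=st.integers(0, 50),
        c=st.integers(0, 50), d=st.integers(0, 50),
    )
    def test_exposure_flip_inverts_or(self, a, b, c, d):
        if a + b == 0 or c + d == 0:
            return
        r1 = haldane_or(ContingencyTable(a, b, c, d))
        r2 = haldane_or(ContingencyTable(c, d, a, b))
        assert r1.or_point * r2.or_point == pytest.approx(1.0, rel=1e-12)

    def test_ci_coverage_near_nominal(self):
        """Simulated 2x2 tables with a known odds ratio: the 95% interval
        should cover the truth at close to nominal rate (500 replicates)."""
        rng = np.random.default_rng(11)
        true_or = 3.0
        p_ctl = 0.2
        p_case = true_or * 0.25 / (1 + true_or * 0.25)  # odds 0.25 * OR
        n = 200
        hits = 0
        reps = 500
        for _ in range(reps):
            a = rng.binomial(n, p_case)
            c = rng.binomial(n, p_ctl)
            r = haldane_or(ContingencyTable(a, n - a, c, n - c))
            hits += r.ci_low <= true_or <= r.ci_high
        coverage = hits / reps
        se = math.sqrt(0.95 * 0.05 / reps)
        assert abs(coverage - 0.95) < 4 * se


class TestStrengthMapping:
    @pytest.mark.parametrize(
        "ci_low,expected",
        [
            (18.7, Strength.STRONG),
            (2.08, Strength.SUPPORTING),
            (1.0, Strength.NOT_MET),
            (4.33, Strength.MODERATE),
            (350.0, Strength.VERY_STRONG),
            (349.99, Strength.STRONG),
        ],
    )
    def test_lower_bound_bands(self, ci_low, expected):
        r = OrResult(or_point=max(ci_low, 1.0) * 2, ci_low=ci_low, ci_high=1e9)
        assert strength_from_lower_ci(r) is expected

    def test_monotone_in_lower_bound(self):
        order = []
        for ci_low in np.linspace(0.5, 400, 200):
            r = OrResult(or_point=500.0, ci_low=float(ci_low), ci_high=1e9)
            order.append(strength_from_lower_ci(r))
        ranks = [
            [Strength.NOT_MET, Strength.SUPPORTING, Strength.MODERATE,
             Strength.STRONG, Strength.VERY_STRONG].index(s)
            for s in order
        ]
        assert ranks == sorted(ranks)


class TestPrevalence:
    def test_published_mds_aml_prevalences(self):
        point, _, _ = prevalence_ci(1366, 34051)
        assert round(point * 100, 1) == 4.0
        point, low, high = prevalence_ci(1083, 34051)
        assert round(point * 100, 1) == 3.2
        assert round(low * 100, 1) == 3.0
        assert round(high * 100, 1) == 3.4

    def test_zero_successes(self):
        point, low, _ = prevalence_ci(0, 10)
        assert point == 0.0 and low == 0.0

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            prevalence_ci(1, 0)
        with pytest.raises(ValueError):
            prevalence_ci(5, 3)


def _fisher_enumeration_p(a, b, c, d):
    """Two-sided Fisher p by exhaustive hypergeometric enumeration:
    sum of outcomes with point probability <= that of the observed table."""
    r1, n, k = a + b, a + b + c + d, a + c
    support = np.arange(max(0, k - (n - r1)), min(k, r1) + 1)
    pmf = stats.hypergeom.pmf(support, n, r1, k)
    p_obs = stats.hypergeom.pmf(a, n, r1, k)
    return float(pmf[pmf <= p_obs * (1 + 1e-7)].sum())


class TestPairwiseFisherBh:
    def test_identical_groups_give_p_one(self):
        m = pairwise_fisher_bh([(3, 10), (3, 10)])
        assert m[0, 1] == 1.0 and m[0, 0] == 1.0

    def test_single_pair_matches_enumeration(self):
        m = pairwise_fisher_bh([(3, 10), (7, 10)])
        assert m[0, 1] == pytest.approx(_fisher_enumeration_p(3, 7, 7, 3), rel=1e-9)

    def test_fisher_equals_enumeration_for_all_small_margins(self):
        """Exhaustive check on every 2x2 table with both row margins <= 15."""
        for r1, r2 in itertools.product(range(1, 16), repeat=2):
            for a in range(r1 + 1):
                for c in range(r2 + 1):
                    _, p = stats.fisher_exact(
                        [[a, r1 - a], [c, r2 - c]], alternative="two-sided"
                    )
                    p_enum = _fisher_enumeration_p(a, r1 - a, c, r2 - c)
                    assert p == pytest.approx(p_enum, rel=1e-7), (a, r1, c, r2)

    def test_bh_adjustment_matches_step_up_by_hand(self):
        groups = [(1, 40), (10, 40), (20, 40), (39, 40)]
        m = pairwise_fisher_bh(groups)
        pairs = list(itertools.combinations(range(4), 2))
        raw = [
            stats.fisher_exact(
                [[groups[i][0], groups[i][1] - groups[i][0]],
                 [groups[j][0], groups[j][1] - groups[j][0]]],
                alternative="two-sided",
            )[1]
            for i, j in pairs
        ]
        mtests = len(raw)
        order = np.argsort(raw)
        adjusted = np.empty(mtests)
        running_min = 1.0
        for rank_from_top in range(mtests - 1, -1, -1):
            idx = order[rank_from_top]
            running_min = min(running_min, raw[idx] * mtests / (rank_from_top + 1))
            adjusted[idx] = running_min
        for (i, j), adj in zip(pairs, adjusted):
            assert m[i, j] == pytest.approx(min(adj, 1.0), rel=1e-9)

    def test_matrix_is_symmetric(self):
        m = pairwise_fisher_bh([(1, 20), (5, 20), (15, 20)])
        assert np.allclose(m, m.T)

    def test_needs_two_groups(self):
        with pytest.raises(ValueError):
            pairwise_fisher_bh([(3, 10)])


def _controls(rows):
    return pd.DataFrame(rows, columns=["variant", "ancestry", "ac", "an"])


class TestVariantPs4:
    def _cases(self, key, ancestries):
        gv = missense(key)
        return [
            make_case(f"c{i}", germline=[gv], ancestry=anc)
            for i, anc in enumerate(ancestries)
        ]

    def test_eas_founder_downgraded_to_matched_strength(self):
        """Carriers concentrated in EAS where the allele is common: the
        pooled OR is strong but the EAS-matched OR is weaker, and the final
        strength is the matched one."""
        key = "A500FS"
        cases = self._cases(key, ["EAS"] * 8 + ["NFE"] * 2)
        controls = _controls(
            [(key, "EAS", 60, 40_000), (key, "NFE", 1, 1_000_000)]
        )
        policy = AncestryPolicy(total_cases=30_000, case_totals={"EAS": 6_000})
        res = variant_ps4(key, cases, controls, policy)
        assert res.dominant_ancestry == "EAS" and res.dominant_share == 0.8
        assert res.final_strength is res.by_ancestry["EAS"].strength
        assert (
            res.by_ancestry["EAS"].or_point < res.overall.or_point
        ), "matching should shrink the founder-inflated OR"

    def test_final_equals_min_of_overall_and_matched(self):
        key = "E256K"
        cases = self._cases(key, ["EAS"] * 9 + ["NFE"])
        controls = _controls([(key, "EAS", 260, 40_000), (key, "NFE", 0, 1_000_000)])
        policy = AncestryPolicy(total_cases=30_000, case_totals={"EAS": 6_000})
        res = variant_ps4(key, cases, controls, policy)
        ranks = [Strength.NOT_MET, Strength.SUPPORTING, Strength.MODERATE,
                 Strength.STRONG, Strength.VERY_STRONG]
        assert ranks.index(res.final_strength) == min(
            ranks.index(res.overall.strength),
            ranks.index(res.by_ancestry["EAS"].strength),
        )

    def test_evenly_split_carriers_keep_overall_strength(self):
        key = "Q208E"
        cases = self._cases(key, ["NFE"] * 5 + ["EAS"] * 5)
        controls = _controls([(key, "NFE", 2, 1_000_000), (key, "EAS", 1, 40_000)])
        policy = AncestryPolicy(total_cases=30_000)
        res = variant_ps4(key, cases, controls, policy)
        assert res.final_strength is res.overall.strength

    def test_excluded_diagnoses_do_not_enter_tables(self):
        key = "Q208E"
        gv = missense(key)
        cases = [
            make_case("a", germline=[gv], ancestry="NFE"),
            make_case("b", germline=[gv], ancestry="NFE", diagnosis=Diagnosis.EXCLUDED),
        ]
        controls = _controls([(key, "NFE", 5, 1_000_000)])
        res = variant_ps4(key, cases, controls, AncestryPolicy(total_cases=30_000))
        assert res.n_carriers == 1

    def test_zero_control_an_raises(self):
        key = "Q208E"
        cases = self._cases(key, ["NFE"] * 3)
        controls = _controls([(key, "NFE", 0, 0)])
        with pytest.raises(ValueError):
            variant_ps4(key, cases, controls, AncestryPolicy(total_cases=30_000))
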
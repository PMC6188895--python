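import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tsaorta.aortic import AorticMeasure, SubjectRecord, Vessel, expected_dimension, invert_z
from tsaorta.risk import (
    ContingencyTable,
    association_test,
    combinatorial_analysis,
    logistic_or,
    odds_ratio,
    attribute_profile,
    reconstruct_total,
    two_sample_t,
)


class TestOddsRatio:
    @pytest.mark.parametrize(
        "cells,expected",
        [
            ((81, 72, 7, 28), 4.50),    # BAV by TIMP1 copy group
            ((28, 66, 1, 23), 9.76),    # BAV with TAD by TIMP1 copy group
            ((9, 9, 20, 80), 4.00),     # BAV with TAD by rs11547635
            ((21, 6, 66, 95), 5.04),    # BAV by rs11547635
            ((43, 110, 1, 34), 13.29),  # lymphedema by TIMP1 copy group
            ((44, 109, 1, 34), 13.72),  # coarctation by TIMP1 copy group
        ],
    )
    def test_published_two_decimal_values(self, cells, expected):
        res = odds_ratio(ContingencyTable(*cells))
        assert round(res.or_point, 2) == expected
        assert not res.corrected

    def test_symmetric_table_is_one(self):
        assert odds_ratio(ContingencyTable(1, 1, 1, 1)).or_point == 1.0

    def test_woolf_interval_brackets_point(self):
        res = odds_ratio(ContingencyTable(20, 30, 10, 40))
        assert res.ci_low < res.or_point < res.ci_high

    def test_zero_cell_gets_haldane_correction(self):
        res = odds_ratio(ContingencyTable(6, 147, 0, 35))
        assert res.corrected
        assert res.or_point == pytest.approx((6.5 * 35.5) / (147.5 * 0.5), rel=1e-12)

    def test_zero_diagonal_undefined(self):
        res = odds_ratio(ContingencyTable(0, 5, 3, 0))
        assert res.undefined and math.isnan(res.or_point)

    @given(
        a=st.integers(1, 50), b=st.integers(1, 50),
        c=st.integers(1, 50), d=st.integers(1, 50),
    )
    @settings(max_examples=100, deadline=None)
    def test_orientation_inversion(self, a, b, c, d):
        t = ContingencyTable(a, b, c, d)
        assert odds_ratio(t).or_point * odds_ratio(t.swapped()).or_point == pytest.approx(
            1.0, rel=1e-12
        )


def fisher_oracle(a, b, c, d):
    """Two-sided Fisher p by exhaustive hypergeometric enumeration."""
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def prob(x):
        return (
            math.comb(r1, x) * math.comb(r2, c1 - x) / math.comb(n, c1)
        )

    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    p_obs = prob(a)
    return sum(prob(x) for x in range(lo, hi + 1) if prob(x) <= p_obs * (1 + 1e-9))


class TestAssociationTest:
    def test_large_table_uses_yates_chi2(self):
        p, test = association_test(ContingencyTable(81, 72, 7, 28))
        assert test == "chi2_yates"
        assert p < 0.005

    def test_sparse_table_uses_fisher(self):
        p, test = association_test(ContingencyTable(1, 26, 5, 156))
        assert test == "fisher"
        assert p > 0.99  # dissection row: no association

    @pytest.mark.parametrize(
        "cells",
        [(2, 8, 5, 5), (1, 9, 3, 12), (0, 10, 4, 6), (3, 3, 3, 3)],
    )
    def test_fisher_matches_enumeration(self, cells):
        t = ContingencyTable(*cells)
        p, test = association_test(t)
        if test == "fisher":
            assert p == pytest.approx(fisher_oracle(*cells), rel=1e-9)

    def test_expected_count_rule(self):
        # expected cell = row*col/total; smallest here is 10*5/53 < 5
        t = ContingencyTable(2, 8, 3, 40)
        _, test = association_test(t)
        assert test == "fisher"
        # all expected counts >= 5 -> chi-squared path
        t2 = ContingencyTable(2, 25, 11, 22)
        _, test2 = association_test(t2)
        assert test2 == "chi2_yates"


class TestTwoSampleT:
    def test_identical_groups(self):
        p, diff = two_sample_t([1.0, 2, 3], [1.0, 2, 3])
        assert diff == 0.0 and p == pytest.approx(1.0)

    def test_matches_hand_computed_pooled_formula(self):
        g1, g2 = [1.0, 2.0, 3.0], [2.0, 4.0, 6.0]
        p, diff = two_sample_t(g1, g2)
        m1, m2 = np.mean(g1), np.mean(g2)
        s2 = (np.var(g1, ddof=1) * 2 + np.var(g2, ddof=1) * 2) / 4
        t_stat = (m1 - m2) / math.sqrt(s2 * (1 / 3 + 1 / 3))
        from scipy import stats as ss

        assert diff == pytest.approx(m1 - m2)
        assert p == pytest.approx(2 * ss.t.sf(abs(t_stat), 4), rel=1e-12)

    def test_bav_z_shift_recovered_at_scale(self, rng):
        bav = rng.normal(1.29, 1.59, size=40_000)
        none = rng.normal(0.31, 1.08, size=40_000)
        p, diff = two_sample_t(bav, none)
        assert diff == pytest.approx(0.98, abs=0.03)
        assert p < 1e-10


class TestLogisticOr:
    def test_equals_cross_product_on_reference_table(self):
        # reconstruct subject-level data for (81, 72, 7, 28)
        predictor = [True] * 153 + [False] * 35
        outcome = [True] * 81 + [False] * 72 + [True] * 7 + [False] * 28
        res = logistic_or(predictor, outcome)
        assert res.or_point == pytest.approx(4.50, abs=1e-6)

    @given(
        a=st.integers(2, 30), b=st.integers(2, 30),
        c=st.integers(2, 30), d=st.integers(2, 30),
    )
    @settings(max_examples=25, deadline=None)
    def test_agrees_with_cross_product_generally(self, a, b, c, d):
        predictor = [True] * (a + b) + [False] * (c + d)
        outcome = [True] * a + [False] * b + [True] * c + [False] * d
        res = logistic_or(predictor, outcome)
        assert res.or_point == pytest.approx((a * d) / (b * c), rel=1e-5)

    def test_wald_interval_matches_reference(self):
        predictor = [True] * 20 + [False] * 20
        outcome = [True] * 12 + [False] * 8 + [True] * 5 + [False] * 15
        res = logistic_or(predictor, outcome)
        se = math.sqrt(1 / 12 + 1 / 8 + 1 / 5 + 1 / 15)
        log_or = math.log((12 * 15) / (8 * 5))
        assert res.ci_low == pytest.approx(math.exp(log_or - 1.96 * se), rel=1e-3)
        assert res.ci_high == pytest.approx(math.exp(log_or + 1.96 * se), rel=1e-3)

    def test_null_predictor_near_one_at_scale(self, rng):
        predictor = rng.random(20_000) < 0.5
        outcome = rng.random(20_000) < 0.3
        res = logistic_or(predictor.tolist(), outcome.tolist())
        assert res.or_point == pytest.approx(1.0, abs=0.12)

    def test_separation_reported_undefined(self):
        res = logistic_or([True] * 5 + [False] * 5, [True] * 5 + [False] * 5)
        assert res.undefined


def _make_subject(i, bav, one_copy, carrier, z=None, measured=True):
    s = SubjectRecord(
        id=f"c{i}", bav=bav, height_cm=145, weight_kg=55,
        timp1_copies=1.0 if one_copy else 2.0,
        timp3_rs11547635_carrier=carrier,
    )
    if measured:
        bsa = s.bsa_m2
        exp = expected_dimension(bsa, Vessel.AR)
        s.ar = AorticMeasure(Vessel.AR, invert_z(z if z is not None else 0.0, exp), bsa)
    return s


class TestCombinatorial:
    def _cohort_from_counts(self, groups, z_for_affected=None):
        """groups: {(snp, one_copy): (n_affected, n_total)}"""
        subjects = []
        i = 0
        for (snp, one_copy), (aff, total) in groups.items():
            for j in range(total):
                bav = j < aff
                z = z_for_affected if bav else 0.0
                subjects.append(_make_subject(i, bav, one_copy, snp, z=z))
                i += 1
        return subjects

    def test_bav_with_tad_reference_odds_ratio(self):
        # affected subjects carry dilated roots so BAV-with-TAD counts equal
        # the BAV counts: ref 2/22 vs SNP+1-copy 9/16 gives OR 12.86
        cohort = self._cohort_from_counts(
            {(False, False): (2, 22), (False, True): (20, 78),
             (True, False): (0, 2), (True, True): (9, 16)},
            z_for_affected=2.5,
        )
        groups = combinatorial_analysis(cohort, outcome="bav_with_tad")
        by_label = {g.label: g for g in groups}
        res = by_label["SNP/1 copy"].odds_ratio
        assert round(res.or_point, 2) == 12.86

    def test_bav_outcome_single_copy_group(self):
        cohort = self._cohort_from_counts(
            {(False, False): (6, 33), (False, True): (60, 128),
             (True, False): (1, 2), (True, True): (20, 25)}
        )
        groups = combinatorial_analysis(cohort, outcome="bav")
        by_label = {g.label: g for g in groups}
        assert round(by_label["no-SNP/1 copy"].odds_ratio.or_point, 2) == 3.97
        assert round(by_label["SNP/1 copy"].odds_ratio.or_point, 2) == 18.00
        # the tiny SNP/>1-copy group gets no estimate
        assert by_label["SNP/>1 copy"].odds_ratio is None

    def test_null_prevalences_give_unit_ors(self):
        cohort = self._cohort_from_counts(
            {(False, False): (20, 100), (False, True): (20, 100),
             (True, False): (20, 100), (True, True): (20, 100)}
        )
        groups = combinatorial_analysis(cohort, outcome="bav")
        for g in groups:
            if g.odds_ratio is not None:
                assert g.odds_ratio.or_point == pytest.approx(1.0, rel=1e-9)

    def test_empty_reference_aborts(self):
        cohort = self._cohort_from_counts({(True, True): (5, 10)})
        with pytest.raises(ValueError, match="reference"):
            combinatorial_analysis(cohort, outcome="bav")

    def test_reconstruct_total_from_percent(self):
        assert reconstruct_total(20, 80.0) == 25
        assert reconstruct_total(6, 18.18) == 33


class TestAttributeProfile:
    def test_rows_reflect_missingness(self):
        subjects = [
            _make_subject(0, True, True, True),
            _make_subject(1, False, False, False),
            _make_subject(2, True, True, False),
            _make_subject(3, False, False, True),
        ]
        subjects[0].lymphedema = True
        subjects[1].lymphedema = False
        # others missing lymphedema
        table = attribute_profile(subjects, "timp1")
        row = table[table.attribute == "Lymphedema"].iloc[0]
        assert row.n == 2

    def test_null_cohort_log_or_centered_at_zero(self):
        # attributes drawn independently of the stratifier: over replicates
        # the mean log OR must be near zero
        from tsaorta.synthetic import EffectConfig, simulate_cohort

        cfg = EffectConfig(
            or_timp1_single_copy=1.0, or_timp3_carrier=1.0, or_interaction=1.0
        )
        logs = []
        for rep in range(30):
            cohort = simulate_cohort(250, cfg, seed=rep)
            table = attribute_profile(cohort.subjects, "timp1")
            row = table[table.attribute == "BAV"].iloc[0]
            if np.isfinite(row.odds_ratio) and row.odds_ratio > 0:
                logs.append(math.log(row.odds_ratio))
        assert abs(np.mean(logs)) < 0.15
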
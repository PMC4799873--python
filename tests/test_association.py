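"""Allele proportions, Z-test/Wald CI, Fisher exact and Bengtsson–Thomson delta."""

import itertools
import math

import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import hypergeom

from founderage.association import (
    DeltaUndefinedError,
    allele_proportions,
    association_table,
    bootstrap_delta_ci,
    bt_delta,
    diff_proportions_test,
    fisher_exact,
)


class TestAlleleProportions:
    @pytest.mark.parametrize(
        "marker, allele, expected",
        [
            ("DXS1108", 171, (23, 24, 29, 96)),
            ("DXS7423", 189, (18, 24, 15, 96)),
            ("DXS1073", 128, (21, 24, 16, 96)),
            ("DXS7423", 999, (0, 24, 0, 96)),  # allele absent everywhere
        ],
    )
    def test_fixture_counts(self, cohort, marker, allele, expected):
        assert allele_proportions(cohort, marker, allele) == expected

    def test_unknown_marker(self, cohort):
        with pytest.raises(KeyError):
            allele_proportions(cohort, "DXS0000", 100)


class TestDiffProportions:
    def test_wald_ci_dxs1073(self):
        dp, lo, hi, p = diff_proportions_test(21, 24, 16, 96)
        assert dp == pytest.approx(0.708, abs=0.0015)
        assert lo == pytest.approx(0.556, abs=0.0015)
        assert hi == pytest.approx(0.860, abs=0.0015)
        assert p < 0.0001

    def test_wald_ci_dxs7423(self):
        # direct Wald evaluation, before any truncation of third decimals
        dp, lo, hi, _ = diff_proportions_test(18, 24, 15, 96)
        assert dp == pytest.approx(0.59375)
        assert lo == pytest.approx(0.406, abs=0.0015)
        assert hi == pytest.approx(0.782, abs=0.0015)

    def test_equal_proportions(self):
        dp, lo, hi, p = diff_proportions_test(12, 24, 48, 96)
        assert dp == 0.0
        assert p == pytest.approx(1.0)
        assert lo <= dp <= hi

    def test_zero_denominator_rejected(self):
        with pytest.raises(ZeroDivisionError):
            diff_proportions_test(0, 0, 1, 10)


class TestBtDelta:
    @pytest.mark.parametrize(
        "counts, expected",
        [
            ((23, 24, 29, 96), 0.940),
            ((22, 24, 80, 96), 0.500),
            ((18, 24, 15, 96), 0.704),
        ],
    )
    def test_printed_values(self, counts, expected):
        assert bt_delta(*counts) == pytest.approx(expected, abs=5e-4)

    def test_complete_association(self):
        # p_D = 1 makes numerator equal denominator regardless of p_N
        assert bt_delta(10, 10, 3, 10) == pytest.approx(1.0)

    def test_fixed_control_allele_undefined(self):
        with pytest.raises(DeltaUndefinedError):
            bt_delta(5, 10, 10, 10)

    def test_negative_when_allele_rarer_in_disease(self):
        assert bt_delta(1, 10, 5, 10) < 0

    @given(
        k_D=st.integers(0, 24),
        k_N=st.integers(0, 95),
        factor=st.integers(1, 7),
    )
    def test_invariant_to_cohort_scaling(self, k_D, k_N, factor):
        a = bt_delta(k_D, 24, k_N, 96)
        b = bt_delta(k_D * factor, 24 * factor, k_N * factor, 96 * factor)
        assert a == pytest.approx(b, rel=1e-12)

    @given(k_N=st.integers(0, 90), data=st.data())
    def test_strictly_increasing_in_p_D(self, k_N, data):
        k1 = data.draw(st.integers(0, 95))
        k2 = data.draw(st.integers(k1 + 1, 96))
        assert bt_delta(k1, 96, k_N, 96) < bt_delta(k2, 96, k_N, 96)


def fisher_oracle(a, b, c, d):
    """Exhaustive minimum-likelihood two-sided Fisher p over fixed margins."""
    r1, n, k = a + b, a + b + c + d, a + c
    p_obs = hypergeom.pmf(a, n, r1, k)
    total = 0.0
    for x in range(max(0, k - (n - r1)), min(r1, k) + 1):
        p = hypergeom.pmf(x, n, r1, k)
        if p <= p_obs * (1 + 1e-7):
            total += p
    return min(total, 1.0)


class TestFisherExact:
    def test_balanced_table_is_one(self):
        # all 4 tables with margins (3,3)x(3,3) are as or less probable
        assert fisher_exact([[2, 1], [1, 2]]) == pytest.approx(1.0)

    def test_complete_separation_vanishes(self):
        # single compatible extreme table: p = 1/C(120,24)
        p = fisher_exact([[24, 0], [0, 96]])
        assert p <= 1e-20
        assert p == pytest.approx(1.0 / math.comb(120, 24), rel=1e-6)

    def test_degenerate_margins_rejected(self):
        with pytest.raises(ValueError, match="margin"):
            fisher_exact([[0, 0], [0, 5]])
        with pytest.raises(ValueError, match="negative"):
            fisher_exact([[-1, 2], [3, 4]])

    @settings(deadline=None, max_examples=150)
    @given(
        a=st.integers(0, 15),
        b=st.integers(0, 15),
        c=st.integers(0, 15),
        d=st.integers(0, 15),
    )
    def test_matches_enumeration_oracle(self, a, b, c, d):
        """Agreement with brute-force enumeration over all tables with the
        observed margins (totals up to 60)."""
        if a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0:
            return
        assert fisher_exact([[a, b], [c, d]]) == pytest.approx(
            fisher_oracle(a, b, c, d), rel=1e-7, abs=1e-12
        )


class TestAssociationTable:
    def test_fixture_delta_column(self, cohort, ancestral):
        rows = association_table(cohort, ancestral, n_boot=200)
        deltas = [r.delta for r in rows]
        assert deltas == pytest.approx(
            [0.704, 0.850, 0.500, 0.758, 0.833, 0.940], abs=5e-4
        )

    def test_str13_difference_in_proportions(self, cohort, ancestral):
        rows = {r.marker: r for r in association_table(cohort, ancestral, n_boot=200)}
        r = rows["STR13"]
        assert r.delta_p == pytest.approx(0.417, abs=0.0015)
        assert r.ci_low == pytest.approx(0.267, abs=0.0015)
        assert r.ci_high == pytest.approx(0.566, abs=0.0015)

    def test_wald_interval_brackets_estimate(self, cohort, ancestral):
        for r in association_table(cohort, ancestral, n_boot=200):
            assert r.ci_low <= r.delta_p <= r.ci_high
            assert r.delta <= 1.0

    def test_bootstrap_ci_brackets_delta_and_is_seeded(self):
        lo1, hi1 = bootstrap_delta_ci(23, 24, 29, 96, n_boot=2000, seed=7)
        lo2, hi2 = bootstrap_delta_ci(23, 24, 29, 96, n_boot=2000, seed=7)
        assert (lo1, hi1) == (lo2, hi2)
        assert lo1 <= bt_delta(23, 24, 29, 96) <= hi1
        assert hi1 <= 1.0
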
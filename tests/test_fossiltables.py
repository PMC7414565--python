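"""Clade-table calculus: cross-tabulation, exact tests, projections."""

import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from pulsetree import fossiltables as ft
from pulsetree import simdata
from pulsetree.errors import DomainError, ValidationError


@pytest.fixture(scope="module")
def african():
    return ft.packaged_table("african_families_synthetic")


@pytest.fixture(scope="module")
def malagasy():
    return ft.packaged_table("malagasy_clades")


class TestCrossTabulate:
    def test_colonization_by_status(self, african):
        t = ft.cross_tabulate(
            african, "colonized_early", "status",
            unknown_as={"colonized_early": "no"},
        )
        assert t.counts.tolist() == [[0, 11], [50, 14]]
        assert t.total == 75

    def test_single_level_factor_rejected(self, african):
        # the 11 early colonizers are all extant and all coded 'yes'
        with pytest.raises(ValidationError, match="fewer than 2"):
            ft.cross_tabulate(african.head(11), "colonized_early", "status")

    def test_unknowns_excluded_and_counted(self):
        fix = simdata.make_clade_fixture(50, 25, seed=3)
        t = ft.cross_tabulate(fix, "widespread", "colonized_early",
                              col_levels=("yes", "no"))
        # extinct clades carry unknown colonization status and are excluded
        assert t.excluded == 50
        assert t.total == 25

    def test_order_invariance(self, african):
        shuffled = african.sample(frac=1.0, random_state=5)
        t1 = ft.cross_tabulate(african, "colonized_early", "status",
                               unknown_as={"colonized_early": "no"})
        t2 = ft.cross_tabulate(shuffled, "colonized_early", "status",
                               unknown_as={"colonized_early": "no"})
        assert t1.counts.tolist() == t2.counts.tolist()

    def test_empty_rejected(self, african):
        with pytest.raises(ValidationError):
            ft.cross_tabulate(african.iloc[0:0], "colonized_early", "status")


def enumeration_oracle(a, b, c, d):
    """Independent brute-force two-sided Fisher: exact rational
    hypergeometric enumeration written against scipy's pmf ordering."""
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    if min(r1, r2, c1, n - c1) == 0:
        return Fraction(1)
    obs = Fraction(math.comb(r1, a) * math.comb(r2, c1 - a), math.comb(n, c1))
    tot = Fraction(0)
    for x in range(max(0, c1 - r2), min(r1, c1) + 1):
        p = Fraction(math.comb(r1, x) * math.comb(r2, c1 - x), math.comb(n, c1))
        if p <= obs * (1 + Fraction(1, 10**7)):
            tot += p
    return min(tot, Fraction(1))


class TestFisherExact:
    @pytest.mark.parametrize(
        "table",
        [(0, 11, 50, 14), (2, 3, 3, 2), (5, 0, 0, 5), (1, 9, 11, 3), (4, 4, 4, 4)],
    )
    def test_matches_enumeration_and_scipy(self, table):
        t = ft.TwoByTwo(*table)
        p = ft.fisher_exact_two_sided(t)
        assert p == pytest.approx(float(enumeration_oracle(*table)), rel=1e-12)
        assert p == pytest.approx(
            stats.fisher_exact(t.counts)[1], rel=1e-7, abs=1e-12
        )

    def test_degenerate_margin_is_one(self):
        assert ft.fisher_exact_two_sided(ft.TwoByTwo(0, 0, 3, 4)) == 1.0
        assert ft.fisher_exact_two_sided(ft.TwoByTwo(3, 0, 4, 0)) == 1.0

    @given(st.integers(0, 12), st.integers(0, 12), st.integers(0, 12),
           st.integers(0, 12))
    @settings(max_examples=80, deadline=None)
    def test_symmetries(self, a, b, c, d):
        if a + b + c + d == 0:
            return
        p = ft.fisher_exact_two_sided(ft.TwoByTwo(a, b, c, d))
        assert 0 <= p <= 1
        # invariance under row swap, column swap, transpose
        assert p == ft.fisher_exact_two_sided(ft.TwoByTwo(c, d, a, b))
        assert p == ft.fisher_exact_two_sided(ft.TwoByTwo(b, a, d, c))
        assert p == ft.fisher_exact_two_sided(ft.TwoByTwo(a, c, b, d))


class TestProjection:
    def test_published_projection(self):
        proj = ft.project_missing_colonizers(50, 11, 25)
        assert proj.projected_extinct_colonizers == 22
        assert proj.total_colonizers == 33
        # margins preserved
        assert proj.counts.sum(axis=0).tolist() == [50, 25]

    @pytest.mark.parametrize("args, expected", [((0, 11, 25), 0), ((50, 0, 25), 0)])
    def test_degenerate_projections(self, args, expected):
        assert ft.project_missing_colonizers(*args).projected_extinct_colonizers == expected

    def test_half_even_rounding(self):
        assert ft.project_missing_colonizers(5, 1, 2).projected_extinct_colonizers == 2
        assert ft.project_missing_colonizers(7, 1, 2).projected_extinct_colonizers == 4


class TestEOBound:
    @pytest.mark.parametrize(
        "args, expected",
        [((50, 11, 75), 52.0), ((50, 50, 75), 0.0), ((75, 0, 75), 100.0)],
    )
    def test_bound(self, args, expected):
        assert ft.eo_disappearance_bound(*args) == pytest.approx(expected)

    def test_ordering_enforced(self):
        with pytest.raises(DomainError):
            ft.eo_disappearance_bound(10, 20, 75)


class TestArrivals:
    def test_packaged_tallies(self, malagasy):
        counts = ft.summarize_arrivals(malagasy)
        assert counts["pre_eo"] == 23
        assert counts["post_eo"] == 48
        assert counts["cretaceous"] == 19
        assert counts["pre_eo"] + counts["post_eo"] == 71

    def test_duplication_invariance(self, malagasy):
        import pandas as pd

        doubled = pd.concat([malagasy, malagasy], ignore_index=True)
        assert ft.summarize_arrivals(doubled) == ft.summarize_arrivals(malagasy)

    def test_empty(self):
        import pandas as pd

        out = ft.summarize_arrivals(pd.DataFrame(columns=simdata.CLADE_COLUMNS))
        assert out["pre_eo"] == 0 and out["total_known"] == 0


class TestConstantRateSurvival:
    def test_closed_form_point(self):
        # F(0.05) with start 66, EO 34 evaluated independently
        expected = (math.exp(-1.7) - math.exp(-3.3)) / (0.05 * 32)
        rep = ft.constant_rate_survival(23, 48, m_grid=[0.05])
        assert rep.sensitivity[0][1] == pytest.approx(expected, rel=1e-12)

    def test_ratio_reproduced(self):
        rep = ft.constant_rate_survival(23, 48)
        assert rep.feasible
        assert rep.achieved_ratio == pytest.approx(23 / 48, abs=1e-8)

    def test_zero_hazard_limit(self):
        assert ft._surviving_fraction(0.0, 66, 34) == 1.0

    def test_monotone_decreasing_in_m(self):
        grid = np.linspace(0.005, 0.5, 40)
        f = [ft._surviving_fraction(m, 66, 34) for m in grid]
        assert all(x > y for x, y in zip(f, f[1:]))

    def test_infeasible_ratio_flagged(self):
        rep = ft.constant_rate_survival(48, 23)  # pre/post > (66-34)/34
        assert not rep.feasible
        assert rep.m_hat == 0.0


class TestFixtureGenerator:
    def test_determinism_and_asymmetry(self):
        a = simdata.make_clade_fixture(seed=9)
        b = simdata.make_clade_fixture(seed=9)
        assert a.equals(b)
        assert (a.loc[a.status == "extinct", "colonized_early"] == "unknown").all()
        assert (a.loc[a.status == "extant", "crossed_eo"] == "unknown").all()

    def test_binomial_expectation_of_colonizers(self):
        hits = []
        for s in range(40):
            df = simdata.make_clade_fixture(50, 25, p_colonize=0.44, seed=s)
            hits.append((df["colonized_early"] == "yes").sum())
        mean = np.mean(hits)
        se = np.std(hits, ddof=1) / math.sqrt(len(hits))
        assert abs(mean - 25 * 0.44) < 3 * max(se, 1e-9) + 1e-9

    def test_zero_probability(self):
        df = simdata.make_clade_fixture(10, 10, p_colonize=0.0, seed=1)
        assert (df.loc[df.status == "extant", "colonized_early"] == "no").all()
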
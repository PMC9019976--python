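"""Score and Tango interval inversions, Wald reference, and the IUT rule."""

import math

import numpy as np
import pytest
from scipy.optimize import minimize_scalar
from scipy.special import xlogy
from scipy.stats import norm

from copriss.intervals import (
    ConfidenceInterval,
    PairedCountTable,
    UnpairedCounts,
    _fm_restricted_mle,
    iut_decision,
    score_ci_diff_independent,
    score_stat_independent,
    tango_ci_diff_paired,
    tango_score_stat,
    wald_ci_diff_independent,
)


def _grid_invert(stat_on_grid, level=0.95, step=1e-5):
    """Oracle: accept every delta on a fine grid whose |statistic| <= z."""
    z = norm.ppf(0.5 + level / 2)
    deltas = np.arange(-1 + 1e-9, 1 - 1e-9, step)
    accepted = deltas[np.abs(stat_on_grid(deltas)) <= z]
    return accepted[0], accepted[-1]


class TestWald:
    def test_symmetric_counts_centre_on_zero(self):
        ci = wald_ci_diff_independent(30, 50, 30, 50)
        assert ci.lower == pytest.approx(-ci.upper, abs=1e-12)

    def test_textbook_formula(self):
        ci = wald_ci_diff_independent(40, 50, 25, 60, 0.95)
        p1, p2 = 0.8, 25 / 60
        half = norm.ppf(0.975) * math.sqrt(p1 * 0.2 / 50 + p2 * (1 - p2) / 60)
        assert ci.lower == pytest.approx(p1 - p2 - half, abs=1e-12)
        assert ci.upper == pytest.approx(p1 - p2 + half, abs=1e-12)

    def test_degenerate_variance_collapses(self):
        ci = wald_ci_diff_independent(500, 500, 0, 500)
        assert ci.lower == ci.upper == pytest.approx(1.0)


class TestScoreIndependent:
    def test_symmetric_counts_centre_on_zero(self):
        ci = score_ci_diff_independent(30, 50, 30, 50)
        assert ci.lower == pytest.approx(-ci.upper, abs=1e-8)

    @pytest.mark.parametrize(
        "x1,n1,x2,n2",
        [(40, 50, 30, 50), (0, 20, 5, 30), (20, 20, 0, 25), (7, 13, 5, 11)],
    )
    def test_matches_grid_inversion(self, x1, n1, x2, n2):
        ci = score_ci_diff_independent(x1, n1, x2, n2)
        lo, hi = _grid_invert(lambda d: score_stat_independent(d, x1, n1, x2, n2))
        assert ci.lower == pytest.approx(lo, abs=2e-5)
        assert ci.upper == pytest.approx(hi, abs=2e-5)

    @pytest.mark.parametrize("x1,n1,x2,n2", [(0, 10, 10, 10), (15, 15, 0, 8), (0, 5, 0, 7)])
    def test_range_preserving_at_boundaries(self, x1, n1, x2, n2):
        ci = score_ci_diff_independent(x1, n1, x2, n2)
        assert -1.0 <= ci.lower <= ci.upper <= 1.0

    def test_restricted_mle_matches_profile_likelihood(self):
        # numeric profile of the constrained binomial likelihood as oracle
        def numeric(x1, n1, x2, n2, delta):
            def nll(p1):
                p2 = p1 - delta
                return -(
                    xlogy(x1, p1) + xlogy(n1 - x1, 1 - p1)
                    + xlogy(x2, p2) + xlogy(n2 - x2, 1 - p2)
                )

            res = minimize_scalar(
                nll,
                bounds=(max(0.0, delta) + 1e-14, min(1.0, 1 + delta) - 1e-14),
                method="bounded",
                options={"xatol": 1e-13},
            )
            return res.x

        rng = np.random.default_rng(42)
        for _ in range(50):
            n1, n2 = rng.integers(5, 60, 2)
            x1 = int(rng.integers(0, n1 + 1))
            x2 = int(rng.integers(0, n2 + 1))
            delta = float(rng.uniform(-0.9, 0.9))
            closed = float(_fm_restricted_mle(x1 / n1, x2 / n2, n1, n2, delta)[0])
            assert closed == pytest.approx(numeric(x1, n1, x2, n2, delta), abs=1e-6)

    def test_agrees_with_statsmodels_on_interior_counts(self):
        statsmodels = pytest.importorskip("statsmodels.stats.proportion")
        for x1, n1, x2, n2 in [(40, 50, 30, 50), (7, 13, 5, 11), (25, 40, 30, 45)]:
            ours = score_ci_diff_independent(x1, n1, x2, n2, bias_correction=True)
            theirs = statsmodels.confint_proportions_2indep(
                x1, n1, x2, n2, method="score", compare="diff"
            )
            # statsmodels inverts the same statistic with a coarser numeric
            # search, so agreement is approximate
            assert ours.lower == pytest.approx(theirs[0], abs=0.01)
            assert ours.upper == pytest.approx(theirs[1], abs=0.01)

    def test_contains_estimate_and_width_shrinks(self):
        widths = []
        for scale in (1, 2, 4, 8):
            ci = score_ci_diff_independent(20 * scale, 30 * scale, 12 * scale, 30 * scale)
            assert ci.lower <= 20 / 30 - 12 / 30 <= ci.upper
            widths.append(ci.width)
        assert widths == sorted(widths, reverse=True)


class TestTango:
    def test_balanced_discordance_centres_on_zero(self):
        ci = tango_ci_diff_paired(7, 7, 80)
        assert ci.lower == pytest.approx(-ci.upper, abs=1e-8)

    @pytest.mark.parametrize("b,c,n", [(10, 3, 50), (0, 0, 20), (5, 5, 100), (12, 0, 40)])
    def test_matches_grid_inversion(self, b, c, n):
        ci = tango_ci_diff_paired(b, c, n)
        lo, hi = _grid_invert(lambda d: tango_score_stat(d, b, c, n))
        assert ci.lower == pytest.approx(lo, abs=2e-5)
        assert ci.upper == pytest.approx(hi, abs=2e-5)

    def test_no_discordance_still_proper(self):
        # all-concordant pairs: closed form +/- z^2 / (n + z^2)
        n = 20
        ci = tango_ci_diff_paired(0, 0, n)
        z2 = norm.ppf(0.975) ** 2
        assert ci.lower == pytest.approx(-z2 / (n + z2), abs=1e-6)
        assert ci.upper == pytest.approx(z2 / (n + z2), abs=1e-6)
        assert ci.lower < 0 < ci.upper

    def test_contains_estimate_and_width_shrinks(self):
        widths = []
        for scale in (1, 2, 4, 8):
            ci = tango_ci_diff_paired(10 * scale, 4 * scale, 60 * scale)
            assert ci.lower <= 6 / 60 <= ci.upper
            widths.append(ci.width)
        assert widths == sorted(widths, reverse=True)

    def test_invalid_counts(self):
        with pytest.raises(ValueError):
            tango_ci_diff_paired(10, 15, 20)


class TestCoverage:
    """Empirical coverage of the score-type inversions near nominal."""

    def test_score_independent_coverage(self):
        rng = np.random.default_rng(7)
        reps = 2000
        for p1, p2 in [(0.9, 0.8), (0.5, 0.5), (0.95, 0.7)]:
            n = 50
            x1 = rng.binomial(n, p1, size=reps)
            x2 = rng.binomial(n, p2, size=reps)
            hits = 0
            for a, b in zip(x1, x2):
                ci = score_ci_diff_independent(int(a), n, int(b), n, 0.95)
                hits += ci.lower <= p1 - p2 <= ci.upper
            assert hits / reps >= 0.93

    def test_tango_coverage(self):
        rng = np.random.default_rng(8)
        reps = 2000
        for p10, p01 in [(0.10, 0.05), (0.2, 0.2), (0.02, 0.01)]:
            n = 60
            delta = p10 - p01
            cells = rng.multinomial(n, [p10, p01, 1 - p10 - p01], size=reps)
            hits = 0
            for b, c, _ in cells:
                ci = tango_ci_diff_paired(int(b), int(c), n)
                hits += ci.lower <= delta <= ci.upper
            assert hits / reps >= 0.93


class TestIut:
    def test_both_positive_rejects(self):
        ci = ConfidenceInterval(0.02, 0.3, 0.95)
        assert iut_decision(ci, ci) is True

    def test_one_nonpositive_fails(self):
        good = ConfidenceInterval(0.02, 0.3, 0.95)
        bad = ConfidenceInterval(-0.01, 0.3, 0.95)
        assert iut_decision(good, bad) is False
        assert iut_decision(bad, good) is False

    def test_equals_conjunction_of_endpoint_decisions(self):
        rng = np.random.default_rng(3)
        for _ in range(100):
            lo1, lo2 = rng.uniform(-0.2, 0.2, 2)
            ci1 = ConfidenceInterval(lo1, lo1 + 0.4, 0.95)
            ci2 = ConfidenceInterval(lo2, lo2 + 0.4, 0.95)
            assert iut_decision(ci1, ci2) == ((lo1 > 0) and (lo2 > 0))


class TestCountContainers:
    def test_paired_table_sums_and_swap(self):
        t = PairedCountTable(d11=5, d10=3, d01=2, d00=1, nd11=1, nd10=4, nd01=6, nd00=20)
        assert t.n_diseased == 11
        assert t.n_nondiseased == 31
        assert t.n_total == 42
        s = t.swap_tests()
        assert (s.d10, s.d01, s.nd10, s.nd01) == (2, 3, 6, 4)
        assert s.swap_tests() == t

    def test_unpaired_counts_validated(self):
        with pytest.raises(ValueError):
            UnpairedCounts(tp_e=10, n_d_e=5, tn_e=1, n_nd_e=2,
                           tp_c=1, n_d_c=2, tn_c=1, n_nd_c=2)
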
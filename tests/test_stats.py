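"""Four-algorithm statistics: exact formula checks, closed-form gamma
posterior oracles, shrinkage properties, fitting, flags, ranking and
overlap."""

import math
from fractions import Fraction

import numpy as np
import pytest
from scipy import integrate, special, stats as sps

from faerspv.contingency import ContingencyTable
from faerspv.faers_io import round2
from faerspv.signal_stats import (
    BcpnnResult, FittingError, MgpsPrior, MgpsResult, PrrResult, RorResult,
    SignalFlags, SignalResult, ebgm, fit_mgps_prior, flags, ic, ic_from_ebgm,
    posterior_lambda_quantile, prr, relative_reporting_ratio, ror,
    signal_overlap, top_k_signals,
)

T_REF = ContingencyTable(10, 90, 100, 9900)


class TestRor:
    def test_reference_table(self):
        r = ror(T_REF)
        assert round2(r.ror) == 11.00
        assert round2(r.ci_low) == 5.56
        # exp(ln 11 + 1.96 * sqrt(1/10+1/90+1/100+1/9900)) = 21.7645
        assert round2(r.ci_high) == 21.76

    def test_equal_odds(self):
        assert ror(ContingencyTable(5, 5, 50, 50)).ror == pytest.approx(1.0)

    def test_zero_cell_undefined(self):
        r = ror(ContingencyTable(0, 10, 10, 100))
        assert not r.defined


class TestPrr:
    def test_reference_table(self):
        p = prr(T_REF)
        assert round2(p.prr) == 10.00
        assert round2(p.chi2) == 74.45

    def test_exact_independence(self):
        p = prr(ContingencyTable(5, 45, 50, 450))
        assert p.prr == pytest.approx(1.0)
        assert p.chi2 == pytest.approx(0.0, abs=1e-20)

    def test_zero_background_undefined(self):
        assert not prr(ContingencyTable(10, 90, 0, 9900)).defined


class TestRelativeReportingRatio:
    def test_reference_table(self):
        assert round2(relative_reporting_ratio(T_REF)) == 9.18

    def test_independence_is_one(self):
        assert relative_reporting_ratio(
            ContingencyTable(5, 45, 50, 450)) == pytest.approx(1.0)

    def test_zero_a(self):
        assert relative_reporting_ratio(
            ContingencyTable(0, 50, 50, 450)) == 0.0


def random_tables(n, rng):
    out = []
    while len(out) < n:
        a = int(rng.integers(1, 200))
        b = int(rng.integers(1, 5000))
        c = int(rng.integers(1, 5000))
        d = int(rng.integers(1, 200000))
        out.append(ContingencyTable(a, b, c, d))
    return out


def test_frequentist_statistics_match_exact_rational_arithmetic():
    """ROR, PRR, chi2 and O/E agree with exact Fraction evaluation."""
    rng = np.random.default_rng(7)
    for t in random_tables(200, rng):
        a, b, c, d = (Fraction(int(t.a)), Fraction(int(t.b)),
                      Fraction(int(t.c)), Fraction(int(t.d)))
        n = a + b + c + d
        assert ror(t).ror == pytest.approx(float(a * d / (b * c)), rel=1e-12)
        assert prr(t).prr == pytest.approx(
            float((a / (a + b)) / (c / (c + d))), rel=1e-12)
        exact_chi2 = n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))
        assert prr(t).chi2 == pytest.approx(float(exact_chi2), rel=1e-12)
        exact_oe = a * n / ((a + b) * (a + c))
        assert relative_reporting_ratio(t) == pytest.approx(
            float(exact_oe), rel=1e-12)


def test_ror_at_least_prr_for_positive_association():
    rng = np.random.default_rng(21)
    checked = 0
    for t in random_tables(500, rng):
        r, p = ror(t), prr(t)
        if r.defined and p.defined and t.a * t.d > t.b * t.c:
            assert r.ror >= p.prr - 1e-12
            checked += 1
    assert checked > 100


# ---------------------------------------------------------------------------
# MGPS
# ---------------------------------------------------------------------------

DEGENERATE_PRIOR = MgpsPrior(1.0, 1.0, 1.0, 1.0, 0.5)


class TestEbgmClosedForm:
    def test_single_gamma_posterior(self):
        """With a Gamma(1,1) prior the posterior is Gamma(11, 1+E) and both
        EBGM and EBGM05 have closed forms via digamma and the chi-square
        quantile."""
        e = T_REF.expected
        res = ebgm(T_REF, DEGENERATE_PRIOR)
        exact = math.exp(special.digamma(11) - math.log(1 + e))
        assert res.ebgm == pytest.approx(exact, rel=1e-10)
        assert round2(res.ebgm) == 5.03
        exact05 = sps.chi2.ppf(0.05, 2 * 11) / 2 / (1 + e)
        assert res.ebgm05 == pytest.approx(exact05, rel=1e-8)
        assert round2(res.ebgm05) == 2.95

    def test_equal_components_reduce_to_single_gamma(self):
        mixed = MgpsPrior(2.0, 3.0, 2.0, 3.0, 0.25)
        single = ebgm(T_REF, MgpsPrior(2.0, 3.0, 2.0, 3.0, 0.5))
        res = ebgm(T_REF, mixed)
        assert res.ebgm == pytest.approx(single.ebgm, rel=1e-12)
        assert res.ebgm05 == pytest.approx(single.ebgm05, rel=1e-10)


def random_priors(n, rng):
    out = []
    for _ in range(n):
        out.append(MgpsPrior(
            float(rng.uniform(0.1, 3)), float(rng.uniform(0.05, 3)),
            float(rng.uniform(0.1, 5)), float(rng.uniform(0.05, 5)),
            float(rng.uniform(0.05, 0.95)),
        ))
    return out


class TestEbgmProperties:
    def test_shrinkage_between_prior_mean_and_observed(self):
        """EBGM is pulled from the raw O/E toward the prior: it always lies
        in the envelope spanned by the observed ratio and the component
        geometric means (the mixture's posterior reweighting can move it
        a fraction of a percent past the averaged prior GM, so the bound
        is taken component-wise)."""
        rng = np.random.default_rng(3)
        tables = random_tables(100, rng)
        priors = random_priors(100, rng)
        for t, pr in zip(tables, priors):
            res = ebgm(t, pr)
            oe = t.a / t.expected
            gm1 = math.exp(special.digamma(pr.alpha1) - math.log(pr.beta1))
            gm2 = math.exp(special.digamma(pr.alpha2) - math.log(pr.beta2))
            lo, hi = min(gm1, gm2, oe), max(gm1, gm2, oe)
            assert lo - 1e-9 <= res.ebgm <= hi + 1e-9

    def test_monotone_in_a_for_fixed_margins(self):
        pr = MgpsPrior(0.5, 0.3, 2.0, 2.0, 0.4)
        last = 0.0
        for a in [1, 2, 5, 10, 20, 50]:
            t = ContingencyTable(a, 200 - a, 300, 50000)
            cur = ebgm(t, pr).ebgm
            assert cur > last
            last = cur

    def test_quantile_inverts_mixture_cdf(self):
        rng = np.random.default_rng(5)
        for t, pr in zip(random_tables(20, rng), random_priors(20, rng)):
            q05 = posterior_lambda_quantile(t, pr, 0.05)
            e = t.expected
            a = round(t.a)
            lw = np.array([
                math.log(pr.p) + sps.nbinom.logpmf(a, pr.alpha1,
                                                   pr.beta1 / (pr.beta1 + e)),
                math.log1p(-pr.p) + sps.nbinom.logpmf(a, pr.alpha2,
                                                      pr.beta2 / (pr.beta2 + e)),
            ])
            w = np.exp(lw - special.logsumexp(lw))
            cdf = (w[0] * sps.gamma.cdf(q05, pr.alpha1 + a, scale=1 / (pr.beta1 + e))
                   + w[1] * sps.gamma.cdf(q05, pr.alpha2 + a,
                                          scale=1 / (pr.beta2 + e)))
            assert cdf == pytest.approx(0.05, abs=1e-8)


class TestFitMgpsPrior:
    def test_requires_fifty_tables(self):
        with pytest.raises(FittingError, match="50"):
            fit_mgps_prior([T_REF] * 49)

    def test_all_null_data_recovers_unit_mean(self):
        """Counts simulated with lambda == 1 should yield a fitted prior
        whose mixture mean is ~1."""
        rng = np.random.default_rng(17)
        es = rng.lognormal(1.5, 1.0, 2000)
        tables = []
        for e in es:
            a = rng.poisson(e)
            # build a table with the desired E and a (margins chosen wide)
            n = 1_000_000
            ab = 1000.0
            ac = e * n / ab
            tables.append(ContingencyTable(a, ab - a, ac - a, n - ab - ac + a))
        prior = fit_mgps_prior(tables)
        assert prior.mean == pytest.approx(1.0, rel=0.10)

    def test_fitted_likelihood_dominates_truth(self):
        from faerspv.signal_stats import _neg_log_marginal

        true = MgpsPrior(0.3, 0.15, 2.0, 1.8, 0.3)
        rng = np.random.default_rng(23)
        es = rng.lognormal(1.0, 1.2, 1500)
        comp = rng.random(1500) < true.p
        lam = np.where(
            comp,
            rng.gamma(true.alpha1, 1 / true.beta1, 1500),
            rng.gamma(true.alpha2, 1 / true.beta2, 1500),
        )
        tables = []
        for e, l in zip(es, lam):
            a = rng.poisson(l * e)
            n = 1_000_000
            ab = 1000.0
            ac = e * n / ab
            tables.append(ContingencyTable(a, ab - a, max(ac - a, 0.0),
                                           n - ab - ac + a))
        fitted = fit_mgps_prior(tables)
        a_arr = np.array([round(t.a) for t in tables], float)
        e_arr = np.array([t.expected for t in tables])

        def nll(p: MgpsPrior) -> float:
            theta = np.array([
                math.log(p.alpha1), math.log(p.beta1), math.log(p.alpha2),
                math.log(p.beta2), math.log(p.p / (1 - p.p)),
            ])
            return _neg_log_marginal(theta, a_arr, e_arr)

        assert nll(fitted) <= nll(true) + 0.1


# ---------------------------------------------------------------------------
# BCPNN
# ---------------------------------------------------------------------------

class TestIc:
    def test_log2_identity(self):
        assert round2(ic_from_ebgm(59.84)) == 5.90

    def test_constant_offset_lower_bound(self):
        res = ic(T_REF, DEGENERATE_PRIOR)
        assert res.ic025 == pytest.approx(res.ic - 1.66)
        assert round2(ic_from_ebgm(1.78 * 2 ** 1.66) - 1.66) > 0  # sanity

    def test_near_null_ic_near_zero(self):
        t = ContingencyTable(50, 450, 500, 4500)
        res = ic(t, DEGENERATE_PRIOR)
        assert abs(res.ic) < 0.1

    def test_credible_interval_mode(self):
        res = ic(T_REF, DEGENERATE_PRIOR, mode="credible_interval")
        assert res.ic025 <= res.ic
        lo = posterior_lambda_quantile(T_REF, DEGENERATE_PRIOR, 0.025)
        assert res.ic025 == pytest.approx(math.log2(lo), rel=1e-10)
        # the principled bound differs from the constant-offset one
        compat = ic(T_REF, DEGENERATE_PRIOR)
        assert res.ic025 != pytest.approx(compat.ic025, abs=1e-6)

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError):
            ic(T_REF, DEGENERATE_PRIOR, mode="nope")


# ---------------------------------------------------------------------------
# flags, ranking, overlap
# ---------------------------------------------------------------------------

def _result(event, a, ebgm_val=10.0, all_flags=True):
    f = SignalFlags(all_flags, all_flags, all_flags, all_flags)
    return SignalResult(
        "d", event, "PT", ContingencyTable(a, 100, 100, 10000),
        RorResult(3.0, 2.0, 4.0), PrrResult(3.0, 50.0),
        BcpnnResult(1.0, 0.5), MgpsResult(ebgm_val, ebgm_val / 2), f,
    )


class TestFlags:
    def test_all_four_required_for_combined(self):
        f = flags(RorResult(3.54, 3.28, 3.82), PrrResult(3.45, 1220.66),
                  BcpnnResult(1.78, 0.12), MgpsResult(3.45, 3.23), a=696)
        assert f.ror_flag and f.prr_flag and f.bcpnn_flag and f.mgps_flag
        assert f.combined

    def test_negative_ic025_blocks_combined(self):
        # strong frequentist statistics, Bayesian lower bound below zero
        f = flags(RorResult(2.40, 2.07, 2.78), PrrResult(2.37, 141.76),
                  BcpnnResult(1.24, -0.42), MgpsResult(2.37, 2.09), a=178)
        assert f.ror_flag and f.prr_flag and f.mgps_flag
        assert not f.bcpnn_flag
        assert not f.combined

    def test_ebgm05_at_most_two_not_flagged(self):
        f = flags(RorResult(2.1, 1.89, 2.33), PrrResult(2.05, 200.02),
                  BcpnnResult(1.04, -0.63), MgpsResult(2.05, 1.88), a=369)
        assert not f.mgps_flag

    def test_minimum_count_rule(self):
        f = flags(RorResult(99.0, 50.0, 200.0), PrrResult(99.0, 500.0),
                  BcpnnResult(6.0, 4.3), MgpsResult(80.0, 40.0), a=2)
        assert not f.ror_flag and not f.prr_flag


class TestTopK:
    def test_rank_by_count_then_ebgm(self):
        results = [
            _result("pt1", 9, 5.0), _result("pt2", 7, 8.0),
            _result("pt3", 7, 2.0), _result("pt4", 3, 9.0),
            _result("pt5", 1, 9.0),
        ]
        top = top_k_signals(results, [], k=3)
        assert [r.event for r in top] == ["pt1", "pt2", "pt3"]

    def test_excluded_top_pt_promotes_next(self):
        results = [_result("death", 9), _result("pt2", 7)]
        top = top_k_signals(results, {"death": ["death"]}, k=2)
        assert [r.event for r in top] == ["pt2"]

    def test_k_larger_than_available(self):
        results = [_result("pt1", 9)]
        assert len(top_k_signals(results, [], k=30)) == 1

    def test_unflagged_rows_dropped(self):
        results = [_result("pt1", 9, all_flags=False), _result("pt2", 7)]
        assert [r.event for r in top_k_signals(results, [], k=5)] == ["pt2"]

    def test_nonpositive_k_rejected(self):
        with pytest.raises(ValueError):
            top_k_signals([], [], k=0)


class TestOverlap:
    def test_two_set_example(self):
        regions = signal_overlap({"A": {"x", "y"}, "B": {"y", "z"}})
        assert regions[("A",)] == 1
        assert regions[("B",)] == 1
        assert regions[("A", "B")] == 1

    def test_identical_sets_all_mass_in_full_region(self):
        sets = {d: {"p", "q"} for d in "ABCDE"}
        regions = signal_overlap(sets)
        assert regions[tuple("ABCDE")] == 2
        assert sum(regions.values()) == 2

    def test_common_event_lands_in_full_region(self):
        sets = {
            "c1": {"DILI", "a"}, "c2": {"DILI", "b"}, "c3": {"DILI"},
            "c4": {"DILI", "d"}, "c5": {"DILI", "e"},
        }
        regions = signal_overlap(sets)
        assert regions[("c1", "c2", "c3", "c4", "c5")] == 1
        assert sum(regions.values()) == len({"DILI", "a", "b", "d", "e"})

    def test_counts_sum_to_union(self):
        sets = {"A": {"x", "y", "z"}, "B": {"y"}, "C": set()}
        assert sum(signal_overlap(sets).values()) == 3
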
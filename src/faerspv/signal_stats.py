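"""Disproportionality statistics and signal classification.

Implements the four standard spontaneous-report signal-detection
algorithms on a 2x2 contingency table (a, b, c, d):

* ROR, reporting odds ratio ad/bc with a 95% Wald interval on the log
  scale;
* PRR, proportional reporting ratio [a/(a+b)] / [c/(c+d)], accompanied
  by the Pearson chi-square without continuity correction;
* MGPS, DuMouchel's empirical-Bayes gamma-Poisson shrinker: a is
  Poisson(lambda * E) with E = (a+b)(a+c)/N, lambda drawn from a
  two-component gamma mixture whose five hyperparameters are fitted by
  maximising the negative-binomial marginal likelihood over all tables;
  EBGM is the posterior geometric mean of lambda and EBGM05 its 5th
  percentile;
* BCPNN information component.  The default ``paper_compat`` mode uses
  the shrunk observed-to-expected ratio, IC = log2(EBGM), with the lower
  bound IC025 = IC - 1.66 — the convention observable in much of the
  FAERS literature.  The ``credible_interval`` mode instead takes IC025
  from the posterior 2.5th percentile of lambda, which is the
  statistically preferred bound.

A pair is a *combined* signal when all four algorithms flag it:
ROR (a >= 3 and CI lower bound > 1), PRR (a >= 3, PRR >= 2, chi2 >= 4),
BCPNN (IC025 > 0) and MGPS (EBGM05 > 2).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
from scipy import optimize, special, stats

from .contingency import ContingencyTable
from .vocab import normalize_term

__all__ = [
    "RorResult", "PrrResult", "BcpnnResult", "MgpsResult", "MgpsPrior",
    "SignalFlags", "SignalThresholds", "SignalResult", "FittingError",
    "ror", "prr", "relative_reporting_ratio", "fit_mgps_prior", "ebgm",
    "posterior_lambda_quantile", "ic", "ic_from_ebgm", "IC025_OFFSET",
    "flags", "combined_dili_assessment", "top_k_signals", "signal_overlap",
    "DEFAULT_PRIOR_START",
]

#: Constant gap between IC and IC025 in ``paper_compat`` mode.
IC025_OFFSET = 1.66

#: DuMouchel's customary optimisation start (alpha1, beta1, alpha2, beta2, p).
DEFAULT_PRIOR_START = (0.2, 0.1, 2.0, 4.0, 1.0 / 3.0)

Z975 = 1.959963984540054  # standard normal 97.5th percentile


class FittingError(RuntimeError):
    """MGPS hyperparameter optimisation failed from every start."""


# ---------------------------------------------------------------------------
# result containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RorResult:
    ror: float
    ci_low: float
    ci_high: float
    defined: bool = True


@dataclass(frozen=True)
class PrrResult:
    prr: float
    chi2: float
    defined: bool = True


@dataclass(frozen=True)
class BcpnnResult:
    ic: float
    ic025: float
    mode: str = "paper_compat"


@dataclass(frozen=True)
class MgpsResult:
    ebgm: float
    ebgm05: float


@dataclass(frozen=True)
class MgpsPrior:
    """Hyperparameters of the two-component gamma mixture prior on lambda,
    Gamma(alpha, beta) parameterised by shape alpha and *rate* beta."""

    alpha1: float
    beta1: float
    alpha2: float
    beta2: float
    p: float

    def __post_init__(self) -> None:
        if min(self.alpha1, self.beta1, self.alpha2, self.beta2) <= 0:
            raise ValueError("gamma hyperparameters must be positive")
        if not 0 < self.p < 1:
            raise ValueError("mixture weight p must lie in (0, 1)")

    @property
    def mean(self) -> float:
        return self.p * self.alpha1 / self.beta1 \
            + (1 - self.p) * self.alpha2 / self.beta2

    @property
    def log_geometric_mean(self) -> float:
        return self.p * (special.digamma(self.alpha1) - math.log(self.beta1)) \
            + (1 - self.p) * (special.digamma(self.alpha2) - math.log(self.beta2))


@dataclass(frozen=True)
class SignalFlags:
    ror_flag: bool
    prr_flag: bool
    bcpnn_flag: bool
    mgps_flag: bool

    @property
    def combined(self) -> bool:
        return self.ror_flag and self.prr_flag and self.bcpnn_flag and self.mgps_flag


@dataclass(frozen=True)
class SignalThresholds:
    """Signal criteria; defaults are the standard four-algorithm set."""

    ror_min_a: int = 3
    ror_ci_low: float = 1.0     # exclusive
    prr_min_a: int = 3
    prr_min: float = 2.0
    chi2_min: float = 4.0
    ic025_min: float = 0.0      # exclusive
    ebgm05_min: float = 2.0     # exclusive


@dataclass
class SignalResult:
    """All four algorithms' output for one drug-event pair."""

    drug: str
    event: str
    level: str
    table: ContingencyTable
    ror: RorResult
    prr: PrrResult
    ic: BcpnnResult
    mgps: MgpsResult
    flags: SignalFlags

    @property
    def a(self) -> float:
        return self.table.a


# ---------------------------------------------------------------------------
# frequentist statistics
# ---------------------------------------------------------------------------

def ror(t: ContingencyTable) -> RorResult:
    """Reporting odds ratio with 95% Wald CI; undefined on any zero cell
    (no silent continuity correction)."""
    if min(t.a, t.b, t.c, t.d) == 0:
        return RorResult(math.nan, math.nan, math.nan, defined=False)
    estimate = (t.a * t.d) / (t.b * t.c)
    se = math.sqrt(1 / t.a + 1 / t.b + 1 / t.c + 1 / t.d)
    log_ror = math.log(estimate)
    return RorResult(
        estimate, math.exp(log_ror - Z975 * se), math.exp(log_ror + Z975 * se)
    )


def prr(t: ContingencyTable) -> PrrResult:
    """Proportional reporting ratio and Pearson chi-square (no Yates
    correction); undefined when the drug margin or cell c is zero."""
    if t.c == 0 or (t.a + t.b) == 0:
        return PrrResult(math.nan, math.nan, defined=False)
    estimate = (t.a / (t.a + t.b)) / (t.c / (t.c + t.d))
    denom = (t.a + t.b) * (t.c + t.d) * (t.a + t.c) * (t.b + t.d)
    chi2 = t.n * (t.a * t.d - t.b * t.c) ** 2 / denom if denom > 0 else math.nan
    return PrrResult(estimate, chi2, defined=not math.isnan(chi2))


def relative_reporting_ratio(t: ContingencyTable) -> float:
    """Observed over expected, a / E with E = (a+b)(a+c)/N — the quantity
    both Bayesian shrinkers pull toward 1."""
    e = t.expected
    if e == 0:
        return math.nan
    return t.a / e


# ---------------------------------------------------------------------------
# MGPS: prior fitting and posterior summaries
# ---------------------------------------------------------------------------

def _neg_log_marginal(theta: np.ndarray, a: np.ndarray, e: np.ndarray) -> float:
    """Negative log marginal likelihood of the gamma-mixture model.

    Marginally a ~ p NB(alpha1, beta1/(beta1+E)) + (1-p) NB(alpha2, ...).
    theta holds (log alpha1, log beta1, log alpha2, log beta2, logit p).
    """
    la1, lb1, la2, lb2, lp = theta
    with np.errstate(over="ignore"):
        a1, b1, a2, b2 = np.exp([la1, lb1, la2, lb2])
    if not np.all(np.isfinite([a1, b1, a2, b2])):
        return 1e12
    # log p and log(1-p) directly from the logit, stable for extreme lp
    log_p = -np.logaddexp(0.0, -lp)
    log_1mp = -np.logaddexp(0.0, lp)
    with np.errstate(divide="ignore", invalid="ignore"):
        ll1 = stats.nbinom.logpmf(a, a1, b1 / (b1 + e))
        ll2 = stats.nbinom.logpmf(a, a2, b2 / (b2 + e))
        ll = np.logaddexp(log_p + ll1, log_1mp + ll2)
    if not np.all(np.isfinite(ll)):
        return 1e12
    return -float(ll.sum())


_EXTRA_STARTS = (
    (1.0, 1.0, 1.0, 1.0, 0.5),
    (0.5, 0.5, 3.0, 3.0, 0.2),
    (2.0, 2.0, 0.2, 0.2, 0.8),
)


def fit_mgps_prior(
    tables: Sequence[ContingencyTable],
    start: tuple[float, float, float, float, float] = DEFAULT_PRIOR_START,
) -> MgpsPrior:
    """Fit the five hyperparameters by maximum marginal likelihood.

    Multi-start L-BFGS-B in unconstrained coordinates (log shapes/rates,
    logit weight), from ``start`` plus three fixed alternatives; the best
    converged solution wins.  Deterministic given the data.  Requires at
    least 50 tables with positive expected count.
    """
    usable = [t for t in tables if t.expected > 0]
    if len(usable) < 50:
        raise FittingError(
            f"need >= 50 tables with E > 0 to fit the prior, got {len(usable)}"
        )
    a = np.array([round(t.a) for t in usable], dtype=float)
    e = np.array([t.expected for t in usable], dtype=float)

    def pack(s):
        a1, b1, a2, b2, p = s
        return np.array([
            math.log(a1), math.log(b1), math.log(a2), math.log(b2),
            math.log(p / (1 - p)),
        ])

    best = None
    best_val = math.inf
    for s in (start,) + _EXTRA_STARTS:
        res = optimize.minimize(
            _neg_log_marginal, pack(s), args=(a, e), method="L-BFGS-B",
            options={"maxiter": 500},
        )
        if res.fun < best_val and np.all(np.isfinite(res.x)):
            best, best_val = res, res.fun
    if best is None or not math.isfinite(best_val):
        raise FittingError(
            f"MGPS prior fit did not converge; best -loglik {best_val}"
        )
    la1, lb1, la2, lb2, lp = best.x
    p = 1.0 / (1.0 + math.exp(-min(max(lp, -30.0), 30.0)))
    return MgpsPrior(
        math.exp(la1), math.exp(lb1), math.exp(la2), math.exp(lb2), p,
    )


def _posterior(t: ContingencyTable, prior: MgpsPrior):
    """Posterior mixture over lambda: weights, shapes, rates."""
    e = t.expected
    a = round(t.a)
    shapes = np.array([prior.alpha1 + a, prior.alpha2 + a])
    rates = np.array([prior.beta1 + e, prior.beta2 + e])
    lw = np.array([
        math.log(prior.p)
        + stats.nbinom.logpmf(a, prior.alpha1, prior.beta1 / (prior.beta1 + e)),
        math.log1p(-prior.p)
        + stats.nbinom.logpmf(a, prior.alpha2, prior.beta2 / (prior.beta2 + e)),
    ])
    lw -= special.logsumexp(lw)
    return np.exp(lw), shapes, rates


def posterior_lambda_quantile(
    t: ContingencyTable, prior: MgpsPrior, q: float
) -> float:
    """Quantile of the posterior gamma mixture over lambda, by monotone
    root finding on the mixture CDF (abs tolerance 1e-8 or better)."""
    w, shapes, rates = _posterior(t, prior)
    ppf = stats.gamma.ppf(q, shapes, scale=1.0 / rates)
    lo, hi = float(ppf.min()), float(ppf.max())
    if hi - lo < 1e-12:
        return lo

    def cdf_gap(x: float) -> float:
        return float(np.dot(w, stats.gamma.cdf(x, shapes, scale=1.0 / rates))) - q

    # the component quantiles bracket the mixture quantile analytically;
    # pad for floating-point slack when one weight dominates
    lo, hi = lo * (1 - 1e-9), hi * (1 + 1e-9)
    for _ in range(60):
        if cdf_gap(lo) <= 0 <= cdf_gap(hi):
            break
        lo, hi = lo * 0.5, hi * 2.0
    return float(optimize.brentq(cdf_gap, lo, hi, xtol=1e-12, rtol=8.9e-16))


def ebgm(t: ContingencyTable, prior: MgpsPrior) -> MgpsResult:
    """Empirical-Bayes geometric mean and 5th percentile of lambda.

    The posterior is the two-component gamma mixture with components
    Gamma(alpha_k + a, beta_k + E); EBGM = exp(E[ln lambda]) via the
    digamma function, EBGM05 the mixture's 5th percentile.
    """
    if t.expected == 0:
        return MgpsResult(math.nan, math.nan)
    w, shapes, rates = _posterior(t, prior)
    e_log = float(np.dot(w, special.digamma(shapes) - np.log(rates)))
    return MgpsResult(math.exp(e_log), posterior_lambda_quantile(t, prior, 0.05))


# ---------------------------------------------------------------------------
# BCPNN information component
# ---------------------------------------------------------------------------

def ic_from_ebgm(ebgm_value: float) -> float:
    """paper_compat identity: IC = log2(EBGM)."""
    return math.log2(ebgm_value)


def ic(
    t: ContingencyTable,
    prior: MgpsPrior,
    mode: Literal["paper_compat", "credible_interval"] = "paper_compat",
) -> BcpnnResult:
    """Information component of the shrunk observed-to-expected ratio.

    ``paper_compat``: IC = log2(EBGM) and IC025 = IC - 1.66, the constant
    offset seen throughout published FAERS tables.  ``credible_interval``:
    IC025 = log2 of the posterior 2.5th percentile of lambda.
    """
    if t.expected == 0:
        return BcpnnResult(math.nan, math.nan, mode)
    post = ebgm(t, prior)
    estimate = ic_from_ebgm(post.ebgm)
    if mode == "paper_compat":
        return BcpnnResult(estimate, estimate - IC025_OFFSET, mode)
    if mode == "credible_interval":
        lo = posterior_lambda_quantile(t, prior, 0.025)
        return BcpnnResult(estimate, math.log2(lo), mode)
    raise ValueError(f"unknown BCPNN mode {mode!r}")


# ---------------------------------------------------------------------------
# classification, ranking, overlap
# ---------------------------------------------------------------------------

def flags(
    ror_result: RorResult,
    prr_result: PrrResult,
    ic_result: BcpnnResult,
    mgps_result: MgpsResult,
    a: float,
    thresholds: SignalThresholds = SignalThresholds(),
) -> SignalFlags:
    """Apply the per-algorithm signal criteria to one pair's statistics."""
    ror_flag = (
        a >= thresholds.ror_min_a
        and ror_result.defined
        and ror_result.ci_low > thresholds.ror_ci_low
    )
    prr_flag = (
        a >= thresholds.prr_min_a
        and prr_result.defined
        and prr_result.prr >= thresholds.prr_min
        and prr_result.chi2 >= thresholds.chi2_min
    )
    bcpnn_flag = (
        not math.isnan(ic_result.ic025) and ic_result.ic025 > thresholds.ic025_min
    )
    mgps_flag = (
        not math.isnan(mgps_result.ebgm05)
        and mgps_result.ebgm05 > thresholds.ebgm05_min
    )
    return SignalFlags(bool(ror_flag), bool(prr_flag), bool(bcpnn_flag),
                       bool(mgps_flag))


def combined_dili_assessment(
    per_drug: Mapping[str, SignalFlags]
) -> dict[str, bool]:
    """A drug is DILI-associated iff all four algorithms flag its DILI pair."""
    return {drug: f.combined for drug, f in per_drug.items()}


def _matches_any(event: str, patterns: Iterable[str]) -> bool:
    ev = normalize_term(event)
    return any(normalize_term(p) in ev for p in patterns)


def top_k_signals(
    results: Sequence[SignalResult],
    exclusions: Mapping[str, Sequence[str]] | Sequence[str],
    k: int,
    require_all_flags: bool = True,
) -> list[SignalResult]:
    """Rank a drug's PT-level signals by report count.

    PTs matching any exclusion pattern (case-insensitive substring) are
    dropped; rows are kept when the combined flag holds (or any flag,
    with ``require_all_flags=False``); ties on report count break by
    EBGM descending, then PT name.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    patterns: list[str] = []
    if isinstance(exclusions, Mapping):
        for plist in exclusions.values():
            patterns.extend(plist)
    else:
        patterns = list(exclusions)

    def keep(r: SignalResult) -> bool:
        if _matches_any(r.event, patterns):
            return False
        f = r.flags
        if require_all_flags:
            return f.combined
        return f.ror_flag or f.prr_flag or f.bcpnn_flag or f.mgps_flag

    ranked = sorted(
        (r for r in results if keep(r)),
        key=lambda r: (-r.a, -(r.mgps.ebgm if math.isfinite(r.mgps.ebgm) else -math.inf),
                       r.event),
    )
    return ranked[:k]


def signal_overlap(
    per_drug_signal_sets: Mapping[str, set[str]]
) -> dict[tuple[str, ...], int]:
    """Venn-region counts: for every nonempty drug subset, the number of
    PTs signalled in exactly that subset.  Counts sum to |union|."""
    drugs = sorted(per_drug_signal_sets)
    if len(drugs) > 6:
        raise ValueError("overlap supported for at most 6 drugs")
    union: set[str] = set()
    for s in per_drug_signal_sets.values():
        union |= s
    regions: dict[tuple[str, ...], int] = {}
    for r in range(1, len(drugs) + 1):
        for subset in combinations(drugs, r):
            regions[subset] = 0
    for pt in union:
        members = tuple(d for d in drugs if pt in per_drug_signal_sets[d])
        regions[members] += 1
    return regions
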
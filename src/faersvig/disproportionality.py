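"""Disproportionality statistics and the four-algorithm conjunction signal.

Four detectors are computed per 2x2 table:

* ROR — reporting odds ratio ``ad/bc`` with a Wald 95% CI on the log scale.
* PRR — proportional reporting ratio ``[a/(a+b)] / [c/(c+d)]`` with the
  Pearson chi-square of the table.
* BCPNN IC — information component ``log2(O/E)`` with Bayesian shrinkage;
  ``IC025`` is its lower 95% credibility bound.
* MGPS EBGM — DuMouchel's empirical-Bayes geometric mean of the relative
  reporting rate under a two-component gamma mixture prior fitted to the
  whole database; ``EBGM05`` is the 5th posterior percentile.

An event is declared a signal only when the positivity thresholds of all
four methods are met simultaneously (the conjunction criterion) — a
deliberately conservative rule that serves as the false-positive control in
place of multiple-testing correction.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from faersvig.cohort import (
    ContingencyTable,
    PtSocMap,
    age_band,
    build_contingency,
    normalize_term,
    unique_pairs,
)
from faersvig.faers_io import ReportRecord

logger = logging.getLogger(__name__)

_Z95 = 1.959963984540054


# ---------------------------------------------------------------------------
# Frequentist detectors


def ror_stat(t: ContingencyTable) -> tuple[float, float, float]:
    """Reporting odds ratio with Wald 95% CI.

    Returns ``(ror, low, high)``.  The point estimate requires ``b>0`` and
    ``c>0``; the CI additionally requires ``a>0`` and ``d>0``.  Cells that
    make a quantity undefined yield ``nan`` (no continuity correction is
    applied — downstream flags treat ``nan`` as not positive).
    """
    a, b, c, d = t.a, t.b, t.c, t.d
    if b == 0 or c == 0:
        return math.nan, math.nan, math.nan
    ror = (a * d) / (b * c)
    if a == 0 or d == 0:
        return ror, math.nan, math.nan
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return ror, ror * math.exp(-_Z95 * se), ror * math.exp(_Z95 * se)


def prr_stat(t: ContingencyTable, yates: bool = False) -> tuple[float, float]:
    """Proportional reporting ratio and the Pearson chi-square of the table.

    Yates continuity correction is off by default, matching common FAERS
    practice; pass ``yates=True`` to enable it.  Non-computable cases
    (zero margins or ``c=0``) yield ``nan``.
    """
    a, b, c, d = t.a, t.b, t.c, t.d
    if a + b == 0 or c + d == 0 or c == 0:
        prr = math.nan
    else:
        prr = (a / (a + b)) / (c / (c + d))
    if min(a + b, c + d, a + c, b + d) == 0:
        return prr, math.nan
    chi2 = stats.chi2_contingency([[a, b], [c, d]], correction=yates)[0]
    return prr, float(chi2)


# ---------------------------------------------------------------------------
# BCPNN information component


def bcpnn_ic(t: ContingencyTable, method: str = "shrinkage") -> tuple[float, float]:
    """Information component and its lower 95% credibility bound.

    ``method="shrinkage"`` (default) uses the shrinkage formulation
    ``IC = log2((a+0.5)/(E+0.5))`` with the asymptotic credibility bound
    ``IC025 = IC - 3.3 (a+0.5)^-1/2 - 2 (a+0.5)^-3/2``, finite even at
    ``a = 0``.  ``method="bate"`` uses the closed-form Dirichlet
    expectation/variance approximation of the original BCPNN with a normal
    lower bound.
    """
    a = t.a
    n = t.n_total
    if n == 0:
        return math.nan, math.nan
    e = t.expected
    if method == "shrinkage":
        ic = math.log2((a + 0.5) / (e + 0.5))
        ic025 = ic - 3.3 * (a + 0.5) ** -0.5 - 2.0 * (a + 0.5) ** -1.5
        return ic, ic025
    if method == "bate":
        n1 = t.a + t.b
        m1 = t.a + t.c
        alpha1 = beta1 = 1.0
        alpha = beta = 2.0
        gamma11 = 1.0
        gamma = gamma11 * (n + alpha) * (n + beta) / ((n1 + alpha1) * (m1 + beta1))
        ic = math.log2(
            (a + gamma11) * (n + alpha) * (n + beta)
            / ((n + gamma) * (n1 + alpha1) * (m1 + beta1))
        )
        var = (1 / math.log(2)) ** 2 * (
            (n - a + gamma - gamma11) / ((a + gamma11) * (1 + n + gamma))
            + (n - n1 + alpha - alpha1) / ((n1 + alpha1) * (1 + n + alpha))
            + (n - m1 + beta - beta1) / ((m1 + beta1) * (1 + n + beta))
        )
        return ic, ic - _Z95 * math.sqrt(var)
    raise ValueError(f"unknown BCPNN method {method!r}")


# ---------------------------------------------------------------------------
# MGPS / EBGM


@dataclass(frozen=True)
class MgpsHyperparams:
    """DuMouchel's two-component gamma mixture prior on the relative
    reporting rate lambda: with probability ``p`` lambda ~ Gamma(alpha1,
    rate beta1), else Gamma(alpha2, rate beta2)."""

    alpha1: float
    beta1: float
    alpha2: float
    beta2: float
    p: float

    def __post_init__(self):
        if min(self.alpha1, self.beta1, self.alpha2, self.beta2) <= 0:
            raise ValueError("gamma shapes and rates must be positive")
        if not 0.0 <= self.p <= 1.0:
            raise ValueError("mixing weight must lie in [0, 1]")

    @property
    def mean(self) -> float:
        """Prior mean of lambda."""
        return self.p * self.alpha1 / self.beta1 + (1 - self.p) * self.alpha2 / self.beta2


#: DuMouchel's classic start values, also the small-data fallback prior.
CLASSIC_PRIOR = MgpsHyperparams(0.2, 0.1, 2.0, 4.0, 1.0 / 3.0)


def _mixture_logpmf(a, e, theta):
    """Marginal log-likelihood terms: mixture of negative binomials."""
    a1, b1, a2, b2, p = theta
    lp1 = stats.nbinom.logpmf(a, a1, b1 / (b1 + e))
    lp2 = stats.nbinom.logpmf(a, a2, b2 / (b2 + e))
    return np.logaddexp(np.log(p) + lp1, np.log1p(-p) + lp2)


def fit_mgps_prior(
    a: Sequence[int],
    expected: Sequence[float],
    min_pairs: int = 50,
    start: MgpsHyperparams = CLASSIC_PRIOR,
) -> MgpsHyperparams:
    """Fit the mixture prior by maximising the marginal likelihood over all
    drug-event pairs of the database.

    Each pair contributes ``a_i ~ Poisson(lambda_i E_i)`` with lambda drawn
    from the mixture; integrating lambda out gives a two-component negative
    binomial likelihood which is maximised by bounded quasi-Newton search on
    log-shapes/rates and logit weight.  With fewer than ``min_pairs`` usable
    pairs, or on optimizer failure, the classic start values are returned
    unchanged (with a warning) so a run can always continue.
    """
    a_arr = np.asarray(a, dtype=float)
    e_arr = np.asarray(expected, dtype=float)
    keep = e_arr > 0
    a_arr, e_arr = a_arr[keep], e_arr[keep]
    if a_arr.size < min_pairs:
        logger.warning(
            "only %d pairs with positive expectation (< %d); using classic prior",
            a_arr.size, min_pairs,
        )
        return start

    def nll(x):
        a1, b1, a2, b2 = np.exp(x[:4])
        p = special.expit(x[4])
        return -float(np.sum(_mixture_logpmf(a_arr, e_arr, (a1, b1, a2, b2, p))))

    x0 = np.array([
        math.log(start.alpha1), math.log(start.beta1),
        math.log(start.alpha2), math.log(start.beta2),
        special.logit(min(max(start.p, 1e-6), 1 - 1e-6)),
    ])
    try:
        res = optimize.minimize(
            nll, x0, method="L-BFGS-B",
            bounds=[(-7, 7)] * 4 + [(-7, 7)],
        )
    except Exception as exc:  # numerical blow-up inside the optimizer
        logger.warning("MGPS prior fit raised %s; using classic prior", exc)
        return start
    if not res.success or not np.all(np.isfinite(res.x)):
        logger.warning("MGPS prior fit did not converge (%s); using classic prior",
                       res.message)
        return start
    a1, b1, a2, b2 = np.exp(res.x[:4])
    return MgpsHyperparams(a1, b1, a2, b2, float(special.expit(res.x[4])))


def _posterior(a: int, e: float, prior: MgpsHyperparams):
    """Posterior mixture of lambda given the observed count: components
    Gamma(alpha_j + a, rate beta_j + E) with weights updated through the
    marginal negative-binomial likelihood."""
    lp1 = math.log(prior.p) + stats.nbinom.logpmf(a, prior.alpha1,
                                                  prior.beta1 / (prior.beta1 + e)) \
        if prior.p > 0 else -math.inf
    lp2 = math.log1p(-prior.p) + stats.nbinom.logpmf(a, prior.alpha2,
                                                     prior.beta2 / (prior.beta2 + e)) \
        if prior.p < 1 else -math.inf
    m = max(lp1, lp2)
    w1 = math.exp(lp1 - m)
    w2 = math.exp(lp2 - m)
    q = w1 / (w1 + w2)
    comps = (
        (q, prior.alpha1 + a, prior.beta1 + e),
        (1 - q, prior.alpha2 + a, prior.beta2 + e),
    )
    return comps


def ebgm_from_counts(a: int, e: float, prior: MgpsHyperparams = CLASSIC_PRIOR
                     ) -> tuple[float, float]:
    """EBGM and EBGM05 for one (observed, expected) pair.

    ``EBGM = 2^{E[log2 lambda | a]}`` has a closed form through the digamma
    function; the 5th posterior percentile is found by root-finding on the
    mixture gamma CDF.  ``E <= 0`` yields ``nan``.
    """
    if not e > 0:
        return math.nan, math.nan
    comps = _posterior(a, e, prior)
    elog = sum(w * (special.digamma(shape) - math.log(rate))
               for w, shape, rate in comps if w > 0)
    ebgm = math.exp(elog)

    def cdf(lam):
        return sum(w * stats.gamma.cdf(lam, shape, scale=1.0 / rate)
                   for w, shape, rate in comps if w > 0)

    lo = min(stats.gamma.ppf(1e-4, shape, scale=1.0 / rate)
             for w, shape, rate in comps if w > 0)
    hi = max(stats.gamma.ppf(1 - 1e-6, shape, scale=1.0 / rate)
             for w, shape, rate in comps if w > 0)
    lo = max(lo * 0.5, 1e-12)
    ebgm05 = float(optimize.brentq(lambda x: cdf(x) - 0.05, lo, hi * 2, xtol=1e-12,
                                   rtol=1e-12))
    return ebgm, ebgm05


def mgps_ebgm(t: ContingencyTable, prior: MgpsHyperparams = CLASSIC_PRIOR
              ) -> tuple[float, float]:
    """EBGM and EBGM05 for a contingency table (expected count from the
    table's margins)."""
    return ebgm_from_counts(t.a, t.expected, prior)


def pair_counts(
    pairs: pd.DataFrame, drug_of_report: Mapping[str, str]
) -> pd.DataFrame:
    """Observed and expected counts for every (drug, PT) pair of a database.

    ``pairs`` holds unique (primary_id, pt) rows; ``drug_of_report`` maps
    each report to its (primary-suspect) drug.  Expected counts use the
    pair-based margins ``E = n_drug * n_pt / N`` where ``n_drug`` is the
    drug's pair total, ``n_pt`` the number of reports with the PT and ``N``
    the total pair count — the same convention as the default 2x2 tables.
    Used to feed :func:`fit_mgps_prior`.
    """
    df = pairs.copy()
    df["drug"] = df["primary_id"].map(drug_of_report)
    df = df.dropna(subset=["drug"])
    n_total = len(df)
    if n_total == 0:
        return pd.DataFrame(columns=["drug", "pt", "a", "expected"])
    obs = df.groupby(["drug", "pt"], sort=True)["primary_id"].nunique().rename("a")
    drug_margin = df.groupby("drug").size()
    pt_margin = df.groupby("pt")["primary_id"].nunique()
    out = obs.reset_index()
    out["expected"] = (
        out["drug"].map(drug_margin).to_numpy(dtype=float)
        * out["pt"].map(pt_margin).to_numpy(dtype=float)
        / n_total
    )
    return out


# ---------------------------------------------------------------------------
# Thresholds, conjunction, ranking


@dataclass(frozen=True)
class Thresholds:
    """Positivity thresholds of the four algorithms (community-standard
    defaults, all overridable from the run configuration)."""

    min_count: int = 3         # ROR/PRR require a >= 3
    ror_low: float = 1.0       # lower CI bound must exceed this
    prr_min: float = 2.0
    chi2_min: float = 4.0
    ic025_min: float = 0.0
    ebgm05_min: float = 2.0
    yates: bool = False
    bcpnn_method: str = "shrinkage"


@dataclass
class SignalResult:
    """All four statistics for one event, with per-algorithm and combined
    positivity flags."""

    event: str
    level: str
    a: int
    ror: float
    ror_low: float
    ror_high: float
    prr: float
    chi2: float
    ic: float
    ic025: float
    ebgm: float
    ebgm05: float
    flag_ror: bool
    flag_prr: bool
    flag_bcpnn: bool
    flag_mgps: bool

    @property
    def positive(self) -> bool:
        return self.flag_ror and self.flag_prr and self.flag_bcpnn and self.flag_mgps


def _gt(x: float, thr: float) -> bool:
    return bool(x > thr) if math.isfinite(x) else False


def _ge(x: float, thr: float) -> bool:
    return bool(x >= thr) if math.isfinite(x) else False


def evaluate_signal(
    t: ContingencyTable,
    prior: MgpsHyperparams = CLASSIC_PRIOR,
    thresholds: Thresholds = Thresholds(),
) -> SignalResult:
    """Compute all four statistics for a table and apply the conjunction
    criterion.  Any non-computable statistic sets its flag to False."""
    ror, ror_low, ror_high = ror_stat(t)
    prr, chi2 = prr_stat(t, yates=thresholds.yates)
    ic, ic025 = bcpnn_ic(t, method=thresholds.bcpnn_method)
    ebgm, ebgm05 = mgps_ebgm(t, prior)
    gate = t.a >= thresholds.min_count
    return SignalResult(
        event=t.event, level=t.level, a=t.a,
        ror=ror, ror_low=ror_low, ror_high=ror_high,
        prr=prr, chi2=chi2, ic=ic, ic025=ic025, ebgm=ebgm, ebgm05=ebgm05,
        flag_ror=gate and _gt(ror_low, thresholds.ror_low),
        flag_prr=gate and _ge(prr, thresholds.prr_min) and _ge(chi2, thresholds.chi2_min),
        flag_bcpnn=_gt(ic025, thresholds.ic025_min),
        flag_mgps=_gt(ebgm05, thresholds.ebgm05_min),
    )


def _fmt(x: float, nd: int = 2) -> str:
    return "NC" if not math.isfinite(x) else f"{x:.{nd}f}"


def rank_and_report(
    results: Iterable[SignalResult],
    top_n: int | None = None,
    known_labels: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Ranked signal table in the layout of published FAERS analyses.

    Rows are sorted by descending case count with alphabetical tie-break,
    truncated to ``top_n``.  Alongside the raw statistics, formatted columns
    mirror the usual ``ROR (95% CI)`` / ``PRR (chi2)`` / ``EBGM (EBGM05)`` /
    ``IC (IC025)`` presentation at two decimals.  When ``known_labels`` is
    given, events absent from it are starred in the ``unlabeled`` column
    (the convention for label-status flagging).
    """
    rows = sorted(results, key=lambda r: (-r.a, r.event))
    if top_n is not None:
        rows = rows[:top_n]
    known = {normalize_term(x) for x in known_labels} if known_labels is not None else None
    columns = ["event", "level", "count", "ror", "ror_low", "ror_high", "prr",
               "chi2", "ebgm", "ebgm05", "ic", "ic025", "flag_ror", "flag_prr",
               "flag_bcpnn", "flag_mgps", "positive", "ROR (95% CI)",
               "PRR (chi2)", "EBGM (EBGM05)", "IC (IC025)"]
    if known is not None:
        columns.append("unlabeled")
    if not rows:
        return pd.DataFrame(columns=columns)
    records = []
    for r in rows:
        rec = {
            "event": r.event, "level": r.level, "count": r.a,
            "ror": r.ror, "ror_low": r.ror_low, "ror_high": r.ror_high,
            "prr": r.prr, "chi2": r.chi2,
            "ebgm": r.ebgm, "ebgm05": r.ebgm05, "ic": r.ic, "ic025": r.ic025,
            "flag_ror": r.flag_ror, "flag_prr": r.flag_prr,
            "flag_bcpnn": r.flag_bcpnn, "flag_mgps": r.flag_mgps,
            "positive": r.positive,
            "ROR (95% CI)": f"{_fmt(r.ror)} ({_fmt(r.ror_low)}-{_fmt(r.ror_high)})",
            "PRR (chi2)": f"{_fmt(r.prr)} ({_fmt(r.chi2)})",
            "EBGM (EBGM05)": f"{_fmt(r.ebgm)} ({_fmt(r.ebgm05)})",
            "IC (IC025)": f"{_fmt(r.ic)} ({_fmt(r.ic025)})",
        }
        if known is not None:
            rec["unlabeled"] = "" if r.event in known else "*"
        records.append(rec)
    return pd.DataFrame(records)


# ---------------------------------------------------------------------------
# Subgroups


def _stratum_of(report: ReportRecord, stratifier: str) -> str | None:
    if stratifier == "sex":
        s = (report.sex or "").upper()
        return s if s in {"M", "F"} else None
    if stratifier == "age":
        band = age_band(report.age_years)
        return None if band == "Miss" else band
    raise ValueError(f"unknown stratifier {stratifier!r}; expected 'sex' or 'age'")


def subgroup_analysis(
    stratifier: str,
    reports: Sequence[ReportRecord],
    reactions,
    cohort_ids: set[str],
    events: Sequence[str],
    level: str = "PT",
    ptsoc: PtSocMap | None = None,
    drug_of_report: Mapping[str, str] | None = None,
    prior: MgpsHyperparams | None = None,
    thresholds: Thresholds = Thresholds(),
    margin: str = "pairs",
    top_n: int | None = None,
) -> dict[str, pd.DataFrame]:
    """Re-run the full contingency/statistics/threshold machinery within
    each stratum of ``sex`` or ``age``.

    Both the cohort and the background are restricted to the stratum.  The
    MGPS prior is refitted on the stratum's own drug-event pairs when
    ``drug_of_report`` is supplied (falling back to the classic prior for
    thin strata); otherwise ``prior`` (or the classic prior) is reused.
    Events with no stratum reports are dropped from that stratum's table.
    Strata with zero cohort reports are skipped (logged).
    """
    if stratifier not in {"sex", "age"}:
        raise ValueError(f"unknown stratifier {stratifier!r}; expected 'sex' or 'age'")
    pairs = reactions if isinstance(reactions, pd.DataFrame) else unique_pairs(reactions)
    out: dict[str, pd.DataFrame] = {}
    strata: dict[str, set[str]] = {}
    for rep in reports:
        s = _stratum_of(rep, stratifier)
        if s is not None:
            strata.setdefault(s, set()).add(rep.primary_id)
    for name in sorted(strata):
        ids = strata[name]
        stratum_cohort = cohort_ids & ids
        logger.info("stratum %s=%s: %d reports, %d in cohort",
                    stratifier, name, len(ids), len(stratum_cohort))
        if not stratum_cohort:
            logger.warning("stratum %s=%s has no cohort reports; skipped",
                           stratifier, name)
            continue
        sub_pairs = pairs[pairs["primary_id"].isin(ids)]
        if drug_of_report is not None:
            pc = pair_counts(sub_pairs, drug_of_report)
            sub_prior = fit_mgps_prior(pc["a"], pc["expected"])
        else:
            sub_prior = prior if prior is not None else CLASSIC_PRIOR
        results = []
        for event in events:
            t = build_contingency(event, level, stratum_cohort, sub_pairs,
                                  ptsoc=ptsoc, margin=margin)
            if t.a == 0:
                continue
            results.append(evaluate_signal(t, sub_prior, thresholds))
        out[name] = rank_and_report(results, top_n=top_n)
    return out
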
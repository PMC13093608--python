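"""Time-to-onset computation and Weibull hazard-pattern classification.

Time to onset (TTO) is the interval in days from the start of therapy with
the suspect drug to the onset of the adverse event.  After binning and
summarising, onset times are modelled with a two-parameter Weibull law
whose shape parameter classifies the hazard: shape < 1 means a declining
hazard ("early failure" — most events shortly after initiation), shape = 1
a constant hazard ("random failure"), shape > 1 an increasing hazard
("wear-out").  Classification is read off the 95% CI of the shape, not the
point estimate.
"""

from __future__ import annotations

import datetime as _dt
import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize

logger = logging.getLogger(__name__)

VALID = "valid"
NEGATIVE_EXCLUDED = "negative-excluded"
MISSING_EXCLUDED = "missing-excluded"

#: Published-style TTO bins in days (closed on both ends, last bin open).
TTO_BINS = ((0, 30), (31, 60), (61, 90), (91, 120), (121, 180))
OVERFLOW_LABEL = ">180"


@dataclass(frozen=True)
class TTOSample:
    """Per-report onset interval with validity status."""

    primary_id: str
    tto_days: int | None
    status: str

    def __post_init__(self):
        if (self.tto_days is not None) != (self.status == VALID):
            raise ValueError("tto_days present iff status is valid")


def compute_tto(
    therapy_starts: Mapping[str, Sequence[_dt.date | None]] | Mapping[str, _dt.date | None],
    event_dates: Mapping[str, _dt.date | None],
) -> list[TTOSample]:
    """Onset intervals in whole days for each report.

    ``therapy_starts`` maps a report id to its therapy start date(s) for the
    suspect drug (the earliest day-resolved start is used); ``event_dates``
    maps the id to the event onset date.  Reports lacking a day-resolved
    date on either side are excluded with status ``missing-excluded``;
    negative intervals (event before start) with ``negative-excluded``.
    One TTO per report.
    """
    samples: list[TTOSample] = []
    for pid in sorted(event_dates):
        event = event_dates[pid]
        starts = therapy_starts.get(pid)
        if starts is None:
            starts = []
        elif isinstance(starts, _dt.date):
            starts = [starts]
        starts = [s for s in starts if s is not None]
        if event is None or not starts:
            samples.append(TTOSample(pid, None, MISSING_EXCLUDED))
            continue
        delta = (event - min(starts)).days
        if delta < 0:
            samples.append(TTOSample(pid, None, NEGATIVE_EXCLUDED))
        else:
            samples.append(TTOSample(pid, int(delta), VALID))
    return samples


def valid_days(samples: Sequence[TTOSample]) -> np.ndarray:
    return np.array([s.tto_days for s in samples if s.status == VALID], dtype=float)


def _as_days(samples) -> np.ndarray:
    """Accept either raw day values or TTOSample sequences."""
    seq = list(samples) if not isinstance(samples, np.ndarray) else samples
    if len(seq) and isinstance(seq[0], TTOSample):
        return valid_days(seq)
    return np.asarray(seq, dtype=float)


@dataclass
class TTOSummary:
    """Binned onset counts/percentages plus median and IQR."""

    n_valid: int
    bins: list[tuple[str, int, float]]
    median: float | None
    q1: float | None
    q3: float | None

    @property
    def iqr(self) -> float | None:
        if self.q1 is None or self.q3 is None:
            return None
        return self.q3 - self.q1

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.bins, columns=["bin", "count", "percent"])


def bin_tto(samples: Sequence[TTOSample]) -> TTOSummary:
    """Bin valid onset intervals into [0,30], [31,60], [61,90], [91,120],
    [121,180] and >180 days, with percentages of the valid sample and the
    median/IQR.  Zero valid samples yield an empty summary with a warning."""
    days = valid_days(samples)
    if days.size == 0:
        logger.warning("no valid time-to-onset samples; empty summary")
        return TTOSummary(0, [(f"{lo}-{hi}", 0, 0.0) for lo, hi in TTO_BINS]
                          + [(OVERFLOW_LABEL, 0, 0.0)], None, None, None)
    n = days.size
    rows = []
    for lo, hi in TTO_BINS:
        cnt = int(np.sum((days >= lo) & (days <= hi)))
        rows.append((f"{lo}-{hi}", cnt, round(100.0 * cnt / n, 1)))
    cnt = int(np.sum(days > TTO_BINS[-1][1]))
    rows.append((OVERFLOW_LABEL, cnt, round(100.0 * cnt / n, 1)))
    q1, med, q3 = np.percentile(days, [25, 50, 75])
    return TTOSummary(int(n), rows, float(med), float(q1), float(q3))


@dataclass
class WeibullFit:
    """Weibull MLE with 95% CIs and the hazard-pattern label."""

    scale: float            # alpha, days
    shape: float            # beta, dimensionless
    scale_ci: tuple[float, float]
    shape_ci: tuple[float, float]
    n: int
    failure_type: str       # early | random | wear-out | indeterminate
    converged: bool = True
    message: str = ""

    @property
    def median(self) -> float:
        """Model median alpha * (ln 2)^(1/beta)."""
        return self.scale * math.log(2) ** (1.0 / self.shape)


def _weibull_nll(theta: np.ndarray, x: np.ndarray) -> float:
    log_scale, log_shape = theta
    alpha = math.exp(log_scale)
    beta = math.exp(log_shape)
    z = x / alpha
    return -float(
        x.size * (math.log(beta) - math.log(alpha))
        + (beta - 1) * np.sum(np.log(z))
        - np.sum(z ** beta)
    )


def _hessian(f, theta, eps=1e-4):
    theta = np.asarray(theta, dtype=float)
    k = theta.size
    h = np.empty((k, k))
    for i in range(k):
        for j in range(i, k):
            ei = np.zeros(k); ei[i] = eps
            ej = np.zeros(k); ej[j] = eps
            h[i, j] = h[j, i] = (
                f(theta + ei + ej) - f(theta + ei - ej)
                - f(theta - ei + ej) + f(theta - ei - ej)
            ) / (4 * eps * eps)
    return h


def fit_weibull(
    samples: Sequence[TTOSample] | np.ndarray,
    ci_method: str = "wald",
    n_boot: int = 1000,
    seed: int = 0,
) -> WeibullFit:
    """Maximum-likelihood Weibull fit of valid onset intervals.

    Requires at least 10 valid samples with at least 2 distinct values.
    Same-day onsets (0 days) are shifted to 0.5 day for the likelihood
    (the Weibull density is degenerate at zero for shape < 1) while binning
    elsewhere keeps them as 0.  Confidence intervals are Wald intervals on
    the log-parameters from the finite-difference observed information
    (``ci_method="bootstrap"`` switches to a nonparametric percentile
    bootstrap).  The hazard label is ``early`` when the shape's upper CI is
    below 1, ``wear-out`` when its lower CI exceeds 1, ``random`` when the
    CI contains 1, and ``indeterminate`` when the fit fails.
    """
    x = _as_days(samples)
    x = x[np.isfinite(x)]
    if x.size < 10 or np.unique(x).size < 2:
        raise ValueError("need >= 10 valid samples with >= 2 distinct values")
    x = np.where(x <= 0, 0.5, x)

    # Moment-style start: sd of log X is pi/(sqrt(6) beta) for a Weibull.
    logx = np.log(x)
    sd = float(np.std(logx))
    beta0 = min(max((math.pi / math.sqrt(6)) / max(sd, 1e-6), 0.05), 20.0)
    alpha0 = math.exp(float(np.mean(logx)) + 0.5772156649 / beta0)
    theta0 = np.array([math.log(alpha0), math.log(beta0)])

    res = optimize.minimize(_weibull_nll, theta0, args=(x,), method="Nelder-Mead",
                            options={"xatol": 1e-10, "fatol": 1e-10, "maxiter": 2000})
    if not res.success:
        logger.warning("Weibull MLE did not converge: %s", res.message)
        return WeibullFit(math.nan, math.nan, (math.nan, math.nan),
                          (math.nan, math.nan), int(x.size), "indeterminate",
                          converged=False, message=str(res.message))
    log_alpha, log_beta = res.x
    alpha, beta = math.exp(log_alpha), math.exp(log_beta)

    z = 1.959963984540054
    if ci_method == "bootstrap":
        rng = np.random.default_rng(seed)
        boots = []
        for _ in range(n_boot):
            xb = rng.choice(x, size=x.size, replace=True)
            rb = optimize.minimize(_weibull_nll, res.x, args=(xb,),
                                   method="Nelder-Mead",
                                   options={"xatol": 1e-8, "fatol": 1e-8})
            if rb.success:
                boots.append(np.exp(rb.x))
        boots = np.array(boots)
        alpha_ci = tuple(np.percentile(boots[:, 0], [2.5, 97.5]))
        beta_ci = tuple(np.percentile(boots[:, 1], [2.5, 97.5]))
    else:
        hess = _hessian(lambda t: _weibull_nll(t, x), res.x)
        try:
            cov = np.linalg.inv(hess)
            se = np.sqrt(np.diag(cov))
            if not np.all(np.isfinite(se)):
                raise np.linalg.LinAlgError("non-finite standard errors")
        except np.linalg.LinAlgError as exc:
            logger.warning("observed information not invertible: %s", exc)
            return WeibullFit(alpha, beta, (math.nan, math.nan), (math.nan, math.nan),
                              int(x.size), "indeterminate", converged=False,
                              message=str(exc))
        alpha_ci = (alpha * math.exp(-z * se[0]), alpha * math.exp(z * se[0]))
        beta_ci = (beta * math.exp(-z * se[1]), beta * math.exp(z * se[1]))

    if beta_ci[1] < 1.0:
        label = "early"
    elif beta_ci[0] > 1.0:
        label = "wear-out"
    else:
        label = "random"
    return WeibullFit(alpha, beta, (float(alpha_ci[0]), float(alpha_ci[1])),
                      (float(beta_ci[0]), float(beta_ci[1])), int(x.size), label)


def cumulative_incidence(samples: Sequence[TTOSample] | np.ndarray) -> pd.DataFrame:
    """Right-continuous empirical CDF of onset day.

    Returns a two-column table (day, cumulative fraction), non-decreasing
    and ending at 1.0.
    """
    x = _as_days(samples)
    x = np.sort(x[np.isfinite(x)])
    if x.size == 0:
        return pd.DataFrame(columns=["day", "cum_fraction"])
    days, counts = np.unique(x, return_counts=True)
    frac = np.cumsum(counts) / x.size
    return pd.DataFrame({"day": days, "cum_fraction": frac})
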
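"""Time-to-onset analysis: Weibull shape-parameter test, KM and log-rank.

Onset latency is the number of days from the earliest (full-precision)
therapy start of the tagged drug to each adverse event's date.  Spontaneous
reports contain only realized onsets, so there is no censoring: the
Kaplan-Meier cumulative incidence reduces to the empirical CDF and is
retained for fidelity to standard pharmacovigilance practice.

The Weibull shape parameter beta classifies the hazard profile:

* ``early``    — beta < 1 with the whole 95% CI below 1 (risk decreases);
* ``random``   — the CI contains 1 (roughly constant hazard);
* ``wear-out`` — beta > 1 with the whole CI above 1 (risk increases).

A CI endpoint exactly at 1 classifies as ``random``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import optimize
from statsmodels.tools.numdiff import approx_hess

from .core import CaseReport, DrugLexicon
from .signals import Z95

logger = logging.getLogger(__name__)

FAILURE_TYPES = ("early", "random", "wear-out")


class DegenerateDataError(ValueError):
    """All observations identical; the Weibull shape is unidentifiable."""


@dataclass(frozen=True)
class WeibullFit:
    """Maximum-likelihood Weibull fit with delta-method 95% CIs."""

    scale_alpha: float
    shape_beta: float
    alpha_ci: tuple[float, float]
    beta_ci: tuple[float, float]
    failure_type: str
    n: int
    median_iqr: tuple[float, float, float]


def extract_tto(
    tagged: Mapping[str, Sequence[CaseReport]],
    lexicon: DrugLexicon,
    soc_name: str | None = None,
) -> pd.DataFrame:
    """Onset-day records (``drug, pt, onset_days``) from tagged reports.

    For each report the earliest full-precision therapy start among the drug
    mentions matching the tagged label is used; events without a full event
    date, outside *soc_name* (when given), or with non-positive latency are
    dropped and counted in the log.
    """
    rows = []
    dropped_missing = dropped_nonpositive = 0
    for label, reports in tagged.items():
        for r in reports:
            starts = [
                m.therapy_start
                for m in r.drugs
                if m.therapy_start is not None and lexicon.match(m.verbatim_name) == label
            ]
            start = min(starts) if starts else None
            for ev in r.events:
                if soc_name is not None and ev.soc != soc_name:
                    continue
                if start is None or ev.event_date is None:
                    dropped_missing += 1
                    continue
                days = (ev.event_date - start).days
                if days < 1:
                    dropped_nonpositive += 1
                    continue
                rows.append((label, ev.pt, days))
    if dropped_missing or dropped_nonpositive:
        logger.info(
            "extract_tto dropped %d events with missing dates and %d with non-positive latency",
            dropped_missing,
            dropped_nonpositive,
        )
    return pd.DataFrame(rows, columns=["drug", "pt", "onset_days"])


def median_iqr(ttos: Sequence[float]) -> tuple[float, float, float]:
    """(median, Q1, Q3) using linear-interpolation (type-7) quantiles."""
    t = np.asarray(ttos, dtype=float)
    if t.size == 0:
        raise ValueError("at least one onset is required")
    med, q1, q3 = np.percentile(t, [50, 25, 75])
    return float(med), float(q1), float(q3)


def _weibull_nll(params: np.ndarray, t: np.ndarray) -> float:
    log_alpha, log_beta = params
    alpha, beta = np.exp(log_alpha), np.exp(log_beta)
    z = (t / alpha) ** beta
    ll = t.size * (np.log(beta) - beta * log_alpha) + (beta - 1) * np.sum(np.log(t)) - np.sum(z)
    return -float(ll)


def weibull_mle(ttos: Sequence[float], min_n: int = 10) -> WeibullFit:
    """Weibull maximum-likelihood fit of onset days.

    The shape is found by solving the profile score equation
    ``1/beta + mean(ln t) - sum(t^beta ln t)/sum(t^beta) = 0`` (Brent's
    method); the scale follows in closed form.  95% CIs come from the
    observed-information normal approximation on (ln alpha, ln beta).
    """
    t = np.asarray(ttos, dtype=float)
    if t.size < min_n:
        raise ValueError(f"need at least {min_n} onsets, got {t.size}")
    if np.any(t <= 0):
        raise ValueError("onset days must be positive")
    if np.ptp(t) == 0:
        raise DegenerateDataError("all onset values identical")

    # scale times by the geometric mean so t^beta stays in range
    gm = np.exp(np.mean(np.log(t)))
    u = t / gm
    logu = np.log(u)
    mean_logu = logu.mean()

    def score(beta: float) -> float:
        ub = u**beta
        return 1.0 / beta + mean_logu - float((ub * logu).sum() / ub.sum())

    lo, hi = 1e-2, 50.0
    if score(lo) < 0 or score(hi) > 0:
        raise RuntimeError("Weibull score equation has no root in (0.01, 50)")
    beta = float(optimize.brentq(score, lo, hi, xtol=1e-12))
    alpha = gm * float(np.mean(u**beta)) ** (1.0 / beta)

    params = np.array([np.log(alpha), np.log(beta)])
    hess = approx_hess(params, _weibull_nll, args=(t,))
    cov = np.linalg.inv(hess)
    se = np.sqrt(np.diag(cov))
    if not np.all(np.isfinite(se)):
        raise RuntimeError("observed information is singular at the optimum")
    alpha_ci = (float(np.exp(params[0] - Z95 * se[0])), float(np.exp(params[0] + Z95 * se[0])))
    beta_ci = (float(np.exp(params[1] - Z95 * se[1])), float(np.exp(params[1] + Z95 * se[1])))
    failure = classify_failure_type(beta, beta_ci)
    return WeibullFit(alpha, beta, alpha_ci, beta_ci, failure, int(t.size), median_iqr(t))


def classify_failure_type(shape_beta: float, beta_ci: tuple[float, float]) -> str:
    """Hazard classification from the shape estimate and its 95% CI.

    Total and mutually exclusive: ``early`` iff the CI upper bound < 1,
    ``wear-out`` iff the lower bound > 1, otherwise ``random`` (a CI endpoint
    exactly at 1 is random).
    """
    low, high = beta_ci
    if shape_beta < 1 and high < 1:
        return "early"
    if shape_beta > 1 and low > 1:
        return "wear-out"
    return "random"


def km_curve(ttos: Sequence[float]) -> pd.DataFrame:
    """Kaplan-Meier cumulative incidence (equals the ECDF with no censoring)."""
    t = np.asarray(ttos, dtype=float)
    if t.size == 0:
        raise ValueError("at least one onset is required")
    kmf = KaplanMeierFitter()
    kmf.fit(t, event_observed=np.ones_like(t))
    surv = kmf.survival_function_
    return pd.DataFrame(
        {"time": surv.index.to_numpy(dtype=float), "cum_incidence": 1.0 - surv.iloc[:, 0].to_numpy()}
    )


def log_rank(groups: Mapping[str, Sequence[float]]) -> tuple[float, float]:
    """k-sample log-rank test across drugs; chi-square(k-1) p-value."""
    nonempty = {k: np.asarray(v, dtype=float) for k, v in groups.items() if len(v) > 0}
    if len(nonempty) < 2:
        raise ValueError("log-rank needs at least two non-empty groups")
    durations = np.concatenate(list(nonempty.values()))
    labels = np.concatenate([[k] * v.size for k, v in nonempty.items()])
    res = multivariate_logrank_test(durations, labels, np.ones_like(durations))
    return float(res.test_statistic), float(res.p_value)
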
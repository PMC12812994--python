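"""Disproportionality statistics for drug-event pairs in spontaneous reports.

Four complementary algorithms are computed on the 2x2 fourfold table

    =============  ============  ============
                   target event  other events
    =============  ============  ============
    target drug    a             b
    other drugs    c             d
    =============  ============  ============

with N = a + b + c + d counted at the report-PT pair level:

* ROR — reporting odds ratio ``ad/bc`` with the Woolf (log-normal) 95% CI.
* PRR — proportional reporting ratio ``[a/(a+b)] / [c/(c+d)]`` paired with a
  Yates-corrected Pearson chi-square statistic.
* BCPNN information component — closed-form posterior expectation of
  ``log2 p(drug,event) / (p(drug) p(event))`` under Beta priors
  (Bate et al., 1998), with ``IC025 = E[IC] - 2 sqrt(V[IC])``.
* MGPS — DuMouchel's Gamma-Poisson Shrinker: the observed count a is Poisson
  with mean ``lambda * E`` where ``E = (a+b)(a+c)/N`` and the prior on the
  reporting-rate ratio lambda is a two-component gamma mixture fitted by
  empirical Bayes; EBGM is the posterior geometric mean of lambda and EB05
  its 5th posterior percentile.

A pair is a *signal* when all four criteria hold simultaneously (the
conventional thresholds, each overridable): a >= 3 with ROR CI lower bound
> 1; PRR >= 2 with chi-square >= 4; IC025 > 0; EB05 > 2.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

logger = logging.getLogger(__name__)

Z95 = 1.959963984540054  # two-sided 95% normal quantile
_LN2 = np.log(2.0)


class DegenerateTableError(ValueError):
    """A margin of the fourfold table is zero; the statistic is undefined."""


class FitError(RuntimeError):
    """The empirical-Bayes hyperparameter fit did not converge."""


# ---------------------------------------------------------------------------
# Types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ContingencyTable:
    """Fourfold table for one drug-event pair against the background."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("cell counts must be non-negative")
        if self.n == 0:
            raise ValueError("table must contain at least one report-PT pair")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def expected(self) -> float:
        """Expected count of cell a under independence: (a+b)(a+c)/N."""
        return (self.a + self.b) * (self.a + self.c) / self.n


@dataclass(frozen=True)
class GPSHyperparams:
    """Two-component gamma-mixture prior on the reporting-rate ratio."""

    alpha1: float
    beta1: float
    alpha2: float
    beta2: float
    mix_weight: float
    loglik: float = float("nan")
    converged: bool = True

    def __post_init__(self) -> None:
        if min(self.alpha1, self.beta1, self.alpha2, self.beta2) <= 0:
            raise ValueError("gamma hyperparameters must be positive")
        if not 0 < self.mix_weight < 1:
            raise ValueError("mix_weight must lie in (0, 1)")


@dataclass(frozen=True)
class SignalCriteria:
    """Thresholds of the four-algorithm signal standard (all must hold)."""

    min_count: int = 3
    ror_ci_low: float = 1.0
    prr_min: float = 2.0
    chi2_min: float = 4.0
    ic025_min: float = 0.0
    eb05_min: float = 2.0


@dataclass(frozen=True)
class SignalStats:
    """All four algorithms' estimates for one drug-event pair."""

    drug: str
    pt: str
    n_reports: int
    ror: float
    ror_ci: tuple[float, float]
    prr: float
    chi2: float
    ic: float
    ic025: float
    ebgm: float
    eb05: float
    is_signal: bool
    ror_corrected: bool = False


# ---------------------------------------------------------------------------
# Vectorized statistic kernels (shared by scalar ops and signal_table)
# ---------------------------------------------------------------------------


def _ror_arrays(a, b, c, d, zero_correction: bool = True):
    a, b, c, d = (np.asarray(x, dtype=float) for x in (a, b, c, d))
    corrected = (a == 0) | (b == 0) | (c == 0) | (d == 0)
    if zero_correction:
        # Haldane-Anscombe: add 0.5 to every cell of tables with a zero cell
        shift = np.where(corrected, 0.5, 0.0)
        a, b, c, d = a + shift, b + shift, c + shift, d + shift
    elif corrected.any():
        raise DegenerateTableError("zero cell with continuity correction disabled")
    ror = (a * d) / (b * c)
    se = np.sqrt(1.0 / a + 1.0 / b + 1.0 / c + 1.0 / d)
    low = np.exp(np.log(ror) - Z95 * se)
    high = np.exp(np.log(ror) + Z95 * se)
    return ror, low, high, corrected


def _prr_arrays(a, b, c, d):
    a, b, c, d = (np.asarray(x, dtype=float) for x in (a, b, c, d))
    with np.errstate(divide="ignore", invalid="ignore"):
        prr = (a / (a + b)) / (c / (c + d))
    return prr


def _chi2_yates_arrays(a, b, c, d):
    a, b, c, d = (np.asarray(x, dtype=float) for x in (a, b, c, d))
    n = a + b + c + d
    num = n * np.maximum(np.abs(a * d - b * c) - n / 2.0, 0.0) ** 2
    den = (a + b) * (c + d) * (a + c) * (b + d)
    with np.errstate(divide="ignore", invalid="ignore"):
        chi2 = num / den
    return chi2


# Bate-1998 prior pseudo-counts for the closed-form BCPNN posterior.
_BCPNN_ALPHA1 = 1.0  # drug margin
_BCPNN_BETA1 = 1.0  # event margin
_BCPNN_ALPHA = 2.0
_BCPNN_BETA = 2.0
_BCPNN_GAMMA11 = 1.0


def _ic_arrays(a, b, c, d, prior_scale: float = 1.0):
    a, b, c, d = (np.asarray(x, dtype=float) for x in (a, b, c, d))
    n = a + b + c + d
    a1, b1 = _BCPNN_ALPHA1 * prior_scale, _BCPNN_BETA1 * prior_scale
    al, be, g11 = _BCPNN_ALPHA * prior_scale, _BCPNN_BETA * prior_scale, _BCPNN_GAMMA11 * prior_scale
    # prior joint pseudo-count chosen so that the prior IC expectation is 0
    gamma = g11 * (n + al) * (n + be) / ((a + b + a1) * (a + c + b1))
    ic = np.log2((a + g11) * (n + al) * (n + be) / ((n + gamma) * (a + b + a1) * (a + c + b1)))
    var = (
        (n - a + gamma - g11) / ((a + g11) * (1 + n + gamma))
        + (n - (a + b) + al - a1) / ((a + b + a1) * (1 + n + al))
        + (n - (a + c) + be - b1) / ((a + c + b1) * (1 + n + be))
    ) / (_LN2**2)
    ic025 = ic - 2.0 * np.sqrt(var)
    return ic, ic025


def _gps_log_marginal(a, e, h: GPSHyperparams):
    """Per-cell log marginal likelihood under the negative-binomial mixture."""
    a = np.asarray(a, dtype=float)
    e = np.asarray(e, dtype=float)
    lp1 = stats.nbinom.logpmf(a, h.alpha1, h.beta1 / (h.beta1 + e))
    lp2 = stats.nbinom.logpmf(a, h.alpha2, h.beta2 / (h.beta2 + e))
    return np.logaddexp(np.log(h.mix_weight) + lp1, np.log1p(-h.mix_weight) + lp2)


def _gps_posterior(a, e, h: GPSHyperparams):
    """Posterior mixture over lambda: weights and gamma (shape, rate) pairs."""
    a = np.asarray(a, dtype=float)
    e = np.asarray(e, dtype=float)
    lp1 = np.log(h.mix_weight) + stats.nbinom.logpmf(a, h.alpha1, h.beta1 / (h.beta1 + e))
    lp2 = np.log1p(-h.mix_weight) + stats.nbinom.logpmf(a, h.alpha2, h.beta2 / (h.beta2 + e))
    tot = np.logaddexp(lp1, lp2)
    q1 = np.exp(lp1 - tot)
    s1, r1 = h.alpha1 + a, h.beta1 + e
    s2, r2 = h.alpha2 + a, h.beta2 + e
    return q1, (s1, r1), (s2, r2)


def _ebgm_arrays(a, e, h: GPSHyperparams):
    q1, (s1, r1), (s2, r2) = _gps_posterior(a, e, h)
    elog = q1 * (special.digamma(s1) - np.log(r1)) + (1 - q1) * (special.digamma(s2) - np.log(r2))
    return np.exp(elog)


def _posterior_mixture_cdf(x, q1, s1, r1, s2, r2):
    return q1 * stats.gamma.cdf(x, s1, scale=1.0 / r1) + (1 - q1) * stats.gamma.cdf(x, s2, scale=1.0 / r2)


def _eb_quantile_arrays(a, e, h: GPSHyperparams, prob: float = 0.05, iters: int = 80):
    """Posterior quantile of lambda by vectorized bisection on the mixture CDF."""
    q1, (s1, r1), (s2, r2) = _gps_posterior(a, e, h)
    hi = np.maximum(stats.gamma.ppf(0.9999, s1, scale=1.0 / r1), stats.gamma.ppf(0.9999, s2, scale=1.0 / r2))
    hi = np.maximum(hi * 2.0, 1e-6)
    lo = np.zeros_like(hi)
    for _ in range(iters):
        mid = 0.5 * (lo + hi)
        below = _posterior_mixture_cdf(mid, q1, s1, r1, s2, r2) < prob
        lo = np.where(below, mid, lo)
        hi = np.where(below, hi, mid)
    return 0.5 * (lo + hi)


# ---------------------------------------------------------------------------
# Scalar operations
# ---------------------------------------------------------------------------


def build_contingency(events: pd.DataFrame, drug: str, pt: str) -> ContingencyTable:
    """Fourfold table for (drug, pt) against the full report-PT pair universe.

    *events* is the analysis-ready table from
    :func:`faersig.core.build_event_table` (one row per distinct
    ``(case_id, drug, pt)``).
    """
    pairs = events.drop_duplicates(["case_id", "drug", "pt"])
    is_drug = pairs["drug"] == drug
    is_pt = pairs["pt"] == pt
    a = int((is_drug & is_pt).sum())
    b = int((is_drug & ~is_pt).sum())
    c = int((~is_drug & is_pt).sum())
    d = int((~is_drug & ~is_pt).sum())
    if a + b == 0 or c + d == 0:
        raise DegenerateTableError(f"no report-PT pairs for one drug margin of ({drug!r}, {pt!r})")
    return ContingencyTable(a, b, c, d)


def ror_stat(t: ContingencyTable, zero_correction: bool = True) -> tuple[float, float, float]:
    """Reporting odds ratio with Woolf 95% CI: ``exp(ln ROR +/- 1.96 SE)``.

    Zero cells receive the Haldane-Anscombe 0.5 continuity correction on all
    four cells (flagged in :func:`signal_table` output) unless disabled.
    """
    ror, low, high, _ = _ror_arrays(t.a, t.b, t.c, t.d, zero_correction)
    return float(ror), float(low), float(high)


def prr_chi2(t: ContingencyTable, yates: bool = True) -> tuple[float, float]:
    """PRR with its companion Pearson chi-square (Yates-corrected by default)."""
    if t.a + t.b == 0 or t.c + t.d == 0 or t.a + t.c == 0 or t.b + t.d == 0:
        raise DegenerateTableError("zero margin in fourfold table")
    prr = float(_prr_arrays(t.a, t.b, t.c, t.d))
    if yates:
        chi2 = float(_chi2_yates_arrays(t.a, t.b, t.c, t.d))
    else:
        chi2 = float(stats.chi2_contingency([[t.a, t.b], [t.c, t.d]], correction=False)[0])
    return prr, chi2


def bcpnn_ic(t: ContingencyTable, prior_scale: float = 1.0) -> tuple[float, float]:
    """Closed-form BCPNN information component and its lower bound IC025.

    *prior_scale* multiplies every prior pseudo-count; as it tends to zero
    (and N is large) the posterior expectation approaches the naive
    information component ``log2(a N / ((a+b)(a+c)))``.
    """
    ic, ic025 = _ic_arrays(t.a, t.b, t.c, t.d, prior_scale)
    return float(ic), float(ic025)


def naive_ic(t: ContingencyTable) -> float:
    """Plug-in information component ``log2(a N / ((a+b)(a+c)))``."""
    return float(np.log2(t.a * t.n / ((t.a + t.b) * (t.a + t.c))))


_GPS_STARTS = (
    # DuMouchel's classic starting point plus four dispersed restarts
    (0.2, 0.1, 2.0, 4.0, 1.0 / 3.0),
    (1.0, 1.0, 1.0, 1.0, 0.5),
    (0.5, 0.25, 4.0, 4.0, 0.2),
    (2.0, 2.0, 0.5, 0.5, 0.5),
    (0.1, 0.1, 5.0, 10.0, 0.1),
)


def _theta_to_params(theta) -> GPSHyperparams:
    # clip so intermediate optimizer iterates stay in the valid domain
    a1, b1, a2, b2 = np.clip(np.exp(np.clip(theta[:4], -25, 25)), 1e-10, 1e10)
    w = special.expit(theta[4])
    return GPSHyperparams(float(a1), float(b1), float(a2), float(b2), float(np.clip(w, 1e-12, 1 - 1e-12)))


def gps_fit(a: Iterable[float], expected: Iterable[float], max_iter: int = 500) -> GPSHyperparams:
    """Empirical-Bayes fit of the gamma-mixture hyperparameters.

    Maximizes the marginal (negative-binomial mixture) likelihood of the
    observed counts *a* given independence expectations *expected* over all
    drug-event cells, by L-BFGS-B on log/logit-transformed parameters from
    five documented starting points.  Convergence: relative log-likelihood
    change below 1e-8.
    """
    a = np.asarray(list(a), dtype=float)
    e = np.asarray(list(expected), dtype=float)
    if a.shape != e.shape or a.size == 0:
        raise ValueError("a and expected must be equal-length, non-empty")
    if a.size < 50:
        logger.warning("gps_fit called with only %d cells; estimates may be unstable", a.size)

    def nll(theta):
        h = _theta_to_params(theta)
        return -float(np.sum(_gps_log_marginal(a, e, h)))

    best = None
    last = None
    for start in _GPS_STARTS:
        theta0 = np.array([np.log(start[0]), np.log(start[1]), np.log(start[2]), np.log(start[3]),
                           special.logit(start[4])])
        res = optimize.minimize(nll, theta0, method="L-BFGS-B",
                                options={"maxiter": max_iter, "ftol": 1e-10, "gtol": 1e-6})
        last = res
        if np.isfinite(res.fun) and (best is None or res.fun < best.fun):
            best = res
    if best is None or not np.isfinite(best.fun):
        raise FitError(f"gamma-mixture fit failed to converge; last iterate: {last}")
    h = _theta_to_params(best.x)
    h = replace(h, loglik=-float(best.fun), converged=bool(best.success))
    if not best.success:
        logger.warning("gps_fit: best start terminated without formal convergence (%s)", best.message)
    return h


def gps_fit_tables(tables: Sequence[ContingencyTable], **kwargs) -> GPSHyperparams:
    """Convenience wrapper fitting directly from fourfold tables."""
    return gps_fit([t.a for t in tables], [t.expected for t in tables], **kwargs)


def ebgm_stat(t: ContingencyTable, h: GPSHyperparams) -> tuple[float, float]:
    """EBGM (posterior geometric mean of lambda) and EB05 (5th percentile)."""
    e = t.expected
    if e == 0:
        raise DegenerateTableError("independence expectation is zero")
    ebgm = float(_ebgm_arrays(t.a, e, h))
    eb05 = float(_eb_quantile_arrays(np.array([t.a]), np.array([e]), h, 0.05)[0])
    return ebgm, eb05


def evaluate_signal(s: SignalStats, criteria: SignalCriteria = SignalCriteria()) -> bool:
    """True iff the pair satisfies all four algorithms' thresholds."""
    return (
        s.n_reports >= criteria.min_count
        and s.ror_ci[0] > criteria.ror_ci_low
        and s.prr >= criteria.prr_min
        and s.chi2 >= criteria.chi2_min
        and s.ic025 > criteria.ic025_min
        and s.eb05 > criteria.eb05_min
    )


# ---------------------------------------------------------------------------
# Whole-universe signal table
# ---------------------------------------------------------------------------


def contingency_frame(events: pd.DataFrame) -> pd.DataFrame:
    """All fourfold tables of the universe, one row per (drug, pt) cell."""
    pairs = events.drop_duplicates(["case_id", "drug", "pt"])
    counts = pairs.groupby(["drug", "pt"], sort=True).size().rename("a").reset_index()
    drug_tot = pairs.groupby("drug").size()
    pt_tot = pairs.groupby("pt").size()
    n = len(pairs)
    counts["b"] = counts["drug"].map(drug_tot) - counts["a"]
    counts["c"] = counts["pt"].map(pt_tot) - counts["a"]
    counts["d"] = n - counts["a"] - counts["b"] - counts["c"]
    counts["expected"] = (counts["a"] + counts["b"]) * (counts["a"] + counts["c"]) / n
    return counts


def signal_table(
    events: pd.DataFrame,
    drugs: Sequence[str] | None = None,
    criteria: SignalCriteria = SignalCriteria(),
    hyperparams: GPSHyperparams | None = None,
) -> pd.DataFrame:
    """Compute all four algorithms for every (drug, pt) pair of the universe.

    The gamma-mixture prior is fitted on *all* cells (background drugs
    included); rows are then restricted to *drugs* if given.  Per-criterion
    boolean columns (``sig_ror``, ``sig_prr``, ``sig_ic``, ``sig_ebgm``) are
    emitted alongside the four-algorithm ``is_signal`` flag.
    """
    cells = contingency_frame(events)
    if cells.empty:
        raise ValueError("event table produced no drug-event cells")
    h = hyperparams if hyperparams is not None else gps_fit(cells["a"], cells["expected"])
    if drugs is not None:
        cells = cells[cells["drug"].isin(drugs)].reset_index(drop=True)
    a, b, c, d = (cells[k].to_numpy() for k in "abcd")
    ror, ror_low, ror_high, corrected = _ror_arrays(a, b, c, d)
    prr = _prr_arrays(a, b, c, d)
    chi2 = _chi2_yates_arrays(a, b, c, d)
    ic, ic025 = _ic_arrays(a, b, c, d)
    e = cells["expected"].to_numpy()
    ebgm = _ebgm_arrays(a, e, h)
    eb05 = _eb_quantile_arrays(a, e, h, 0.05)

    out = cells.copy()
    out["ror"], out["ror_low"], out["ror_high"], out["ror_corrected"] = ror, ror_low, ror_high, corrected
    out["prr"], out["chi2"] = prr, chi2
    out["ic"], out["ic025"] = ic, ic025
    out["ebgm"], out["eb05"] = ebgm, eb05
    out["sig_ror"] = (out["a"] >= criteria.min_count) & (out["ror_low"] > criteria.ror_ci_low)
    out["sig_prr"] = (out["prr"] >= criteria.prr_min) & (out["chi2"] >= criteria.chi2_min)
    out["sig_ic"] = out["ic025"] > criteria.ic025_min
    out["sig_ebgm"] = out["eb05"] > criteria.eb05_min
    out["is_signal"] = out["sig_ror"] & out["sig_prr"] & out["sig_ic"] & out["sig_ebgm"]
    out.attrs["gps_hyperparams"] = h
    return out


def rank_tables(
    table: pd.DataFrame, by: Literal["frequency", "ror"] = "frequency", k: int = 10
) -> pd.DataFrame:
    """Top-k signal-positive pairs by report count or by ROR.

    Ties are broken by the other key (descending), then by PT alphabetically.
    """
    if k <= 0:
        raise ValueError("k must be a positive integer")
    if by not in ("frequency", "ror"):
        raise ValueError(f"unknown ranking key {by!r}")
    sig = table[table["is_signal"]].copy()
    keys = ["a", "ror"] if by == "frequency" else ["ror", "a"]
    sig = sig.sort_values(by=[*keys, "pt"], ascending=[False, False, True], kind="mergesort")
    return sig.head(k).reset_index(drop=True)


def stats_from_row(row: Mapping) -> SignalStats:
    """Pack one :func:`signal_table` row into a :class:`SignalStats` record."""
    return SignalStats(
        drug=row["drug"],
        pt=row["pt"],
        n_reports=int(row["a"]),
        ror=float(row["ror"]),
        ror_ci=(float(row["ror_low"]), float(row["ror_high"])),
        prr=float(row["prr"]),
        chi2=float(row["chi2"]),
        ic=float(row["ic"]),
        ic025=float(row["ic025"]),
        ebgm=float(row["ebgm"]),
        eb05=float(row["eb05"]),
        is_signal=bool(row["is_signal"]),
        ror_corrected=bool(row["ror_corrected"]),
    )
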
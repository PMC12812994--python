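"""Sex-stratified disproportionality with volcano-plot coordinates.

For each target drug and PT, reports with known sex are cross-classified as
(male vs female) x (PT vs other PTs) *within the drug's reports* — the
default orientation, so an ROR above 1 reads "this event is reported more
often in males than females on this drug".  The reciprocal question (drug vs
other drugs within one sex stratum) is available behind the ``orientation``
flag.  The chi-square p-value on the same 2x2 supplies the volcano y-axis
(-log10 p); the x-axis is log2 ROR.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .signals import _chi2_yates_arrays, _ror_arrays

logger = logging.getLogger(__name__)

_P_FLOOR = 1e-300  # keeps -log10(p) finite for vanishing p


@dataclass(frozen=True)
class SubgroupResult:
    """Sex-stratified ROR for one drug-event pair."""

    drug: str
    pt: str
    stratum_def: str
    a: int
    b: int
    c: int
    d: int
    ror: float
    ci: tuple[float, float]
    p_value: float
    n_excluded_missing_sex: int

    @property
    def log2_ror(self) -> float:
        return math.log2(self.ror)

    @property
    def neg_log10_p(self) -> float:
        return -math.log10(max(self.p_value, _P_FLOOR))


def sex_stratified_ror(
    events: pd.DataFrame,
    drug: str,
    pt: str,
    orientation: Literal["sex-within-drug", "drug-within-sex"] = "sex-within-drug",
    stratum: str | None = None,
    yates: bool = True,
) -> SubgroupResult | None:
    """Sex-subgroup ROR and chi-square p for one (drug, pt) pair.

    Reports with unknown sex are excluded (their count is recorded).  Returns
    None — flagged in the log — when a margin of the stratified table is
    empty.  ``orientation="drug-within-sex"`` with ``stratum`` in
    {"male", "female"} computes drug-vs-other-drugs within that sex instead.
    """
    pairs = events.drop_duplicates(["case_id", "drug", "pt"])
    known = pairs[pairs["sex"].isin(["male", "female"])]
    excluded = int(pairs.loc[~pairs["sex"].isin(["male", "female"]), "case_id"].nunique())

    if orientation == "sex-within-drug":
        sub = known[known["drug"] == drug]
        is_pt = sub["pt"] == pt
        is_male = sub["sex"] == "male"
        a = int((is_male & is_pt).sum())
        b = int((is_male & ~is_pt).sum())
        c = int((~is_male & is_pt).sum())
        d = int((~is_male & ~is_pt).sum())
        stratum_def = f"male vs female within {drug}"
    elif orientation == "drug-within-sex":
        if stratum not in ("male", "female"):
            raise ValueError("drug-within-sex orientation requires stratum='male' or 'female'")
        sub = known[known["sex"] == stratum]
        is_pt = sub["pt"] == pt
        is_drug = sub["drug"] == drug
        a = int((is_drug & is_pt).sum())
        b = int((is_drug & ~is_pt).sum())
        c = int((~is_drug & is_pt).sum())
        d = int((~is_drug & ~is_pt).sum())
        stratum_def = f"{drug} vs other drugs within {stratum} reports"
    else:
        raise ValueError(f"unknown orientation {orientation!r}")

    if a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0:
        logger.warning("degenerate sex stratum for (%s, %s): a=%d b=%d c=%d d=%d", drug, pt, a, b, c, d)
        return None
    ror, low, high, _ = (float(x) for x in _ror_arrays(a, b, c, d))
    chi2 = float(_chi2_yates_arrays(a, b, c, d)) if yates else float(
        stats.chi2_contingency([[a, b], [c, d]], correction=False)[0]
    )
    p = float(stats.chi2.sf(chi2, df=1))
    return SubgroupResult(drug, pt, stratum_def, a, b, c, d, ror, (low, high), p, excluded)


def volcano_table(
    results: Sequence[SubgroupResult],
    p_adjust: Literal["none", "BH"] = "none",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Volcano-plot coordinates for a collection of subgroup results.

    Significance is non-strict: a pair is flagged when its (optionally
    Benjamini-Hochberg adjusted) p-value is <= *alpha*, so a point exactly at
    the threshold is flagged.
    """
    if not results:
        raise ValueError("at least one subgroup result is required")
    rows = []
    pvals = np.array([r.p_value for r in results])
    if p_adjust == "BH":
        p_adj = multipletests(pvals, method="fdr_bh")[1]
    elif p_adjust == "none":
        p_adj = pvals
    else:
        raise ValueError(f"unknown p_adjust {p_adjust!r}")
    for r, pa in zip(results, p_adj):
        rows.append(
            {
                "drug": r.drug,
                "pt": r.pt,
                "ror": r.ror,
                "ror_low": r.ci[0],
                "ror_high": r.ci[1],
                "p_value": r.p_value,
                "p_adjusted": float(pa),
                "log2_ror": r.log2_ror,
                "neg_log10_p": r.neg_log10_p,
                "significant": bool(pa <= alpha),
            }
        )
    return pd.DataFrame(rows)
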
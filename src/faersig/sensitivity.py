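"""Sensitivity re-analysis: exclude reports co-mentioning a named drug.

Concomitant neurotoxic medication (thalidomide in the default study
conditions) can confound a disproportionality signal.  The sensitivity stage
drops every report that mentions the named drug in a non-primary-suspect
role, re-runs the signal table, and quantifies how stable each drug-event
pair's statistics and signal flag are across the exclusion.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd

from .core import CaseReport, DrugLexicon

logger = logging.getLogger(__name__)


def exclude_concomitant(
    reports: Sequence[CaseReport],
    drug_name: str,
    lexicon: DrugLexicon | None = None,
    include_primary: bool = False,
) -> list[CaseReport]:
    """Drop reports carrying a mention of *drug_name* in any non-primary role.

    *drug_name* is matched through *lexicon* when it is one of its labels
    (brand names included), otherwise by normalized token comparison.  With
    ``include_primary=True`` primary-suspect mentions also trigger exclusion.
    A pure filter: output is a subset of input and the operation is
    idempotent.
    """
    if lexicon is not None and drug_name in lexicon:
        matcher = lexicon
    else:
        matcher = DrugLexicon({drug_name: []})

    kept: list[CaseReport] = []
    removed = 0
    for r in reports:
        hit = any(
            (include_primary or m.role != "primary-suspect")
            and matcher.match(m.verbatim_name) == drug_name
            for m in r.drugs
        )
        if hit:
            removed += 1
        else:
            kept.append(r)
    logger.info("sensitivity exclusion of %r removed %d of %d reports", drug_name, removed, len(reports))
    return kept


def compare_runs(base: pd.DataFrame, filtered: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Pair-by-pair stability report between two signal tables.

    Merges on (drug, pt) — pairs present in only one run appear with absent
    markers — and reports the count change, the ROR ratio and whether the
    four-algorithm signal flag agrees.  The summary gives the percentage of
    pairs whose flag is unchanged.
    """
    cols = ["drug", "pt", "a", "ror", "is_signal"]
    merged = base[cols].merge(filtered[cols], on=["drug", "pt"], how="outer", suffixes=("_base", "_excl"))
    merged["delta_n"] = merged["a_excl"].fillna(0) - merged["a_base"].fillna(0)
    merged["ror_ratio"] = merged["ror_excl"] / merged["ror_base"]
    flag_base = merged["is_signal_base"].eq(True)  # absent pairs count as unflagged
    flag_excl = merged["is_signal_excl"].eq(True)
    merged["flag_unchanged"] = flag_base == flag_excl
    pct = float(100.0 * merged["flag_unchanged"].mean()) if len(merged) else float("nan")
    summary = {
        "n_pairs": int(len(merged)),
        "pct_flags_unchanged": pct,
        "n_flag_gained": int((~flag_base & flag_excl).sum()),
        "n_flag_lost": int((flag_base & ~flag_excl).sum()),
        "median_ror_ratio": float(np.nanmedian(merged["ror_ratio"])) if len(merged) else float("nan"),
    }
    logger.info("signal flags unchanged for %.1f%% of %d pairs", pct, len(merged))
    return merged, summary
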
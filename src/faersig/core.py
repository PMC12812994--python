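"""Case-level preparation of FAERS-style spontaneous adverse event reports.

This module turns raw quarterly-style tables (demographics, drugs, reactions,
therapy dates, outcomes) into an analysis-ready set of deduplicated case
reports, tags the reports whose primary-suspect drug matches a target lexicon,
maps MedDRA Preferred Terms (PTs) to System Organ Classes (SOCs) and produces
the event-level universe on which disproportionality statistics are computed.

File dialects
-------------
``faers-ascii``
    ``$``-delimited text with a header row, one file per table.
``csv``
    Comma-separated equivalents with identical columns.

Expected columns (missing mandatory columns raise :class:`FormatError`):

========  =====================================================
table     columns
========  =====================================================
demo      caseid, caseversion, receipt_dt, sex, age, country, occp_cod
drug      caseid, caseversion, drug_seq, drugname, role_cod
ther      caseid, caseversion, drug_seq, start_dt
reac      caseid, caseversion, pt, event_dt
outc      caseid, caseversion, outc_cod
========  =====================================================

Dates are ``YYYYMMDD``; partial (year- or month-precision) or unparseable
dates become absent — they are never imputed.  Codes follow the FAERS
conventions: sex ``F``/``M``, drug roles ``PS``/``SS``/``C``/``I``,
reporter occupations ``MD``/``CN``/``HP``/``PH``, outcomes
``DE``/``DS``/``HO``/``LT``/``OT``.
"""

from __future__ import annotations

import datetime as _dt
import logging
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml

from ._text import contains_token_phrase, normalize_name

logger = logging.getLogger(__name__)

SEXES = ("female", "male", "unknown")
ROLES = ("primary-suspect", "secondary-suspect", "concomitant", "interacting")
REPORTERS = ("consumer", "health-professional", "pharmacist", "physician", "unknown")
OUTCOMES = ("death", "disability", "hospitalization", "life-threatening", "other")

ROLE_CODES = {"PS": "primary-suspect", "SS": "secondary-suspect", "C": "concomitant", "I": "interacting"}
SEX_CODES = {"F": "female", "M": "male"}
REPORTER_CODES = {"CN": "consumer", "HP": "health-professional", "PH": "pharmacist", "MD": "physician"}
OUTCOME_CODES = {"DE": "death", "DS": "disability", "HO": "hospitalization", "LT": "life-threatening", "OT": "other"}

_CODE_FOR_ROLE = {v: k for k, v in ROLE_CODES.items()}
_CODE_FOR_SEX = {v: k for k, v in SEX_CODES.items()}
_CODE_FOR_REPORTER = {v: k for k, v in REPORTER_CODES.items()}
_CODE_FOR_OUTCOME = {v: k for k, v in OUTCOME_CODES.items()}

DIALECTS = {"faers-ascii": "$", "csv": ","}

_REQUIRED_COLUMNS = {
    "demo": ["caseid", "caseversion", "receipt_dt", "sex", "age", "country", "occp_cod"],
    "drug": ["caseid", "caseversion", "drug_seq", "drugname", "role_cod"],
    "ther": ["caseid", "caseversion", "drug_seq", "start_dt"],
    "reac": ["caseid", "caseversion", "pt", "event_dt"],
    "outc": ["caseid", "caseversion", "outc_cod"],
}

AGE_BANDS = ("<18", "18-64.9", "65-85", ">85", "missing")


class FormatError(ValueError):
    """A mandatory column is missing or a table cannot be parsed."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class DrugMention:
    """One drug row of a report: verbatim name, role code and therapy start."""

    verbatim_name: str
    role: str = "primary-suspect"
    therapy_start: _dt.date | None = None

    def __post_init__(self) -> None:
        if not self.verbatim_name:
            raise ValueError("verbatim_name must be non-empty")
        if self.role not in ROLES:
            raise ValueError(f"unknown drug role {self.role!r}")


@dataclass
class EventMention:
    """One reaction row: MedDRA PT, its SOC once mapped, and the event date."""

    pt: str
    soc: str | None = None
    event_date: _dt.date | None = None

    def __post_init__(self) -> None:
        if not self.pt:
            raise ValueError("pt must be non-empty")


@dataclass
class CaseReport:
    """One safety report version (one ``(case_id, version_id)`` row group)."""

    case_id: str
    version_id: str
    receipt_date: _dt.date | None = None
    sex: str = "unknown"
    age_years: float | None = None
    country: str | None = None
    reporter: str = "unknown"
    outcomes: set[str] = field(default_factory=set)
    drugs: list[DrugMention] = field(default_factory=list)
    events: list[EventMention] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.case_id:
            raise ValueError("case_id must be non-empty")
        if self.sex not in SEXES:
            raise ValueError(f"unknown sex {self.sex!r}")
        if self.reporter not in REPORTERS:
            raise ValueError(f"unknown reporter {self.reporter!r}")
        unknown = set(self.outcomes) - set(OUTCOMES)
        if unknown:
            raise ValueError(f"unknown outcomes {sorted(unknown)}")
        if self.age_years is not None and self.age_years < 0:
            raise ValueError("age_years must be non-negative")


class DrugLexicon:
    """Canonical drug labels with case-insensitive synonym matching.

    Matching is exact-token after casefolding and punctuation stripping:
    a synonym matches a verbatim drug string iff its tokens occur contiguously
    among the verbatim string's tokens.  Synonym sets of different labels must
    be disjoint.
    """

    def __init__(self, synonyms: Mapping[str, Iterable[str]]):
        self._synonyms: dict[str, tuple[str, ...]] = {}
        seen: dict[str, str] = {}
        for label, syns in synonyms.items():
            all_syns = tuple(dict.fromkeys([label, *syns]))
            for s in all_syns:
                key = normalize_name(s)
                if key in seen and seen[key] != label:
                    raise ValueError(f"synonym {s!r} shared by {seen[key]!r} and {label!r}")
                seen[key] = label
            self._synonyms[label] = all_syns

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(self._synonyms)

    def synonyms(self, label: str) -> tuple[str, ...]:
        return self._synonyms[label]

    def match(self, verbatim: str) -> str | None:
        """Return the canonical label matching *verbatim*, or None."""
        for label, syns in self._synonyms.items():
            for s in syns:
                if contains_token_phrase(verbatim, s):
                    return label
        return None

    def __contains__(self, label: str) -> bool:
        return label in self._synonyms

    def __len__(self) -> int:
        return len(self._synonyms)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "DrugLexicon":
        with open(path, "r", encoding="utf-8") as fh:
            mapping = yaml.safe_load(fh) or {}
        return cls(mapping)

    @classmethod
    def from_csv(cls, path: str | Path) -> "DrugLexicon":
        df = pd.read_csv(path, dtype=str)
        mapping: dict[str, list[str]] = {}
        for _, row in df.iterrows():
            mapping.setdefault(row.iloc[0], []).append(row.iloc[1])
        return cls(mapping)


def default_lexicon() -> DrugLexicon:
    """The packaged proteasome-inhibitor target lexicon."""
    with resources.as_file(resources.files("faersig.data") / "target_drugs.yaml") as p:
        return DrugLexicon.from_yaml(p)


def default_concomitant_lexicon() -> DrugLexicon:
    with resources.as_file(resources.files("faersig.data") / "concomitant_drugs.yaml") as p:
        return DrugLexicon.from_yaml(p)


def default_pt_soc_map() -> dict[str, str]:
    """The packaged miniature PT -> SOC mapping."""
    with resources.as_file(resources.files("faersig.data") / "pt_soc.csv") as p:
        return load_pt_soc_map(p)


def load_pt_soc_map(path: str | Path) -> dict[str, str]:
    df = pd.read_csv(path, dtype=str)
    for col in ("pt", "soc"):
        if col not in df.columns:
            raise FormatError(f"missing column {col!r} in PT-SOC mapping {path}")
    return dict(zip(df["pt"], df["soc"]))


# ---------------------------------------------------------------------------
# Ingestion
# ---------------------------------------------------------------------------


def parse_date(value: str | None) -> _dt.date | None:
    """Parse ``YYYYMMDD``; partial or malformed dates become None."""
    if value is None:
        return None
    value = str(value).strip()
    if len(value) != 8 or not value.isdigit():
        return None
    try:
        return _dt.datetime.strptime(value, "%Y%m%d").date()
    except ValueError:
        return None


def _read_table(path: str | Path, name: str, sep: str) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        logger.warning("table %s at %s is empty", name, path)
        return pd.DataFrame(columns=_REQUIRED_COLUMNS[name])
    missing = [c for c in _REQUIRED_COLUMNS[name] if c not in df.columns]
    if missing:
        raise FormatError(f"missing column {missing[0]!r} in {name} table {path}")
    logger.info("read %d rows from %s table %s", len(df), name, path)
    return df


def load_tables(paths: Mapping[str, str | Path], dialect: str = "faers-ascii") -> list[CaseReport]:
    """Read a bundle of FAERS-dialect tables into :class:`CaseReport` objects.

    *paths* maps table names (``demo``, ``drug``, ``reac``; optionally
    ``ther``, ``outc``) to file locations.  One report is produced per
    ``(caseid, caseversion)`` group present in the demographics table.
    """
    if dialect not in DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of {sorted(DIALECTS)}")
    sep = DIALECTS[dialect]
    for required in ("demo", "drug", "reac"):
        if required not in paths:
            raise ValueError(f"paths must include the {required!r} table")

    demo = _read_table(paths["demo"], "demo", sep).drop_duplicates(subset=["caseid", "caseversion"])
    drug = _read_table(paths["drug"], "drug", sep)
    reac = _read_table(paths["reac"], "reac", sep)
    ther = _read_table(paths["ther"], "ther", sep) if "ther" in paths else pd.DataFrame(columns=_REQUIRED_COLUMNS["ther"])
    outc = _read_table(paths["outc"], "outc", sep) if "outc" in paths else pd.DataFrame(columns=_REQUIRED_COLUMNS["outc"])

    key = ["caseid", "caseversion"]
    starts: dict[tuple[str, str, str], _dt.date | None] = {}
    for row in ther.itertuples(index=False):
        starts[(row.caseid, row.caseversion, row.drug_seq)] = parse_date(row.start_dt)

    drugs_by_case: dict[tuple[str, str], list[DrugMention]] = {}
    for row in drug.itertuples(index=False):
        mention = DrugMention(
            verbatim_name=row.drugname,
            role=ROLE_CODES.get(row.role_cod, "concomitant"),
            therapy_start=starts.get((row.caseid, row.caseversion, row.drug_seq)),
        )
        drugs_by_case.setdefault((row.caseid, row.caseversion), []).append(mention)

    events_by_case: dict[tuple[str, str], list[EventMention]] = {}
    for row in reac.itertuples(index=False):
        events_by_case.setdefault((row.caseid, row.caseversion), []).append(
            EventMention(pt=row.pt, event_date=parse_date(row.event_dt))
        )

    outcomes_by_case: dict[tuple[str, str], set[str]] = {}
    for row in outc.itertuples(index=False):
        code = OUTCOME_CODES.get(row.outc_cod)
        if code is not None:
            outcomes_by_case.setdefault((row.caseid, row.caseversion), set()).add(code)

    reports: list[CaseReport] = []
    for row in demo.itertuples(index=False):
        k = (row.caseid, row.caseversion)
        age: float | None
        try:
            age = float(row.age)
            if age < 0:
                age = None
        except (TypeError, ValueError):
            age = None
        reports.append(
            CaseReport(
                case_id=row.caseid,
                version_id=row.caseversion,
                receipt_date=parse_date(row.receipt_dt),
                sex=SEX_CODES.get(row.sex, "unknown"),
                age_years=age,
                country=row.country or None,
                reporter=REPORTER_CODES.get(row.occp_cod, "unknown"),
                outcomes=outcomes_by_case.get(k, set()),
                drugs=drugs_by_case.get(k, []),
                events=events_by_case.get(k, []),
            )
        )
    known = {(r.case_id, r.version_id) for r in reports}
    orphans = (set(drugs_by_case) | set(events_by_case)) - known
    if orphans:
        logger.warning("%d drug/reaction row-groups without a demographics row were ignored", len(orphans))
    logger.info("loaded %d case versions", len(reports))
    return reports


# ---------------------------------------------------------------------------
# Deduplication and tagging
# ---------------------------------------------------------------------------


def _version_key(version_id: str) -> tuple[int, int, str]:
    # numeric versions compare numerically and sort below non-numeric ones
    v = version_id.strip()
    if v.isdigit():
        return (0, int(v), "")
    return (1, 0, v)


def deduplicate(reports: Sequence[CaseReport]) -> list[CaseReport]:
    """Keep one version per ``case_id``: the latest ``receipt_date``, ties
    broken by the greatest ``version_id``.  Reports without a receipt date
    sort before any dated version."""
    best: dict[str, CaseReport] = {}
    for r in reports:
        cur = best.get(r.case_id)
        if cur is None:
            best[r.case_id] = r
            continue
        key = (r.receipt_date or _dt.date.min, _version_key(r.version_id))
        cur_key = (cur.receipt_date or _dt.date.min, _version_key(cur.version_id))
        if key > cur_key:
            best[r.case_id] = r
    out = list(best.values())
    removed = len(reports) - len(out)
    if removed:
        logger.info("deduplication removed %d of %d report versions", removed, len(reports))
    return out


def select_target_reports(
    reports: Sequence[CaseReport], lexicon: DrugLexicon
) -> dict[str, list[CaseReport]]:
    """Tag deduplicated reports whose primary-suspect drug matches *lexicon*.

    Returns a mapping from canonical drug label to the reports tagged for it.
    A report is tagged at most once per label; a report whose primary-suspect
    mentions match several labels contributes to each (logged).
    """
    if len(lexicon) == 0:
        raise ValueError("lexicon must contain at least one drug label")
    tagged: dict[str, list[CaseReport]] = {label: [] for label in lexicon.labels}
    multi = 0
    for r in reports:
        labels = set()
        for m in r.drugs:
            if m.role != "primary-suspect":
                continue
            label = lexicon.match(m.verbatim_name)
            if label is not None:
                labels.add(label)
        for label in labels:
            tagged[label].append(r)
        if len(labels) > 1:
            multi += 1
    if multi:
        logger.info("%d reports are co-suspect for more than one target drug", multi)
    for label, rs in tagged.items():
        logger.info("tagged %d reports for %s", len(rs), label)
    return tagged


def map_soc(reports: Sequence[CaseReport], pt_to_soc: Mapping[str, str]) -> Sequence[CaseReport]:
    """Fill each event's SOC from a PT -> SOC mapping (case-insensitive on PT).

    Events whose PT is absent from the mapping keep ``soc=None`` and are
    counted in a log line.  Returns the same report sequence for chaining.
    """
    if not pt_to_soc:
        raise ValueError("pt_to_soc mapping must cover at least one PT")
    lookup = {pt.casefold(): soc for pt, soc in pt_to_soc.items()}
    unmapped = 0
    for r in reports:
        for ev in r.events:
            soc = lookup.get(ev.pt.casefold())
            if soc is None:
                unmapped += 1
            ev.soc = soc
    if unmapped:
        logger.warning("%d event mentions had PTs absent from the SOC mapping", unmapped)
    return reports


# ---------------------------------------------------------------------------
# Event-level universe
# ---------------------------------------------------------------------------


def build_event_table(reports: Sequence[CaseReport], lexicon: DrugLexicon) -> pd.DataFrame:
    """Build the report-PT pair universe used by disproportionality stats.

    One row per distinct ``(case_id, drug, pt)``: the drug is the canonical
    lexicon label when the primary suspect matches, otherwise the normalized
    verbatim name of the first primary-suspect mention.  Reports without any
    primary-suspect mention are skipped (logged).  Columns:
    ``case_id, drug, pt, soc, sex``.
    """
    rows: list[tuple[str, str, str, str | None, str]] = []
    skipped = 0
    for r in reports:
        ps = [m for m in r.drugs if m.role == "primary-suspect"]
        if not ps:
            skipped += 1
            continue
        labels: list[str] = []
        for m in ps:
            lab = lexicon.match(m.verbatim_name)
            if lab is not None and lab not in labels:
                labels.append(lab)
        if not labels:
            labels = [normalize_name(ps[0].verbatim_name)]
        seen: set[tuple[str, str]] = set()
        for lab in labels:
            for ev in r.events:
                if (lab, ev.pt) in seen:
                    continue
                seen.add((lab, ev.pt))
                rows.append((r.case_id, lab, ev.pt, ev.soc, r.sex))
    if skipped:
        logger.info("%d reports without a primary-suspect drug were skipped", skipped)
    return pd.DataFrame(rows, columns=["case_id", "drug", "pt", "soc", "sex"])


def restrict_to_soc(events: pd.DataFrame, soc_name: str) -> pd.DataFrame:
    """Event records whose SOC equals *soc_name* (empty + warning if unknown)."""
    if soc_name not in set(events["soc"].dropna()):
        logger.warning("SOC %r not present in the event table", soc_name)
        return events.iloc[0:0].copy()
    return events[events["soc"] == soc_name].copy()


# ---------------------------------------------------------------------------
# Descriptive summary
# ---------------------------------------------------------------------------


def percentage(n: int, total: int) -> float:
    """Percentage of *n* out of *total*, rounded half-up to one decimal."""
    if total == 0:
        return 0.0
    return float((Decimal(n) * 100 / Decimal(total)).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def _age_band(age: float | None) -> str:
    if age is None:
        return "missing"
    if age < 18:
        return "<18"
    if age < 65:
        return "18-64.9"
    if age <= 85:
        return "65-85"
    return ">85"


def summarize_baseline(tagged: Mapping[str, Sequence[CaseReport]], top_countries: int = 6) -> pd.DataFrame:
    """Per-drug demographic summary in the style of a baseline table.

    Counts and percentages (against the drug's total report count) for sex,
    age bands, reporter source, the top reporting countries and outcome
    categories.  Outcome categories are not a partition — a report may carry
    several outcomes.
    """
    rows = []
    for drug, reports in tagged.items():
        total = len(reports)

        def add(category: str, level: str, n: int) -> None:
            rows.append((drug, category, level, n, percentage(n, total)))

        sex_counts = {"female": 0, "male": 0, "missing": 0}
        for r in reports:
            sex_counts["missing" if r.sex == "unknown" else r.sex] += 1
        for level in ("female", "male", "missing"):
            add("sex", level, sex_counts[level])

        age_counts = {band: 0 for band in AGE_BANDS}
        for r in reports:
            age_counts[_age_band(r.age_years)] += 1
        for band in AGE_BANDS:
            add("age", band, age_counts[band])

        rep_counts = {level: 0 for level in REPORTERS}
        for r in reports:
            rep_counts[r.reporter] += 1
        for level in ("consumer", "health-professional", "pharmacist", "physician"):
            add("reporter", level, rep_counts[level])
        add("reporter", "missing", rep_counts["unknown"])

        country_counts: dict[str, int] = {}
        for r in reports:
            country_counts[r.country or "missing"] = country_counts.get(r.country or "missing", 0) + 1
        top = sorted(country_counts.items(), key=lambda kv: (-kv[1], kv[0]))[:top_countries]
        for country, n in top:
            add("country", country, n)

        for outcome in OUTCOMES:
            add("outcome", outcome, sum(1 for r in reports if outcome in r.outcomes))

    return pd.DataFrame(rows, columns=["drug", "category", "level", "n", "pct"])
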
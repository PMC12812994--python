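"""End-to-end pipeline: one YAML config in, reproducible tables out.

The pipeline chains ingestion (or synthetic generation), deduplication,
target tagging, SOC mapping, the four-algorithm signal table, frequency and
signal-strength rankings, the sex-subgroup volcano table, time-to-onset
(Weibull + KM + log-rank) and the concomitant-exclusion sensitivity
re-analysis.  All randomness flows from a single root seed; a run manifest
records the config hash, the seed, library versions and row counts at every
stage so that identical configs give byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

from . import core, onset, sensitivity, signals, subgroup, synthetic

logger = logging.getLogger(__name__)

STAGES = ("simulate", "ingest", "signals", "subgroup", "tto", "sensitivity")


class ConfigError(ValueError):
    """The pipeline config does not validate against the schema."""


@dataclass
class PipelineConfig:
    """Validated pipeline configuration (see ``ConfigError`` for schema)."""

    synthetic: synthetic.SyntheticConfig | None = None
    input: dict | None = None
    lexicon: str | None = None
    concomitant_lexicon: str | None = None
    pt_soc_map: str | None = None
    soc_of_interest: str = "Nervous system disorders"
    thresholds: signals.SignalCriteria = field(default_factory=signals.SignalCriteria)
    top_k: int = 10
    subgroup_min_count: int = 3
    p_adjust: str = "none"
    tto_min_n: int = 10
    sensitivity_exclude: str = "thalidomide"
    seed: int | None = None

    @classmethod
    def from_dict(cls, raw: Mapping) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        bad = sorted(set(raw) - known)
        if bad:
            raise ConfigError(f"unknown config keys: {bad}")
        kw = dict(raw)
        if ("synthetic" in kw) == ("input" in kw):
            raise ConfigError("config must contain exactly one of 'synthetic' or 'input'")
        if "synthetic" in kw:
            try:
                kw["synthetic"] = synthetic.SyntheticConfig.from_dict(kw["synthetic"] or {})
            except (TypeError, ValueError) as exc:
                raise ConfigError(f"invalid 'synthetic' block: {exc}") from exc
        if "input" in kw:
            inp = kw["input"] or {}
            missing = [k for k in ("demo", "drug", "reac") if k not in inp]
            if missing:
                raise ConfigError(f"input block missing table paths: {missing}")
            if "pt_soc_map" not in raw:
                raise ConfigError("config key 'pt_soc_map' is required when ingesting files")
        if "thresholds" in kw:
            try:
                kw["thresholds"] = signals.SignalCriteria(**(kw["thresholds"] or {}))
            except TypeError as exc:
                raise ConfigError(f"invalid 'thresholds' block: {exc}") from exc
        cfg = cls(**kw)
        if cfg.top_k <= 0:
            raise ConfigError("top_k must be positive")
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    def canonical_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if self.synthetic is not None:
            d["synthetic"] = self.synthetic.to_dict()
        if self.thresholds is not None:
            d["thresholds"] = dataclasses.asdict(self.thresholds)
        return d


def _config_hash(cfg: PipelineConfig) -> str:
    blob = json.dumps(cfg.canonical_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def run_pipeline(
    config: PipelineConfig | str | Path,
    outdir: str | Path,
    seed: int | None = None,
    stages: Sequence[str] = STAGES,
) -> dict:
    """Execute the requested stages and write their outputs under *outdir*.

    Returns the run manifest (also written as ``manifest.json``).  Stage
    accounting is conserved: at every filter the number of retained plus
    dropped reports equals the input count, and the counts are recorded.
    """
    if not isinstance(config, PipelineConfig):
        config = PipelineConfig.from_yaml(config)
    bad = sorted(set(stages) - set(STAGES))
    if bad:
        raise ValueError(f"unknown stages: {bad}")
    stages = set(stages)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    if seed is None:
        seed = config.seed
    manifest: dict = {"config_hash": _config_hash(config), "seed": seed, "counts": {}, "versions": _versions()}

    lexicon = core.DrugLexicon.from_yaml(config.lexicon) if config.lexicon else core.default_lexicon()
    conc_lex = (
        core.DrugLexicon.from_yaml(config.concomitant_lexicon)
        if config.concomitant_lexicon
        else core.default_concomitant_lexicon()
    )
    pt_soc = core.load_pt_soc_map(config.pt_soc_map) if config.pt_soc_map else core.default_pt_soc_map()

    # --- acquire reports -------------------------------------------------
    if config.synthetic is not None:
        syn_cfg = config.synthetic
        if seed is not None:
            syn_cfg = dataclasses.replace(syn_cfg, seed=seed)
        reports, truth = synthetic.generate(syn_cfg)
        if "simulate" in stages:
            bundle_dir = outdir / "bundle"
            synthetic.write_bundle(reports, bundle_dir)
            truth.to_json(bundle_dir / "ground_truth.json")
        manifest["counts"]["generated_case_versions"] = len(reports)
    else:
        inp = dict(config.input)
        dialect = inp.pop("dialect", "faers-ascii")
        reports = core.load_tables(inp, dialect=dialect)
        manifest["counts"]["loaded_case_versions"] = len(reports)

    # --- dedup / tag / map ----------------------------------------------
    deduped = core.deduplicate(reports)
    manifest["counts"]["after_dedup"] = len(deduped)
    manifest["counts"]["duplicates_removed"] = len(reports) - len(deduped)

    tagged = core.select_target_reports(deduped, lexicon)
    manifest["counts"]["tagged_per_drug"] = {k: len(v) for k, v in tagged.items()}
    core.map_soc(deduped, pt_soc)
    events = core.build_event_table(deduped, lexicon)
    manifest["counts"]["event_pairs"] = int(len(events))

    baseline = core.summarize_baseline(tagged)
    baseline.to_csv(outdir / "baseline.csv", index=False)

    if "ingest" in stages and config.synthetic is None:
        pass  # counts above are the ingest deliverable

    soc_name = config.soc_of_interest
    want_stats = stages & {"signals", "subgroup", "sensitivity"}
    table = None
    if want_stats:
        table = signals.signal_table(events, drugs=list(lexicon.labels), criteria=config.thresholds)
        table["soc"] = table["pt"].map(pt_soc)

    if "signals" in stages:
        table.to_csv(outdir / "signals.csv", index=False)
        soc_table = table[table["soc"] == soc_name]
        top_freq = signals.rank_tables(soc_table, "frequency", config.top_k)
        top_ror = signals.rank_tables(soc_table, "ror", config.top_k)
        top_freq.to_csv(outdir / "top_frequency.csv", index=False)
        top_ror.to_csv(outdir / "top_ror.csv", index=False)
        bubble = top_ror.reset_index().rename(columns={"index": "rank"})
        bubble["rank"] += 1
        bubble[["rank", "drug", "pt", "a", "ror"]].rename(columns={"a": "size", "ror": "color"}).to_csv(
            outdir / "bubble.csv", index=False
        )
        manifest["counts"]["signal_pairs"] = int(table["is_signal"].sum())

    if "subgroup" in stages:
        soc_cells = table[(table["soc"] == soc_name) & (table["a"] >= config.subgroup_min_count)]
        results = []
        for row in soc_cells.itertuples(index=False):
            res = subgroup.sex_stratified_ror(events, row.drug, row.pt)
            if res is not None:
                results.append(res)
        if results:
            volcano = subgroup.volcano_table(results, p_adjust=config.p_adjust)
            volcano.to_csv(outdir / "volcano.csv", index=False)
            manifest["counts"]["subgroup_pairs"] = len(results)
        else:
            logger.warning("no subgroup pair met the count floor; volcano table not written")

    if "tto" in stages:
        tto = onset.extract_tto(tagged, lexicon, soc_name)
        fits = []
        groups = {}
        for drug in lexicon.labels:
            days = tto.loc[tto["drug"] == drug, "onset_days"]
            if len(days) >= config.tto_min_n:
                fit = onset.weibull_mle(days, min_n=config.tto_min_n)
                med, q1, q3 = fit.median_iqr
                fits.append(
                    {
                        "drug": drug,
                        "n": fit.n,
                        "median_days": med,
                        "q1_days": q1,
                        "q3_days": q3,
                        "min_days": int(days.min()),
                        "max_days": int(days.max()),
                        "scale_alpha": fit.scale_alpha,
                        "alpha_low": fit.alpha_ci[0],
                        "alpha_high": fit.alpha_ci[1],
                        "shape_beta": fit.shape_beta,
                        "beta_low": fit.beta_ci[0],
                        "beta_high": fit.beta_ci[1],
                        "failure_type": fit.failure_type,
                    }
                )
                groups[drug] = days.to_numpy()
                onset.km_curve(days).to_csv(outdir / f"km_{drug}.csv", index=False)
        pd.DataFrame(fits).to_csv(outdir / "weibull.csv", index=False)
        if len(groups) >= 2:
            stat, p = onset.log_rank(groups)
            manifest["logrank"] = {"statistic": stat, "p_value": p}
        manifest["counts"]["tto_records"] = int(len(tto))

    if "sensitivity" in stages:
        kept = sensitivity.exclude_concomitant(deduped, config.sensitivity_exclude, conc_lex)
        manifest["counts"]["sensitivity_excluded"] = len(deduped) - len(kept)
        events_excl = core.build_event_table(kept, lexicon)
        table_excl = signals.signal_table(events_excl, drugs=list(lexicon.labels), criteria=config.thresholds)
        stability, summary = sensitivity.compare_runs(table, table_excl)
        stability.to_csv(outdir / "sensitivity_stability.csv", index=False)
        manifest["sensitivity"] = summary

    with open(outdir / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest


def _versions() -> dict[str, str]:
    import lifelines
    import numpy
    import scipy

    from . import __version__

    return {
        "faersig": __version__,
        "numpy": numpy.__version__,
        "pandas": pd.__version__,
        "scipy": scipy.__version__,
        "lifelines": lifelines.__version__,
    }
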
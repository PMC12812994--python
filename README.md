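# faersig

Disproportionality signal detection and time-to-onset modelling for
FAERS-style spontaneous adverse event reports, built around the
pharmacovigilance question of proteasome-inhibitor neurotoxicity
(bortezomib / VELCADE, carfilzomib / KYPROLIS, ixazomib / NINLARO), with a
synthetic FAERS-like generator that provides exact ground truth for every
stage.

## Who this is for

Pharmacoepidemiologists and biostatisticians who want a tested, reproducible
pipeline for spontaneous-report safety analyses: reading FAERS-dialect
quarterly tables, deduplicating multi-version cases, tagging primary-suspect
reports of target drugs, mapping MedDRA PTs to SOCs, computing the four
standard disproportionality statistics, stratifying by sex, fitting onset
latencies, and checking robustness to a concomitant drug.

## Methods in brief

For each drug–event pair a fourfold table `a, b, c, d` is counted at the
report–PT pair level (N = a+b+c+d), and four algorithms are computed:

* **ROR** = `ad/bc` with Woolf 95% CI `exp(ln ROR ± 1.96·√(1/a+1/b+1/c+1/d))`;
* **PRR** = `[a/(a+b)] / [c/(c+d)]` with a Yates-corrected χ²;
* **BCPNN IC** — closed-form posterior expectation of
  `log₂ p(drug,event)/(p(drug)p(event))` under Beta priors (Bate et al. 1998),
  with `IC025 = IC − 2√V(IC)`;
* **MGPS EBGM** — DuMouchel's Gamma-Poisson Shrinker: `a ~ Poisson(λE)` with
  `E = (a+b)(a+c)/N` and a two-component gamma-mixture prior on λ fitted by
  empirical Bayes; EBGM is the posterior geometric mean, EB05 its 5th
  percentile.

A pair is a **signal** when all four criteria hold: `a ≥ 3` and ROR CI lower
bound > 1; PRR ≥ 2 and χ² ≥ 4; IC025 > 0; EB05 > 2 (each threshold
configurable).

Sex subgroups use a (male vs female) × (PT vs other PTs) table within a
drug's reports, plotted as a volcano (x = log₂ ROR, y = −log₁₀ p).
Time to onset (therapy start → event date, whole days ≥ 1) is fitted by
Weibull maximum likelihood; the shape β classifies the hazard as *early*
(CI < 1), *random* (CI spans 1) or *wear-out* (CI > 1); drugs are compared
by Kaplan–Meier cumulative incidence and the log-rank test.

## Worked example

```bash
faersig all --config config.yaml --outdir out
```

with a minimal `config.yaml`:

```yaml
synthetic:
  n_cases: 20000
  seed: 1
```

`out/top_ror.csv` then ranks the nervous-system signal pairs by strength —
the four planted associations, and nothing else, are flagged:

```
       drug                          pt   a   ror  ror_low  ror_high   ic  ic025  ebgm  eb05
 bortezomib              Polyneuropathy 506 24.90    21.83     28.41 3.28   3.12  9.89  9.18
carfilzomib Hypertensive encephalopathy 401 15.04    13.14     17.21 2.92   2.74  7.70  7.08
   ixazomib       Burning feet syndrome 392 14.64    12.78     16.78 2.90   2.72  7.59  6.98
 bortezomib       Neuropathy peripheral 273 10.37     8.91     12.06 2.67   2.46  6.47  5.85
```

(`a` is the report count; the EBGM column shows the empirical-Bayes
shrinkage of the raw ROR.)  `out/weibull.csv` holds the onset analysis:

```
       drug   n  median_days  q1_days  q3_days  scale_alpha  shape_beta  beta_low  beta_high failure_type
 bortezomib 849         39.0    12.00   102.00        67.49        0.75      0.71       0.79        early
carfilzomib 734         48.0    11.00   131.75        82.56        0.67      0.64       0.71        early
   ixazomib 748         98.0    25.75   282.00       168.78        0.69      0.66       0.73        early
```

All three drugs show an early-failure profile (β 95% CI below 1 — the
hazard of a neurological event declines over treatment time), and the
log-rank test separates the three onset distributions
(statistic 172.6, p ≈ 3×10⁻³⁸).  The run also writes the baseline
demographics table, the full signal table, the sex-subgroup volcano
coordinates, per-drug KM curves, the thalidomide-exclusion stability report
(100% of signal flags unchanged here) and a manifest with the seed, config
hash and row counts at every stage; identical config + seed reruns are
byte-identical.

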
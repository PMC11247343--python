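# faers-signal

Disproportionality analysis of spontaneous adverse-event reports, built
around the infection-safety question for the CDK4/6 inhibitors
(palbociclib, ribociclib, abemaciclib) used in hormone-receptor-positive
breast cancer.

Spontaneous-report databases such as the FDA Adverse Event Reporting
System (FAERS) collect voluntary case reports linking a patient's drug
exposures — each with a role code: primary suspect (PS), secondary suspect
(SS), concomitant (C), interacting (I) — to adverse-event *preferred
terms* (PTs, MedDRA's unit concept), grouped into *system organ classes*
(SOCs). Because there is no denominator population, safety signals are
screened by **disproportionality**: is a drug–event pair reported more
often than the database background would predict?

## The statistic

For a target drug and target PT, count

|             | target PT | other PTs |
|-------------|-----------|-----------|
| target drug | a         | b         |
| other drugs | c         | d         |

The **reporting odds ratio** is

```
ROR = (a/c) / (b/d),
95% CI = exp( ln ROR ± 1.96 · sqrt(1/a + 1/b + 1/c + 1/d) )
```

and a pair is screened in as a signal when **a ≥ 3 and the lower 95%
confidence bound exceeds 1**. Zero cells are reported as undefined
(no continuity correction) and never signal.

The package implements the full workflow as composable modules:

- `faers_signal.io` — parsers for FAERS-style `$`-delimited quarterly
  tables (DEMO/DRUG/REAC/OUTC) and an equivalent TSV dialect;
  case-version deduplication; PT→SOC map and drug-synonym loading.
- `faers_signal.signal` — contingency counting (report–PT pair or
  report-level conventions), ROR with Woolf CI, signal screening.
- `faers_signal.pipeline` — the five-step procedure: extract each drug's
  PTs, keep those in the infection-related SOCs, ROR-screen them, enrol
  the signals, and retrieve the primary-suspect cases listing them.
- `faers_signal.descriptives` — clinical-characteristics tables, outcome
  and severity tables, Pearson chi-square severity comparisons, yearly
  trend of infection cases among all PS reports.
- `faers_signal.simulate` — a seedable generator of FAERS-like synthetic
  databases with planted drug–PT enrichments and full ground truth.
- `faers_signal.cli` — the `faers-signal` command (`run`, `simulate`,
  `report`).

## Worked example

Generate a 5,000-report synthetic database (three CDK4/6 inhibitors among
endocrine/chemotherapy comparators, with planted infection enrichments),
deduplicate it, and screen ribociclib against every PT in the universe:

```python
import faers_signal as fs

config = fs.default_config(n_reports=5000, seed=42)
reports, truth = fs.generate(config)
dedup = fs.deduplicate(reports)           # 5278 raw rows -> 5000 cases
results = fs.screen_signals(
    dedup, ["ribociclib"], [p.name for p in config.pts], drug_name="ribociclib"
)
print(fs.signals_frame(results).head(6).round(2).to_string(index=False))
```

```
      drug         pt  a   b   c    d  ror  ci_low  ci_high  is_signal
ribociclib cellulitis 20 215  73 6411 8.17    4.89    13.65       True
ribociclib  pneumonia 36 199 245 6239 4.61    3.16     6.72       True
ribociclib   alopecia  9 226 289 6195 0.85    0.43     1.68      False
ribociclib arthralgia  8 227 287 6197 0.76    0.37     1.56      False
ribociclib      cough 10 225 297 6187 0.93    0.49     1.76      False
ribociclib  diarrhoea 23 212 797 5687 0.77    0.50     1.20      False
```

The two planted ribociclib enrichments (cellulitis, relative rate 8;
pneumonia, rate 6) are flagged: cellulitis was reported 20 times with
ribociclib where independence would predict about 2.5-fold fewer, an ROR
of 8.17 whose CI lower bound (4.89) is far above 1. The background PTs sit
near ROR = 1 and none signals.

The full pipeline gives per-drug stage counts (total AE pairs → cases in
the infection SOCs enrolled by screening → those with the drug as primary
suspect):

```python
from faers_signal.pipeline import PipelineConfig, TargetDrug, run_pipeline

pcfg = PipelineConfig(target_drugs=(
    TargetDrug("palbociclib"), TargetDrug("ribociclib"), TargetDrug("abemaciclib"),
))
result = run_pipeline(pcfg, reports, fs.pt_soc_map_of(config))
print(result.stage_counts_frame().to_string(index=False))
```

```
       drug  total_aes  infection_aes  infection_aes_ps
palbociclib        505            100                31
 ribociclib        224             52                13
abemaciclib        118             12                 6
```

The same workflow runs from the shell:

```
faers-signal simulate --out-dir fixtures/ --n-reports 5000 --seed 42
faers-signal run --config config.yaml \
    --demo fixtures/simple_tsv/demo.tsv --drug fixtures/simple_tsv/drug.tsv \
    --reac fixtures/simple_tsv/reac.tsv --outc fixtures/simple_tsv/outc.tsv \
    --pt-soc-map fixtures/pt_soc_map.tsv --out-dir out/
faers-signal report --run-dir out/
```

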
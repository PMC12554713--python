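# pvsignal

Disproportionality signal detection for FAERS-style spontaneous
adverse-event reports, built around the motivating question of whether
antiepileptic drugs are disproportionately reported with osteopenia
(reduced bone mineral density).

Spontaneous-report databases such as the FDA Adverse Event Reporting
System (FAERS) collect voluntary reports of suspected drug–event pairs.
They cannot estimate incidence, but they can flag *signals*: drug–event
pairs reported more often than the background of all other reports would
predict. `pvsignal` implements the standard screening stack for such data
— quarterly-file ingestion and case deduplication, drug-name
normalization, MedDRA-style PT→HLT→HLGT→SOC event mapping, four
disproportionality statistics with a Bonferroni-corrected exact test, and
sex/age subgroup re-analysis — together with a seeded synthetic FAERS
generator so every stage can be validated against known ground truth.

## The statistics

For one drug *D* and one target event set *Y*, deduplicated cases are
cross-classified into the 2×2 table

|                    | event in *Y* | other events |
|--------------------|:---:|:---:|
| *D* primary suspect | a | b |
| all other cases     | c | d |

with N = a+b+c+d and E = (a+b)(a+c)/N the count expected under
independence. The four screening methods are

- **ROR** = ad/bc with Wald 95% CI
  exp(ln ROR ± 1.96·√(1/a+1/b+1/c+1/d)); Haldane–Anscombe +0.5 on all
  cells when any cell is zero. Positive when the CI lower bound > 1.
- **PRR** = [a/(a+b)] / [c/(c+d)] with the Yates-corrected χ²;
  positive when PRR ≥ 2 and χ² ≥ 4.
- **IC** = log₂((a+½)/(E+½)), the shrinkage information component, with
  the IC025 lower credibility bound IC − 3.3(a+½)^−½ − 2(a+½)^−3/2;
  positive when IC025 > 0.
- **EBGM**: DuMouchel's multi-item gamma-Poisson shrinker. Cell counts
  O ~ Poisson(λE) with λ drawn from a two-component gamma mixture whose
  five hyperparameters are fit by maximum likelihood across the whole
  drug×PT grid; EBGM = exp E[ln λ | O] and EBGM05 is the posterior 5th
  percentile. Positive when EBGM05 > 2.

A pair is a signal when at least **any one** method is positive and
a ≥ 3 cases support it. Each pair also gets a two-sided Fisher exact
p-value, Bonferroni-adjusted over the drug hypotheses in the run. All
thresholds, the positivity rule (any/all) and the comparator universe are
configuration, not constants.

## Worked example

Simulate 20,000 reports under the default study conditions with one
injected signal — gabapentin–osteopenia at 5× the background reporting
rate — then ingest, deduplicate, normalize and screen:

```python
from pvsignal import synthetic, faers_io, pipeline
from pvsignal.pipeline import RunConfig

sim = synthetic.SyntheticConfig(
    n_reports=20_000, seed=11,
    signal_multipliers=(synthetic.Multiplier("GABAPENTIN", "OSTEOPENIA", 5.0),),
)
ds = synthetic.generate(sim)
cd, report = faers_io.ingest_tables(ds.frames["demo"], ds.frames["drug"],
                                    ds.frames["reac"], ds.frames["outc"])
print(f"cases: {cd.n_cases}  duplicates removed: {report['duplicates_removed']}")
cd = pipeline.normalize_case_drugs(cd, RunConfig().load_vocab())
overall, prior, info = pipeline.run_overall(cd, RunConfig())
cols = ["drug", "N", "ror", "ror_lo", "ror_hi", "prr", "chi2",
        "ic", "ic025", "p_adj", "positive"]
print(overall.loc[overall["N"] > 0, cols].round(2).to_string(index=False))
```

prints

```
cases: 20000  duplicates removed: 2047
         drug  N  ror  ror_lo  ror_hi  prr  chi2    ic  ic025  p_adj  positive
CARBAMAZEPINE  1 0.33    0.05    2.43 0.33  0.69 -1.16  -4.94    1.0     False
    PHENYTOIN  1 0.65    0.09    4.74 0.65  0.00 -0.43  -4.21    1.0     False
VALPROIC ACID  1 0.63    0.09    4.58 0.63  0.00 -0.46  -4.25    1.0     False
   GABAPENTIN 22 3.71    1.97    7.00 3.70 17.39  1.09   0.37    0.0      True
  LAMOTRIGINE  3 0.42    0.13    1.38 0.42  1.58 -0.98  -3.05    1.0     False
LEVETIRACETAM  6 0.60    0.25    1.44 0.60  0.92 -0.55  -1.97    1.0     False
OXCARBAZEPINE  2 1.67    0.40    6.95 1.67  0.07  0.54  -2.06    1.0     False
   TOPIRAMATE  2 0.58    0.14    2.40 0.58  0.23 -0.61  -3.21    1.0     False
   LACOSAMIDE  1 0.39    0.05    2.87 0.39  0.39 -0.97  -4.75    1.0     False
```

The injected pair is flagged (N = 22 cases, ROR 3.71 with CI lower bound
1.97 > 1, IC025 0.37 > 0, Bonferroni-adjusted Fisher p ≈ 10⁻⁵); the
eleven null drugs are not. Drugs with N = 0 (here ethosuximide,
zonisamide and eslicarbazepine, whose simulated report volumes are small)
are emitted with undefined statistics and never called positive.

The same flow is available from a shell:

```bash
pvsignal simulate --seed 11 --n 20000 --out data/
pvsignal ingest --quarters data/ --out ingested/
pvsignal analyze --config run.yaml --cases ingested/cases.csv --out out/
```

writing `descriptives.csv`, `signals_overall.csv`, `signals_subgroup.csv`,
`soc_summary.csv` and `run_report.json` (config hash, thresholds, fitted
MGPS prior).

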
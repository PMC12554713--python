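# Methods

## Scope and data model

`pvsignal` screens spontaneous adverse-event reports for
disproportionality signals. Its inputs follow the FAERS quarterly layout:
`$`-delimited ASCII tables DEMO (demographics), DRUG, REAC (reaction
preferred terms), OUTC (outcome codes), keyed by PRIMARYID (report
version) and CASEID (case). One case can appear as several report
versions; all analyses run on one version per case.

**Deduplication.** Within a CASEID the version with the latest FDA_DT
survives; ties are broken by the higher PRIMARYID (numeric comparison
when the whole column is numeric, otherwise lexicographic). A missing
FDA_DT sorts below any date, so a dated version always beats an undated
one — the ordering of reports with no date is not specified by FDA
practice, and this convention is ours. Child-table rows are joined to the
surviving version on PRIMARYID (FAERS child tables key on PRIMARYID, not
CASEID); rows referencing eliminated versions are dropped and counted.

**Age.** FAERS ages carry a unit code (DEC/YR/MON/WK/DY/HR) and are
converted to years (week = 52.1775 per year, hour = 8766 per year, i.e.
Julian-year averages). An age with a missing or unknown unit is treated
as missing rather than assumed to be years: silently mis-stratifying a
case is worse than excluding it from the age dimension. Negative ages
are flagged and treated as missing.

**Drug normalization.** Raw drug names are uppercased, trimmed, stripped
of trailing dose/form tokens (e.g. `300MG`, `CAPSULE`, `ER`) and looked
up exactly in an editable synonym dictionary covering the 12 study
antiepileptic drugs (generics, salts, common US brands). No fuzzy
matching: a misspelling maps to nothing and is counted. The bundled
dictionary is a fixture for testing, not a validated reference
vocabulary.

**Event mapping.** Reaction PTs map through a four-level PT → HLT → HLGT
→ SOC table. MedDRA itself is licensed and not shipped; a mock hierarchy
covering every PT used in tests is bundled, and the loader accepts any
user-supplied table in the same format (at most 27 SOCs, matching
MedDRA). Unmapped PTs route to an `UNMAPPED` sentinel so SOC counts
always conserve total PT occurrences.

**Target event.** The default target set is the single PT `OSTEOPENIA`.
Reports in this field sometimes blur osteopenia and osteoporosis; because
the intended granularity is genuinely ambiguous, the target set is
configuration (`target_events.yaml` also ships a broader bone-loss set),
and the default stays with the single PT.

## Signal statistics

For drug D and target set Y, each deduplicated case is classified by
"D among its primary-suspect (PS) drugs after normalization" × "any
reaction PT in Y", giving (a, b, c, d), N and E = (a+b)(a+c)/N. Only PS
drug entries count: concomitant and secondary-suspect entries do not
assign a case to a drug row.

- ROR = ad/bc, CI = exp(ln ROR ± 1.96·√(Σ 1/cell)); if any cell is 0 the
  Haldane–Anscombe +0.5 correction applies to all four cells for this
  statistic only.
- PRR = [a/(a+b)]/[c/(c+d)]; companion χ² is Yates-corrected,
  N(|ad−bc|−N/2)²/[(a+b)(c+d)(a+c)(b+d)], floored at 0 when
  |ad−bc| ≤ N/2. Zero-margin tables are undefined and excluded from
  signal calls.
- IC = log₂((a+½)/(E+½)); IC025 = IC − 3.3(a+½)^−½ − 2(a+½)^−3/2
  (Norén's credibility-interval approximation).
- p-value: two-sided Fisher exact by the method of small p-values,
  summed in log space with a 1e−8 relative log-tolerance for
  floating-point ties; robust at very small a. The χ² statistic is
  retained alongside PRR because screening tables conventionally print
  "PRR (χ²)". Bonferroni: p_adj = min(1, m·p) with m defaulting to the
  number of drug×event hypotheses in the run (12 here); m is
  configuration because reasonable family definitions differ.
- Positivity (defaults): a ≥ 3 AND any of {ROR CI lower > 1; PRR ≥ 2 ∧
  χ² ≥ 4; IC025 > 0; EBGM05 > 2}. These are the conventional published
  criteria for FAERS screening; every threshold and the any/all rule live
  in `thresholds.yaml`. Undefined methods count as negative.

**Comparator universe.** The background (cells c, d) is a first-class
parameter: `all_ingested` (every loaded case — the default) or
`study_drugs_only`. Published studies typically screen against the full
database; a desk-scale run only has whatever was ingested, so the
universe is always recorded in the outputs.

## MGPS / EBGM

Cell counts over the full drug×PT grid follow O ~ Poisson(λE) with
λ ~ w·Gamma(α₁,β₁) + (1−w)·Gamma(α₂,β₂) (shape/rate). The marginal is a
two-component negative-binomial mixture, available in closed form, so the
five hyperparameters are estimated by direct maximum likelihood rather
than EM: L-BFGS-B on (logit w, log α, log β) with analytic gradients,
bounds 1e−4…1e4 on shapes/rates, and a four-point multi-start grid from
the classic initialization (w=⅓, α₁=0.2, β₁=0.1, α₂=2, β₂=4) to guard
against the known bimodality of this likelihood. The starting point is
always retained as a candidate, so the returned log-likelihood never
falls below the initializer's; non-convergence is flagged, never silent.

E is computed from the row/column margins of the drug×PT case-count
matrix within the same universe as the 2×2 tables, so shrinkage borrows
strength across the full grid. No count squashing is applied (desk-scale
grids are small). Posterior per cell is again a gamma mixture;
EBGM = exp(Q·(ψ(α₁+O)−ln(β₁+E)) + (1−Q)·(ψ(α₂+O)−ln(β₂+E))) with Q the
posterior component weight, and EBGM05 solves mixture-CDF(x) = 0.05 by
Brent root-finding (bracket expanded from the component quantiles; the
CDF is monotone with CDF(0)=0, so the bracket is always valid) to 1e−12.

Subgroup runs refit the prior inside each stratum (stratum-internal E)
rather than Mantel–Haenszel pooling; this matches re-running the whole
analysis on the stratum subset.

**A note on EBGM under the synthetic null.** The generator draws event
PTs from one shared distribution for all drugs (unless a multiplier is
injected), so the true λ is exactly 1 for almost every cell. The ML
prior then concentrates tightly around 1 and EBGM correctly shrinks even
a genuine single-pair signal toward 1 — empirical Bayes behaving as
designed on a homogeneous background. Detection power on synthetic data
therefore comes from ROR/PRR/IC and the Fisher test; EBGM earns its keep
on real, heterogeneous backgrounds. This is a property of the simplest
sufficient generative model, not of the estimator, and it is why the
EBGM implementation is validated directly against quadrature and
analytic posteriors rather than through the generator.

## Synthetic generator

The generator emulates the structure of antiepileptic-drug reports with
every default chosen once from published descriptive marginals:

- **Drug marginals**: proportional to the 12 drugs' real report volumes
  (gabapentin ≈ 26%, levetiracetam ≈ 23%, … eslicarbazepine ≈ 0.03%).
  Probability maps summing to < 1 spill the remainder into a non-study
  background drug pool.
- **Sex** F/M/unknown = 0.50/0.33/0.17; **age** a four-bin mixture
  (<18, 18–64.9, 65–85, >85 at 15.8/62.0/20.0/2.3% of knowns, uniform
  within bin) with 38.2% missing; **outcome codes** CA 2.2%, DE 6.6%,
  DS 1.6%, HO 19.8%, LT 3.8%, OT 32.0%, RI 0.1%, remainder none.
- **Events**: each report draws 1–5 PT slots i.i.d. from a ~40-PT
  categorical (weighted toward nervous-system and general disorders,
  mirroring the SOC profile of real antiepileptic reports), then keeps
  the set. OSTEOPENIA's slot weight of 3×10⁻⁴ yields a case-level rate
  ≈ 0.09%, matching the observed 181 osteopenia cases per 206,680
  reports. A multiplier m on (drug, PT) — optionally restricted to a sex
  or age stratum — scales that PT's weight for matching reports and
  renormalizes, so `expected_table` can state the implied (a,b,c,d)
  probabilities in closed form.
- **Duplicates**: each case emits an extra earlier-dated version with
  probability 0.1 (same CASEID, lower PRIMARYID, children copied), so
  ingestion must really deduplicate. 20% of PS entries use brand/salt
  spellings so normalization is load-bearing.
- Events depend only on the PS drug; concomitant drugs are structural
  noise. Identical config + seed gives byte-identical files.

What the generator does **not** emulate: reporting-rate secular trends,
drug-name misspellings, correlated PTs within a report, within-case
drug–drug interaction effects, INDI/THER content, and any real
heterogeneity of λ across pairs (see the EBGM note). Passing tests
demonstrate correctness of the statistical machinery and calibration
under this model, not performance on real FAERS extracts.

## Study-scale choices

The replicated experiments use 20,000-report null datasets (200
replicates for the familywise-rate check; its exact binomial 95% CI must
cover values ≤ α = 0.05) and 50,000-report signal datasets (20
replicates; multiplier 3 must be detected in ≥ 90%, and a female-only
multiplier 5 must reproduce the female-positive/male-negative pattern in
≥ 80%). The acceptance script uses the same conditions with 10–50
replicates per experiment; sizes were fixed in advance as the smallest
grids at which the expected injected-pair count (≈ 34 at multiplier 3)
gives stable operating characteristics. The female-only multiplier is 5
because the female stratum halves the sample: it gives an expected
stratum count ≈ 29, comparable support to the overall-signal experiment.

## Numerical and degenerate-input conventions

- Dedup ordering and all outputs are deterministically sorted; CSV floats
  print via `%.10g`, making byte-identical reruns a testable contract.
- Empty strata or absent drugs emit rows with N = 0 and undefined (NaN)
  statistics, flagged, never silently dropped — mirroring the dashes
  printed in published subgroup tables; they are never called positive.
- ROR on an all-zero row is finite only through the +0.5 correction and
  is gated out by the minimum-case rule.
- The intermediate case CSV pipe-joins list columns; drug names
  containing `|` or `:` are rejected at write time (FAERS names do not
  contain them).
- Fisher p on a table with a zero row/column margin is defined as 1.

## Limitations

Disproportionality is hypothesis generation: it cannot quantify risk or
establish causation, and spontaneous-report data carry reporting,
selection and duplication biases that deduplication only partly removes.
Printed signal tables from full-database studies are not reproducible
from a desk-scale ingest because their background denominators (cells c
and d over the whole database) are not published; all validation here is
therefore property-based against oracles and synthetic ground truth.
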
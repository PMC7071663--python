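# prioritycompass

Gap analysis and multi-criteria prioritization of the WHO menu of
interventions for the prevention and control of non-communicable diseases
(NCDs), built for health-policy analysts who need to (a) find which of the
105 WHO-recommended actions and interventions are missing from a country's
national NCD policies and (b) rank the remainder for that country's context.

## What it computes

**Policy-gap labelling.** The WHO menu has six objectives with 105 numbered
items (88 interventions + 17 overarching/enabling actions). Each item is
compared against a curated mention index of national documents and labelled
*green* (reflected in the national NCD action plan), *blue* (mentioned only
in other national documents) or *red* (mentioned nowhere — a gap).

**Criterion weights (AHP).** Five criteria enter the ranking: people
potentially affected, cost-effectiveness, attributable burden (DALY per
100,000), preventable hospitalization, and the prevalence difference
between income levels. Experts compare criteria pairwise; each expert's
judgments form a positive reciprocal matrix A with a_ij ≈ w_i/w_j. Weights
are the normalized principal right eigenvector of A (power iteration), with
the row geometric mean as a cross-check, and experts are combined by the
element-wise geometric mean of their matrices. Judgment quality is screened
by the consistency ratio CR = CI/RI with CI = (λ_max − n)/(n − 1) and RI
from Saaty's random-index table; CR ≥ 0.1 aborts a run by default.

**Hospitalization criterion (4×4 model).** ICD-10 inpatient claims are
aggregated into the four main NCD groups (cardiovascular, cancer, diabetes,
chronic respiratory) through a packaged 33-code map. Under the "4 diseases,
4 modifiable shared risk factors" model, tobacco links to all four groups
and diet, physical inactivity and alcohol each to cardiovascular, diabetes
and cancer; a risk-factor intervention scores the summed admissions of its
linked groups, a clinical intervention its own group's total.

**Ranking (distributive mode).** Every criterion column is divided by its
column sum, composite scores are the weighted sums s_i = Σ_c w_c·n_ic
(which therefore sum to 1), and the risk-factor (objective 3) and clinical
(objective 4) interventions are ranked in separate runs. Ties break on the
largest-weight criterion, then on the item code.

Because the study's underlying national criterion values are unpublished,
the packaged inputs combine transcribed reference tables (the WHO menu, the
33-code claims table, the published weight table) with clearly marked
reconstructions (the mention fixture) and a synthetic-data generator for
everything else.

## Worked example

```python
import prioritycompass as pc

catalog = pc.who_reference_catalog()                  # 105 items
labels = pc.label_interventions(catalog, pc.iran_mention_fixture())
report = pc.gap_report(labels, catalog)
print(report.by_label)
print(report.red_count_by_ce_tier())

summary = pc.aggregate_admissions(pc.reference_claims())
print(summary.by_group, summary.grand_total)

matrix = pc.build_consistent_matrix(pc.REFERENCE_WEIGHTS)
rep = pc.consistency_ratio(matrix)
print(rep.lambda_max, rep.cr)
```

prints

```
{'blue': 44, 'red': 12, 'green': 49}
{'not_applicable': 4, 'best_buy': 1, 'no_cea': 4, 'effective_gt_100': 3}
{'cardiovascular': 205823, 'cancer': 29898, 'diabetes': 22800, 'chronic_respiratory': 95052} 353573
5.0 0.0
```

i.e. 12 of the 105 menu items are absent from the national policy corpus
(four of them overarching actions, four interventions without a CEA, three
effective interventions, one best buy); the four disease groups account for
205,823 / 29,898 / 22,800 / 95,052 admissions (353,573 in total); and the
exact-ratio matrix of the published weights (0.133, 0.293, 0.337, 0.160,
0.077) is perfectly consistent (λ_max = 5, CR = 0).

A full pipeline run on synthetic criteria:

```python
from prioritycompass import RunConfig, run_pipeline
paths = run_pipeline(RunConfig(objective=3, seed=42, out_dir="run"))
```

writes `ranking.csv` (40 rows for objective 3, composite scores summing
to 1), `gap_report.json`, `weights.json`, `consistency.json` and `run.log`,
byte-identical on re-run with the same config. The same pipeline is
available from the shell:

```
prioritycompass run --config run.yaml --seed 42
prioritycompass label --out labels.csv
prioritycompass gap-report --labels labels.csv
prioritycompass claims --out summary.json
prioritycompass simulate --seed 5 --out-dir sim/
prioritycompass weights --matrix sim/expert_01.csv ... --out weights.json
prioritycompass rank --criteria sim/criteria_obj3.csv --weights weights.json \
    --objective 3 --out ranking.csv
```

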
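# Methods

## Scope and data model

The package implements a two-part national prioritization workflow for the
WHO NCD intervention menu:

1. **Gap analysis** — a documentary comparison of the 105-item menu against
   a national policy corpus, summarized as green/blue/red labels;
2. **Multi-criteria ranking** — a weighted-sum (AHP-weighted, distributive
   mode) prioritization of the 70 quantifiable interventions, run
   separately for risk-factor interventions (objective 3, 40 items) and
   clinical interventions (objective 4, 30 items).

The menu structure is fixed: objectives 1/2/5/6 contain 4/4/5/5 general
policy options, objective 3 contains 49 items (9 overarching actions at
codes 3.1–3.3, 3.13–3.15, 3.27–3.28, 3.42 across the tobacco, alcohol,
diet and physical-activity blocks), and objective 4 contains 38 items
(8 overarching actions 4.1–4.8, then 10 cardiovascular, 7 diabetes,
7 cancer and 6 chronic-respiratory interventions). Overarching actions and
the objective-1/2/5/6 policy options are non-quantifiable and are excluded
from ranking; this exclusion list is packaged.

Item codes are stored as strings and ordered by (objective, item index) —
never parsed as decimals, so 3.4 and 3.40 remain distinct.

## Gap labelling

A mention index lists (code, document, document class) records with two
document classes: the national NCD action plan and all other national
documents. Labels are assigned by precedence: any action-plan mention ⇒
green; otherwise any mention ⇒ blue; otherwise red. The labelling is
therefore monotone: adding a mention can only move a label toward green.

The packaged Iran mention index is a **reconstruction**: the study's
per-document table is not public. It pins the published facts — the twelve
red items with their cost-effectiveness tiers (4 overarching / 4 without
CEA / 3 effective above I$100 per DALY averted / 1 best buy), 49 green
interventions, item 3.9 blue (mentioned without a financing decision) —
and fills the remaining green/blue split editorially. Tests and the gap
report assert only the pinned facts. Likewise, cost-effectiveness tiers of
non-gap items and titles of the overarching actions are editorial
reconstructions of the WHO menu and carry no analytic weight beyond the
tier encoding described below.

## Criterion weights (AHP)

Weights for the five criteria come from expert pairwise-comparison
matrices: positive, reciprocal (a_ji = 1/a_ij), unit diagonal. Defaults:

* **Weight extraction**: principal right eigenvector by power iteration
  (stop when successive iterates differ by < 1e-12 in max-norm, cap 10,000
  iterations — consistent matrices converge in one step; realistic noisy
  5×5 matrices in tens). The row geometric mean is provided as an
  alternative; the two agree to 1e-9 whenever CR = 0, and the dense
  eigendecomposition serves as an independent oracle in the test suite
  only.
* **Group aggregation**: element-wise geometric mean across experts
  (aggregation of individual judgments). The upper triangle is averaged in
  log space and the lower triangle stored as its exact float reciprocal,
  so reciprocity survives aggregation bit-for-bit. The study does not say
  whether weights were derived per expert and averaged or from one
  aggregated matrix; the aggregated-matrix route is the default here
  because it keeps the consistency screen meaningful for the group.
* **Consistency screen**: CI = (λ_max − n)/(n − 1), CR = CI/RI with
  Saaty's random indices packaged for n ≤ 10 (0, 0, 0.58, 0.90, 1.12,
  1.24, 1.32, 1.41, 1.45, 1.49) and overridable; CR is defined as 0 for
  n ≤ 2 (2×2 reciprocal matrices are always consistent) and requires a
  user-supplied RI for n > 10. CR < 0.1 is the conventional pass rule; the
  pipeline treats CR ≥ 0.1 as a hard failure unless explicitly overridden,
  since an inconsistent judgment set invalidates the weights downstream.

The packaged reference weight vector is (0.133, 0.293, 0.337, 0.160,
0.077) for (people affected, cost-effectiveness, attributable burden,
hospitalization, income-level difference). Pairwise CSV inputs accept
Saaty-style fractions ("1/3"), parsed as exact rationals; aggregated
values are never rounded back to the 1–9 scale (rounding exists only as a
generator option).

## Hospitalization criterion

Claims records are (ICD-10 code, admission count) pairs. Codes are
normalized (trim, uppercase, dot inserted before the fourth character when
absent) and mapped through a packaged 33-code table — 15 cardiovascular,
4 cancer, 6 diabetes, 8 chronic-respiratory codes, transcribed as printed
in the source table even where an assignment is clinically surprising
(J35.3 and O24.4 under diabetes). Unmapped codes accumulate in an
"unmapped" bucket rather than erroring, duplicate codes are summed
(insurer extracts overlap), and conservation (mapped + unmapped = grand
total) holds by construction in exact integer arithmetic.

The 4×4 risk-factor model links tobacco to all four disease groups and
each of unhealthy diet, physical inactivity and harmful alcohol use to
cardiovascular disease, diabetes and cancer. Criterion-4 scores are raw
admission counts (tobacco interventions score the grand mapped total;
clinical interventions their group total); normalization is deferred to
the ranking stage so these conservation checks stay exact. The packaged
reference claims reproduce the published group totals 205,823 / 29,898 /
22,800 / 95,052 (sum 353,573). The source's percentage column is not
validated: its denominator (against ">2.4 million admissions") is
unstated and inconsistent with the printed percentages.

## Ranking

Distributive-mode synthesis: each criterion column is divided by its
column sum (an all-zero column is left at zero with a warning), composite
scores are weighted sums of the resulting shares and therefore sum to 1,
and rankings are invariant to positive rescaling of any column and to row
order. Cost-effectiveness is a three-tier categorical in the source and is
encoded 3/2/1 (best buy / effective above I$100 per DALY / no CEA) before
normalization — configurable, since no numeric CE values per intervention
exist. The income-level criterion is an absolute prevalence difference
(direction of inequity not modelled). Exact score ties break on the
attributable-burden share (the largest-weight criterion), then on the item
code, making every ranking total and deterministic. A weight-sensitivity
helper re-ranks under multiplicative Uniform(1−p, 1+p) weight jitter and
reports per-item rank ranges and top-1 stability.

The published final orderings themselves are **not** reproducible: the
per-intervention criterion values behind them were never released. The
package reproduces the machinery and every published intermediate quantity
instead.

## Synthetic data

The generator emulates the statistical shape of the unpublished inputs:

* **Expert matrices**: a_ij = (w_i/w_j)·exp(ε), ε ~ Normal(0, sd) i.i.d.
  on the upper triangle, exact reciprocals below; defaults 8 experts,
  sd = 0.2 (which yields group CRs well inside the 0.1 gate and mean L∞
  weight-recovery error below 0.05), latent weights = the reference
  vector. Optional rounding to the Saaty scale.
* **Claims**: 10,000 records splitting 2.4 million admissions by a uniform
  multinomial; each record's code is one of the 33 reference codes with
  probability 0.15 (Dirichlet-perturbed shares) and a synthetic unmapped
  code otherwise. The 0.15 default is the ratio of the published mapped
  total to the stated national volume (353,573 / 2.4M ≈ 0.147). Totals
  are conserved exactly.
* **Criteria**: people affected ~ LogNormal(log 1e6, 1.0) persons,
  attributable burden ~ LogNormal(log 500, 0.7) DALY per 100,000,
  income-level difference ~ LogNormal(log 5, 0.5) percentage points —
  placeholder scales chosen to be positively skewed and order-of-magnitude
  plausible for a country of ~80 million, not calibrated to any survey.
  Cost-effectiveness comes from the catalog tier; hospitalization is
  computed through the claims machinery (never drawn independently), so
  the cross-module path is exercised end to end.

Every generator is a pure function of (config, seed); per-stage random
streams are derived from the seed via CRC32-keyed SeedSequence spawning,
so stages never share a stream and outputs are byte-reproducible.
Passing tests on synthetic data demonstrate correctness of the machinery
and parameter recovery under the assumed noise model; they say nothing
about the marginals of the real national data, which the generator does
not attempt to match.

## Numerical and design choices

* Reciprocity and positivity of pairwise matrices are validated at 1e-9
  relative tolerance; λ_max ≥ n is asserted to the same tolerance and CR
  is floored at 0 (a CR below −1e-9 is treated as an invalid matrix).
* Weights are reported normalized to sum 1; scaling a weight vector before
  building a consistent matrix changes nothing.
* Output CSV/JSON carry a provenance header (tool version, seed, config
  hash — no timestamps); floats are written with shortest round-trip repr
  and read back with round-trip parsing, so write→read is lossless and
  identical configs give byte-identical artifacts. Pipeline outputs are
  computed fully in memory and written together, so a failed stage leaves
  no partial files.
* The pipeline's default problem sizes (40- and 30-item rankings, 8
  experts, 10,000 claims records) are the study conditions themselves;
  property suites use 200 random matrices and 50-seed grids, which keep
  the full test run around ten seconds.

## Known limitations

* The green/blue split beyond the pinned facts, non-gap cost-effectiveness
  tiers and overarching-action titles are reconstructions (see above).
* The duplicated tobacco-cessation items (3.9 and 3.12) are kept as two
  codes, as printed in the source menu.
* No ICD-9 conversion, per-patient deduplication, incomplete-matrix
  imputation, fuzzy/interval AHP, ideal-mode synthesis, or outranking
  methods (ELECTRE/TOPSIS/PROMETHEE).
* The published group CR of 0.01 cannot be re-derived — the experts' raw
  matrices are unpublished; the consistency machinery is instead validated
  on constructed matrices with a dense-eigensolver oracle.
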
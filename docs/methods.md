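# Methods

## The weighted-profile model

`targetrank` scores each candidate protein additively over three
components, `S_total = ε + S_drug + E`. The components are deliberately
simple — weighted indicator sums — because the inputs are binary or
thresholded annotation evidence, not continuous measurements. The model
assumes:

* evidence arrives precomputed and trustworthy (database hits, TM counts,
  signal peptides, FPKM values and essentiality flags are produced by
  upstream tools; this package only applies decision rules to them);
* criteria contribute independently: an approved-drug hit and high liver
  expression add, never interact;
* within the DrugBank, TTD and lead-compound tiers, only the strongest
  applicable line of evidence counts (an approved-target hit subsumes
  clinical-only data; a lead compound subsumes a bare drug-binding domain),
  while the three ChEMBL literature flags stack, since they describe
  different properties (a literature hit, druggability, tractability).

With non-negative weights the score is monotone in the evidence: adding
evidence or raising expression across the threshold can never demote a
candidate. This is property-tested over randomized candidates, and tier
exclusivity is checked against an exhaustive enumeration of all valid
combinations of the ten evidence flags.

### Parameters

All parameters live in `WeightConfig` (score units unless noted):

| parameter | default | meaning |
|---|---|---|
| `w_fpkm_per_tissue` | 0.1 | added per tissue with FPKM above threshold |
| `fpkm_threshold` | 10 (FPKM) | strict threshold (`>`) on per-tissue expression |
| `w_essential` | 0.1 | added when the mouse ortholog knockout is lethal |
| `w_drugbank_approved` | 1 | approved-target hit (tier winner) |
| `w_drugbank_clinical` | 0.25 | clinical data only, no approved target |
| `w_ttd_successful` | 1 | ortholog of a successful (marketed-drug) target |
| `w_ttd_compound` | 0.25 | compound-target match only |
| `w_chembl_hit` / `w_chembl_druggable` / `w_chembl_tractable` | 0.25 / 0.75 / 0.25 | stacking literature flags |
| `w_chembl` | 1 | aggregate multiplier on the ChEMBL term |
| `w_lead_compound` | 1 | known drug or approved compound for the target |
| `w_drug_domain_no_lead` | 0.2 | drug-binding domain without a lead |
| `w_gpcr_or_kinase` | 1 | family bonus, applied at most once |
| `w_drugbank_experimental` | 0 | experimental-only DrugBank hits; kept as a knob because the evidence field exists, but unweighted by default |
| `count_weighted` | off | multiply DrugBank/TTD tier weights by hit counts instead of treating them as indicators |

The defaults are the published criterion weights and reproduce the
packaged worked example exactly; with them `S_drug ≤ 5.25` and
`S_total ≤ 6.05`.

Hit counts (`Ia`, `Ie`, `Is`, `Ic`) enter as indicators (count > 0) by
default. The published criteria list flat per-criterion weights, and flat
weights reproduce the worked-example totals; the count-weighted variant is
kept behind `count_weighted` for sensitivity analysis only.

A per-candidate normalization by the candidate-set size N is sometimes
written into profile formulations of this kind; it is not applied here —
it would scale every published worked-example score down by orders of
magnitude — and N is reported only as metadata (`EvaluationResult.n_candidates`).

### Numerical choices

* Scores are carried at full double precision; two-decimal rounding
  (round-half-even, e.g. 4.625 → 4.62) applies only when serializing,
  because the tabular output surface prints two decimals.
* The FPKM comparison is strict (`> 10`); for code-list inputs, which only
  record which tissues exceed the threshold, listed tissues are assigned a
  sentinel FPKM of 11 (any above-threshold value is score-equivalent) and
  unlisted tissues 0.
* Ranking sorts by total score descending, breaking ties by drug score
  descending and then by input order (stable). Ranks are 1..N with no
  gaps and no sharing. The tie-break is a package convention: published
  top-target tables do not print enough fields to determine their internal
  tie order, so only the totals and the top rank are claimed, not the
  order within tie groups.
* The homology E-value cutoff is inclusive (`e_value ≤ 1e-10` by default)
  and configurable; redundancy removal collapses exact string-identical
  sequences only (each group keeps its lexicographically smallest id),
  leaving sub-100%-identity clustering to dedicated tools.
* Degenerate evaluation inputs fail loudly: AUC is refused when either
  class is empty, ortholog comparison when the score maps share no ids.

## Worked-example fixture

The packaged 20-row table carries gene ids, annotations, isoform counts,
thresholded tissue sets and printed drug scores of a published top-20
target list. The per-target evidence rows behind those drug scores were
never published, so the fixture injects the printed drug scores as
`precomputed_drug_score` — the engine then computes expression and
essentiality contributions and the total. Essentiality flags are not
printed either; they are reconstructed from the score arithmetic
(`total − drug − 0.1·|tissues above threshold|` is either 0 or exactly one
essentiality weight for every row), which forces *essential* for 19 rows
and *not essential* for exactly one (MME). A fully synthetic fixture
exercises the evidence-to-drug-score path end to end instead.

## Synthetic data generator

`simulate_candidates` emulates the statistical shape of a
transcriptome-scale candidate set:

* a categorical family mixture (defaults weighted toward kinases, GPCRs
  and immune proteins, with neuropeptides rare);
* sparse independent Bernoulli drug-evidence flags (defaults 0.05–0.30),
  with hit counts drawn as 1 + Poisson(0.5) when a tier fires and the
  clinical-only/approved exclusivity enforced after the draw;
* per-tissue FPKM from a two-part model — Bernoulli(0.35) above-threshold
  indicator; above-threshold magnitudes are threshold + LogNormal(μ=3,
  σ=1), below-threshold values Uniform(0, threshold) — giving the heavy
  right tail typical of RNA-seq abundance;
* Bernoulli(0.25) essentiality.

`simulate_ortholog_scores` plants ortholog scores realizing a chosen
higher/comparable/lower split (default 57.5% / 17.5% / 25%) with
Exponential(0.5) delta magnitudes, so the cross-species comparison can be
verified against a known ground truth.

What the generator does **not** emulate: correlations between evidence
channels (real approved-drug targets are enriched for kinases/GPCRs and
for high expression), tissue-tissue expression correlation, isoform-level
structure, or orthology-mapping noise. Passing tests therefore demonstrate
that the rules, arithmetic and bookkeeping are correct and that planted
parameters are recovered — not that the scoring recovers true biological
druggability, which depends entirely on the quality of the input evidence.

All stochastic tests fix a single integer seed and state their sample
sizes. Property suites run on 1,000 randomized candidates; frequency
recovery uses n = 10,000 (flags checked to within three binomial standard
errors); the AUC oracle comparison uses 100 instances of 50 candidates;
the ortholog-split recovery uses n = 200 at tolerance 0. These sizes make
the full suite run in seconds while leaving the binomial checks tight.

## Evaluation

`compute_roc` sweeps the decision threshold over the observed scores
(scikit-learn's sweep, no intermediate-point dropping) and integrates by
the trapezoidal rule; for a step-function ROC this equals the Mann–Whitney
statistic with ties counted ½, which the tests verify against a brute-force
O(n²) pair-counting oracle. `compare_orthologs` classifies each shared
target by whether its score exceeds the ortholog's by more than a
tolerance. "Comparable" has no canonical definition, so the tolerance is
an explicit parameter (default 0.05 score units) and is always echoed in
the result.

## Limitations

* The engine cannot regenerate published drug scores from raw evidence it
  was never given; it guarantees forward consistency (criteria → drug
  score) and total/rank consistency given drug scores.
* Orthology mapping is an input: shared ids across score tables are
  assumed to pair orthologous genes.
* Candidate screening implements decision rules only (E-value cutoff, TM
  count, exact-duplicate collapse, signal-peptide cleavage, isoform
  grouping); it does not run homology searches, topology predictors or
  clustering.
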
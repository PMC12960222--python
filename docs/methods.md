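# Methods

## The multinomial second-hit model (PP4)

Each somatically evaluable carrier of a germline *DDX41* variant falls into
exactly one of four pattern categories: single recurrent hotspot hit,
single non-recurrent hit, multiple hits, or none. Under either hypothesis
("the germline variant is deleterious" / "it is not") the category counts
(n₁, n₂, n₃, n₀) over N carriers are multinomial, so the likelihood ratio
reduces to `Π_k (p_path[k]/p_null[k])^{n_k}` — the multinomial coefficient
cancels, which the test suite verifies against direct PMF evaluation. The
model treats carriers as exchangeable and their patterns as independent
given the hypothesis; it deliberately ignores *which* hotspot occurred and
the hit's allele fraction.

Defaults, all exposed on `MultinomialModel`:

| parameter | default | meaning |
|---|---|---|
| `p_path` | (0.58, 0.10, 0.007, 0.313) | category probabilities among carriers of established pathogenic alleles |
| `p_null` | (0.0023, 0.0020, 0.0014, 0.9943) | the same among cases with no germline *DDX41* variant |
| `prior` | 0.10 | prior probability of pathogenicity for the posterior transform |

The prior is a modelling choice, not a measured quantity: 0.10 is the value
under which the canonical single-hit observation (odds 252.17) yields a
posterior of 25.217/26.117 ≈ 0.966, i.e. the conventionally quoted 97%.
`estimate_model_from_cohort` is the explicit re-derivation path (pattern
frequencies among anchor-variant carriers and among non-carriers, with
optional additive smoothing, default pseudo-count 0); the model is otherwise
a fixed parameter set, not re-fit per call.

Numerical choices: the ratio is computed in log space; an empty tally
returns odds 1 (no evidence); because the null probabilities are small
empirical frequencies, the odds are capped at 10⁶ with a warning (configurable,
`cap=None` disables); a zero null probability facing a positive count raises
rather than returning infinity. Evidence bands are half-open
([2.08, 4.33) supporting, [4.33, 18.7) moderate, [18.7, 350) strong,
≥ 350 very strong) and shared with the PS4 mapping.

The `original_pp4` comparator implements the presence-based rule family
(any hotspot hit → strong, any other hit → moderate); its strengths are
configurable because the historical rule tables vary between groups, and it
exists to quantify disagreement with the odds-based banding (e.g. one
hotspot among four carriers: strong under presence, moderate under odds).

## Quasi-case-control enrichment (PS4)

2×2 tables put carrier cases against population controls. Haldane's +½
correction is applied to every cell unconditionally by default — this is
the convention that reproduces the published aggregate OR of 346 from the
cells (800, 538, 139, 32499) — with `on_zero` and `none` available. The CI
is the log-OR normal approximation with SE = √(Σ 1/cell) on the corrected
cells. Control carriers are assumed heterozygous (exposed = AC, unexposed =
AN/2 − AC), appropriate for a rare autosomal-dominant predisposition
allele; the whole control pool is used as the comparator since no
other-variant exclusion rule is defined.

Ancestry matching: screened-case denominators (overall and, when known, per
ancestry) are supplied through `AncestryPolicy` because the carrier table
alone does not contain them. When at least `dominant_fraction` (default
2/3 — an explicit, configurable choice of this package) of a variant's
carriers belong to one ancestry outside the reference set, the final
strength is the minimum of the pooled and the ancestry-matched strengths;
ancestry groups with fewer than `min_carriers` (default 3) carriers or zero
control AN are skipped with a warning. Proportion CIs use the Wilson score
method, which is stable at small counts and agrees with the Wald interval
at the reported precision for the cohort-scale prevalences. Pairwise group
comparisons use the two-sided probability-mass Fisher exact convention with
Benjamini-Hochberg step-up adjustment over all pairs.

## In-silico calibration (PP3/BP4)

Truth sets are defined by somatic co-occurrence rather than curated labels:
pathogenic = germline missense variants with at least one carrier showing a
single recurrent hotspot hit, excluding variants flagged near a splice
junction (the flag is carried on the annotation; the default notion is the
canonical ±2 intronic / terminal exonic region, recorded upstream of this
package); benign = population missense variants absent from the case
collection. AUC is the tie-corrected Mann–Whitney statistic; its variance
and the paired two-tool comparison use DeLong placement values (positives'
mean win rate over negatives and vice versa), written here because no
installed dependency exposes them and cross-checked against a bootstrap in
the tests. The Youden threshold maximises sensitivity + specificity over
the observed scores, ties resolved toward the higher (more specific)
threshold. Default cutoffs: REVEL ≥ 0.7 / ≤ 0.3, AlphaMissense ≥ 0.792 /
≤ 0.169, both applied at supporting strength only; a SpliceAI score
≥ 0.2 (a common clinical convention — the cutoff is configurable) asserts
PP3 and suppresses BP4 regardless of the missense score.

## Evidence combination

Strengths map to Bayesian points (1/2/4/8, benign negative) and tiers to
point bands (P ≥ 10, LP 6–9, VUS 0–5, LB −6…−1, B ≤ −7). This scale is
consistent with classifying a truncating variant absent from controls
(PVS1 8 + PM2 1 = 9) as LP. The classical 2015 categorical combining rules
are available behind `combiner="categorical"`; they are stricter for
single-code-plus-supporting combinations. PVS1 defaults: very strong for
nonsense/frameshift/canonical-splice, strong for start-loss (no exon-level
NMD logic — out of scope). PM2 is applied at supporting strength, met on
absence from controls or a grpmax allele frequency ≤ 2×10⁻⁵ (inclusive).
PS4 and PP4 are combined as independent codes, mirroring their parallel
roles, although both derive from case data; users who consider this
double-counting can override either code, and every override is recorded
with an audit note in the report.

## Synthetic cohorts

The generator emulates the aggregated-cohort structure: a diagnosis mix
dominated by MDS/AML (0.702/0.166/0.106/0.026 across MDS/AML, other
myeloid, cytopenia, lymphoid — proportional to the screened-case
composition), an ancestry mix of NFE 0.6 / EAS 0.3 / other 0.1, and a
six-allele catalog of pathogenic (two frameshifts, one start-loss, one
missense; one frameshift concentrated in EAS to emulate a founder allele)
and benign missense variants. Somatic patterns are drawn from the same
multinomial model the inference assumes — pathogenic carriers from
`p_path`, everyone else from `p_null` — with hotspot identities drawn at
their observed relative frequencies and VAFs from a Beta(1.5, 8) (median
≈ 13%, matching the observed low-VAF second hits). Control tables draw
AC ~ Binomial(AN, AF) per ancestry at AN = 100 000 per group by default.

The catalog frequencies set the *population* allele frequency; because the
enrichment analysis needs carriers to be over-represented among cases, each
pathogenic entry carries a `case_enrichment` odds multiplier (default 400,
placing pathogenic alleles in the strong-enrichment regime) while benign
entries use 1. Score distributions are Beta fixtures (pathogenic vs benign
shapes chosen to give one clearly stronger and one weaker tool); they are
test scaffolding for the ROC machinery, not claims about any real
predictor. Three RNG streams (cases, scores, controls) are spawned from the
master seed so components stay independent.

What passing the synthetic round trips shows — and does not: the estimator
and classifier are internally consistent with the generating process
(vectors recovered within Monte-Carlo error; generated-pathogenic alleles
with ≥ 10 carriers reach LP/P and generated-benign alleles never do, over
200 replicate cohorts of 1 500 cases). Real cohorts violate the generator's
assumptions in known ways — misassigned germline/somatic origin, varying
somatic-testing sensitivity, literature reporting bias, non-independent
carriers — so these tests validate the machinery, not the clinical
calibration of the default parameters.

## Problem sizes and determinism

Test and acceptance runs use desk-scale inputs: 200-replicate cohorts of
1 500 cases for recovery, 10 000-carrier calibration checks, exhaustive
Fisher enumeration to row margins of 15, and 2 000-resample bootstraps at
n = 300 for the DeLong cross-check. All stochastic tests run under fixed
seeds; `scripts/acceptance.py` threads its `--seed` through the generator
run it performs, while its reported checkpoints are deterministic
computations on published inputs.

## Known limitations

- Somatic "evaluability" is taken at face value from the input flag
  (defaulting to evaluable for cohort sources); no attempt is made to infer
  whether somatic testing was performed.
- Protein-change matching is exact string comparison after normalisation;
  no HGVS grammar, validation or liftover.
- The per-variant model ignores VAF magnitude, the specific hotspot
  identity and per-diagnosis pattern differences.
- The dominant-ancestry downgrade is an outcome-motivated policy with a
  configurable threshold, not an inference about population structure.
- PP3/BP4 are fixed at supporting strength; calibrated-strength schemes are
  not implemented.
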
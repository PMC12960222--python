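# ddx41kit

Evidence framework for classifying germline *DDX41* variants — the leading
cause of heritable predisposition to myelodysplastic neoplasia and acute
myeloid leukemia (MDS/AML). The package is aimed at clinical molecular
pathology laboratories and researchers curating *DDX41* variants under the
ACMG/AMP framework, where late-onset disease, incomplete penetrance, founder
alleles and the absence of functional assays make standard criteria hard to
apply.

It implements four refinements as a tested Python library with a thin CLI:

**PP4 — odds of pathogenicity from somatic second hits.** In *DDX41*-driven
myeloid malignancy the tumor typically acquires a second, somatic *DDX41*
variant (classically the missense hotspot R525H). For a germline variant
observed in *N* somatically evaluable carriers, the counts
(n₁, n₂, n₃, n₀) of carriers with a single recurrent hotspot, a single
non-recurrent hit, multiple hits, or none are modelled as multinomial draws
under two hypotheses, giving the likelihood ratio

```
OddsPath = Π_k (p_path[k] / p_null[k])^{n_k}
```

with default category vectors p_path = (0.58, 0.10, 0.007, 0.313) — the
empirical pattern among carriers of established pathogenic alleles — and
p_null = (0.0023, 0.0020, 0.0014, 0.9943), the pattern among cases without a
germline *DDX41* variant. The posterior follows Tavtigian's transform
`Post = OP·π / ((OP−1)·π + 1)` with prior π = 0.10, and odds map onto the
evidence bands supporting ≥ 2.08, moderate ≥ 4.33, strong ≥ 18.7, very
strong ≥ 350. Unlike presence-based rules, the odds *decrease* with every
quiet carrier, so a hotspot co-occurrence diluted over many carriers stops
counting as evidence.

**PS4 — ancestry-matched quasi-case-control enrichment.** Affected carriers
are compared against population allele counts (gnomAD-style per-ancestry
AC/AN tables) using the Haldane-corrected odds ratio
`OR = (a+½)(d+½) / ((b+½)(c+½))` with a log-normal CI; the CI lower bound
sets the strength on the same bands. When carriers concentrate in one
non-reference ancestry group (founder alleles), the final strength is capped
at the ancestry-matched strength.

**PP3/BP4 — calibrated in-silico evidence.** Truth sets are built from
somatic co-occurrence (pathogenic: missense variants seen with a recurrent
hotspot second hit; benign: population missense variants absent from the
case collection), scored with ROC/AUC, DeLong confidence intervals and
paired AUC comparison, and applied at supporting strength with a SpliceAI
override.

**Evidence integration.** PVS1/PM2/PS4/PP4/PP3/BP4 combine through a
Bayesian point scale (supporting 1, moderate 2, strong 4, very strong 8;
benign negative) into the five tiers P (≥ 10), LP (6–9), VUS (0–5),
LB (−6…−1), B (≤ −7), with manual overrides and full provenance reports.
A synthetic-cohort generator with the same statistical structure makes every
stage testable end to end.

## Worked example

```
$ python examples/01_somatic_pattern_odds.py
one carrier, one hotspot hit           OddsPath=     252.2  posterior= 96.6%  band=strong
one hotspot among four carriers        OddsPath=     7.866  posterior= 46.6%  band=moderate
39 carriers, 3 non-recurrent hits      OddsPath= 1.061e-13  posterior=  0.0%  band=not_met
```

A single recurrent somatic hit in an isolated carrier is, by itself, strong
evidence (odds ≈ 252, posterior ≈ 97%). The same hit among four evaluable
carriers is only moderate, and three non-recurrent hits spread over 39
carriers argue *against* pathogenicity. Full curation composes all codes:

```
$ python examples/05_full_curation.py
 variant tier  points         pp4      ps4        pvs1        pm2
c.100del    P      19 very_strong moderate very_strong supporting
     Q4H  VUS       0     not_met  not_met     not_met    not_met
   M155I  VUS       0     not_met  not_met     not_met    not_met
```

The other examples cover enrichment ORs and prevalence
(`02_case_enrichment.py`), generator round-trips (`03_synthetic_cohort.py`)
and ROC/DeLong calibration (`04_score_calibration.py`). The same
functionality is scriptable through the `ddx41kit` CLI
(`ddx41kit pp4 --n1 1 --n0 3`, `ddx41kit grid --max-n 25`,
`ddx41kit curate …`, `ddx41kit simulate …`).

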
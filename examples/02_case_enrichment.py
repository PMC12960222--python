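"""Case-enrichment evidence (PS4): Haldane odds ratios and prevalence.

The quasi-case-control design compares affected carriers against population
allele counts; the CI lower bound sets the evidence strength.
"""

from ddx41kit import (
    ContingencyTable,
    haldane_or,
    prevalence_ci,
    strength_from_lower_ci,
)

# single somatic DDX41 hit vs germline carriage among MDS/AML cases
table = ContingencyTable(a=800, b=538, c=139, d=32499)
r = haldane_or(table)
print(f"OR = {r.or_point:.0f} (95% CI {r.ci_low:.0f}-{r.ci_high:.0f})")
print(f"strength from CI lower bound: {strength_from_lower_ci(r).value}")

# prevalence of germline P/LP variants among screened MDS/AML cases
point, low, high = prevalence_ci(1083, 34051)
print(f"P/LP prevalence: {point:.1%} (95% CI {low:.1%}-{high:.1%})")

# An OR in the hundreds with a lower bound far above 18.7 is strong
# enrichment evidence; the prevalence line reproduces the ~3.2% carriage
# rate of deleterious alleles among myeloid-malignancy cases.
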
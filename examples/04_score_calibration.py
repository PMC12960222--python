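"""ROC calibration of two in-silico predictors and a paired DeLong test.

Synthetic labelled scores stand in for REVEL/AlphaMissense-style predictors;
the ROC machinery returns the AUC with a DeLong CI and the Youden-optimal
threshold, and the paired test compares the two tools on the same variants.
"""

from ddx41kit import delong_compare, roc_auc
from ddx41kit.insilico import ScoredEntry, ScoredSet
from ddx41kit.synthetic import GeneratorConfig, generate_truth_scores

scores = generate_truth_scores(GeneratorConfig(seed=11))


def scored_set(tool: str) -> ScoredSet:
    return ScoredSet(
        tuple(
            ScoredEntry(row.variant, getattr(row, tool), row.label)
            for row in scores.itertuples()
        )
    )


for tool in ("revel", "alphamissense"):
    r = roc_auc(scored_set(tool))
    print(
        f"{tool:14s} AUC={r.auc:.3f} "
        f"(95% CI {r.auc_ci[0]:.3f}-{r.auc_ci[1]:.3f})  "
        f"Youden threshold={r.youden_threshold:.3f}"
    )

z, p = delong_compare(scored_set("alphamissense"), scored_set("revel"))
print(f"paired DeLong test: z={z:.2f}, p={p:.2g}")

# A positive z with a small p says the first tool's AUC is genuinely higher
# on these paired variants, not a resampling artefact.
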
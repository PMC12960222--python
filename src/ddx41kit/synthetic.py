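"""Synthetic cohort generator emulating the structure of an aggregated
germline/somatic DDX41 case collection.

The generator draws cases with a diagnosis group and ancestry label, assigns
germline variants from a catalog of pathogenic and benign alleles with
per-ancestry allele frequencies (one entry concentrates its frequency in the
EAS group to emulate a founder allele), and realises each case's somatic
second-hit pattern from the same multinomial model the inference assumes:
carriers of a pathogenic allele draw from the pathogenic category vector,
everyone else from the null vector. A matching control allele-count table and
a truth table of generating parameters accompany the cohort, so every
downstream analysis is testable without external data.

Three independent pseudo-random streams (cases, scores, controls) are spawned
from the master seed, so adding draws to one component does not perturb the
others.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cohort import (
    CaseRecord,
    Diagnosis,
    GermlineVariant,
    PATTERN_ORDER,
    SomaticHit,
    SomaticPattern,
    Source,
    VariantType,
)
from .oddspath import MultinomialModel


class ConfigError(ValueError):
    """Degenerate generator configuration."""


@dataclass(frozen=True)
class CatalogEntry:
    """One germline variant the generator can seed into cases.

    ``key`` is the variant's aggregation key (protein change for missense/
    in-frame entries, cDNA description otherwise). ``carrier_freq`` maps
    ancestry label -> population allele frequency; the control table is drawn
    binomially from it. ``case_enrichment`` multiplies the carriage odds
    among cases relative to the population (pathogenic alleles are enriched
    in patients; benign alleles are not).
    """

    key: str
    true_class: str  # "pathogenic" | "benign"
    carrier_freq: Mapping[str, float]
    variant_type: VariantType = VariantType.MISSENSE
    hgvsc: str = ""
    protein: str = ""
    case_enrichment: float = 1.0

    def __post_init__(self) -> None:
        if self.true_class not in ("pathogenic", "benign"):
            raise ConfigError(f"unknown class {self.true_class!r}")
        for anc, f in self.carrier_freq.items():
            if not 0.0 <= f <= 1.0:
                raise ConfigError(f"frequency out of [0,1] for {anc}: {f}")
        if not self.hgvsc:
            object.__setattr__(self, "hgvsc", f"c.sim_{self.key}")
        if not self.protein:
            object.__setattr__(self, "protein", self.key)


@dataclass(frozen=True)
class ScoreModel:
    """Beta-distributed tool scores, class-separated; fixture parameters for
    exercising ROC machinery (not claims about any real predictor)."""

    revel_pathogenic: tuple[float, float] = (4.0, 2.0)
    revel_benign: tuple[float, float] = (2.0, 4.0)
    alpha_pathogenic: tuple[float, float] = (6.0, 1.5)
    alpha_benign: tuple[float, float] = (1.5, 6.0)


def _default_catalog() -> tuple[CatalogEntry, ...]:
    # small catalog: common frameshift and start-loss pathogenic alleles
    # spread over ancestries, one EAS-concentrated founder (A500fs-like),
    # plus benign missense alleles at higher population frequency.
    return (
        CatalogEntry(
            "c.415_418dup", "pathogenic",
            {"NFE": 1.5e-5, "EAS": 3e-6, "other": 5e-6},
            VariantType.FRAMESHIFT, protein="D140fs", case_enrichment=400.0,
        ),
        CatalogEntry(
            "c.3G>A", "pathogenic",
            {"NFE": 1.2e-5, "EAS": 2e-6, "other": 4e-6},
            VariantType.START_LOSS, protein="M1?", case_enrichment=400.0,
        ),
        CatalogEntry(
            "c.1498dup", "pathogenic",
            {"NFE": 1e-6, "EAS": 4e-5, "other": 1e-6},
            VariantType.FRAMESHIFT, protein="A500fs", case_enrichment=400.0,
        ),
        CatalogEntry(
            "Y340N", "pathogenic",
            {"NFE": 8e-6, "EAS": 2e-6, "other": 2e-6},
            VariantType.MISSENSE, hgvsc="c.1018T>A", case_enrichment=400.0,
        ),
        CatalogEntry(
            "M155I", "benign",
            {"NFE": 4e-4, "EAS": 2e-4, "other": 3e-4},
            VariantType.MISSENSE, hgvsc="c.465G>C", case_enrichment=1.0,
        ),
        CatalogEntry(
            "G173R", "benign",
            {"NFE": 3e-4, "EAS": 3e-4, "other": 3e-4},
            VariantType.MISSENSE, hgvsc="c.517G>A", case_enrichment=1.0,
        ),
    )


@dataclass(frozen=True)
class GeneratorConfig:
    """Generator parameters; probability vectors must sum to 1 within 1e-9.

    Defaults mirror the published cohort structure: diagnosis mix proportional
    to the screened-case composition (MDS/AML dominating), ancestry mix
    dominated by NFE and EAS, and the default pattern model.
    """

    seed: int = 0
    n_cases: int = 2000
    diagnosis_mix: Mapping[Diagnosis, float] = field(
        default_factory=lambda: {
            Diagnosis.MDS_AML: 0.702,
            Diagnosis.OTHER_MYELOID: 0.166,
            Diagnosis.CYTOPENIA: 0.106,
            Diagnosis.LYMPHOID: 0.026,
        }
    )
    ancestry_mix: Mapping[str, float] = field(
        default_factory=lambda: {"NFE": 0.60, "EAS": 0.30, "other": 0.10}
    )
    variant_catalog: tuple[CatalogEntry, ...] = field(default_factory=_default_catalog)
    pattern_model: MultinomialModel = field(default_factory=MultinomialModel)
    score_model: ScoreModel = field(default_factory=ScoreModel)
    control_an: int = 100_000  # alleles per ancestry group in the control table
    n_score_pathogenic: int = 61
    n_score_benign: int = 503

    def __post_init__(self) -> None:
        for name, mix in (("diagnosis_mix", self.diagnosis_mix),
                          ("ancestry_mix", self.ancestry_mix)):
            if abs(sum(mix.values()) - 1.0) > 1e-9:
                raise ConfigError(f"{name} must sum to 1 within 1e-9")
        if not self.variant_catalog:
            raise ConfigError("variant catalog must be non-empty")
        if self.n_cases < 1:
            raise ConfigError("n_cases must be positive")


_HOTSPOT_WEIGHTS = {
    # relative frequencies among single recurrent somatic hits
    "R525H": 0.667 / 0.834,
    "G530D": 0.064 / 0.834,
    "P321L": 0.041 / 0.834,
    "T227M": 0.026 / 0.834,
    "E345D": 0.018 / 0.834,
    "G530S": 0.014 / 0.834,
    "D344E": 0.014 / 0.834,
}

_NONRECURRENT_POOL = (
    "L87V", "Q52P", "S21F", "K494N", "R164Q", "E247K", "I396T", "G580S",
)


def _streams(seed: int) -> tuple[np.random.Generator, np.random.Generator, np.random.Generator]:
    cases_ss, scores_ss, controls_ss = np.random.SeedSequence(seed).spawn(3)
    return (
        np.random.default_rng(cases_ss),
        np.random.default_rng(scores_ss),
        np.random.default_rng(controls_ss),
    )


def _draw_pattern(rng: np.random.Generator, probs: Sequence[float]) -> SomaticPattern:
    return PATTERN_ORDER[int(rng.choice(4, p=np.asarray(probs) / np.sum(probs)))]


def _realize_hits(
    rng: np.random.Generator, pattern: SomaticPattern
) -> list[SomaticHit]:
    def _vaf() -> float:
        return float(np.clip(rng.beta(1.5, 8.0), 1e-3, 1.0))

    if pattern is SomaticPattern.NONE:
        return []
    if pattern is SomaticPattern.SINGLE_RECURRENT:
        names = list(_HOTSPOT_WEIGHTS)
        w = np.array([_HOTSPOT_WEIGHTS[n] for n in names])
        name = names[int(rng.choice(len(names), p=w / w.sum()))]
        return [SomaticHit(name, _vaf())]
    if pattern is SomaticPattern.SINGLE_NONRECURRENT:
        name = _NONRECURRENT_POOL[int(rng.integers(len(_NONRECURRENT_POOL)))]
        return [SomaticHit(name, _vaf())]
    picks = rng.choice(len(_NONRECURRENT_POOL), size=2, replace=False)
    return [SomaticHit(_NONRECURRENT_POOL[int(i)], _vaf()) for i in picks]


def generate_cohort(
    config: GeneratorConfig | None = None,
) -> tuple[list[CaseRecord], pd.DataFrame, pd.DataFrame]:
    """Generate (cases, control allele-count table, truth table).

    Reproducible for a given seed. Each case draws a diagnosis and ancestry,
    then carries each catalog variant independently with probability
    2 * AF * case_enrichment (heterozygous carriers, capped at 1; at most two
    germline variants are kept per case). Carriers of a pathogenic allele
    draw their somatic pattern from the pathogenic category vector; all other
    cases from the null vector. The control table draws AC ~ Binomial(AN, AF)
    per ancestry so AC/AN matches the configured frequencies within binomial
    error.
    """
    config = config or GeneratorConfig()
    rng_cases, _, rng_controls = _streams(config.seed)

    diags = list(config.diagnosis_mix)
    diag_p = np.array([config.diagnosis_mix[d] for d in diags], dtype=float)
    ancs = list(config.ancestry_mix)
    anc_p = np.array([config.ancestry_mix[a] for a in ancs], dtype=float)

    # catalog keys are the aggregation keys: protein change for missense/
    # in-frame entries, cDNA description otherwise (variant_key auto mode)
    variants = {}
    for e in config.variant_catalog:
        if e.variant_type in (VariantType.MISSENSE, VariantType.INFRAME):
            gv = GermlineVariant(
                hgvsc=e.hgvsc, protein_change=e.key, variant_type=e.variant_type,
                pop_af=dict(e.carrier_freq),
            )
        else:
            gv = GermlineVariant(
                hgvsc=e.key, protein_change=e.protein, variant_type=e.variant_type,
                pop_af=dict(e.carrier_freq),
            )
        variants[e.key] = gv

    cases: list[CaseRecord] = []
    for i in range(config.n_cases):
        diagnosis = diags[int(rng_cases.choice(len(diags), p=diag_p))]
        ancestry = ancs[int(rng_cases.choice(len(ancs), p=anc_p))]
        germline: list[GermlineVariant] = []
        pathogenic_carrier = False
        for entry in config.variant_catalog:
            af = entry.carrier_freq.get(ancestry, 0.0)
            p_carry = min(2.0 * af * entry.case_enrichment, 1.0)
            if rng_cases.random() < p_carry and len(germline) < 2:
                germline.append(variants[entry.key])
                if entry.true_class == "pathogenic":
                    pathogenic_carrier = True
        probs = (
            config.pattern_model.p_path if pathogenic_carrier
            else config.pattern_model.p_null
        )
        pattern = _draw_pattern(rng_cases, probs)
        cases.append(
            CaseRecord(
                case_id=f"SYN{i:06d}",
                source=Source.COHORT,
                diagnosis=diagnosis,
                ancestry=ancestry,
                germline_variants=germline,
                germline_confirmed=bool(rng_cases.random() < 0.25),
                somatic_hits=_realize_hits(rng_cases, pattern),
                somatic_evaluable=True,
            )
        )

    ctl_rows = []
    for entry in config.variant_catalog:
        for anc in ancs:
            af = entry.carrier_freq.get(anc, 0.0)
            an = config.control_an
            ac = int(rng_controls.binomial(an, af))
            ctl_rows.append({"variant": entry.key, "ancestry": anc, "ac": ac, "an": an})
    controls = pd.DataFrame(ctl_rows)

    truth = pd.DataFrame(
        [
            {
                "variant": e.key,
                "true_class": e.true_class,
                "variant_type": e.variant_type.value,
                "case_enrichment": e.case_enrichment,
                **{f"af_{a}": e.carrier_freq.get(a, 0.0) for a in ancs},
            }
            for e in config.variant_catalog
        ]
    )
    return cases, controls, truth


def generate_truth_scores(config: GeneratorConfig | None = None) -> pd.DataFrame:
    """Labelled per-tool score table for ROC calibration tests.

    Returns one row per synthetic variant with columns variant, label, revel,
    alphamissense; pathogenic-class score distributions are stochastically
    larger than benign-class ones under the default score model.
    """
    config = config or GeneratorConfig()
    _, rng_scores, _ = _streams(config.seed)
    sm = config.score_model
    rows = []
    for label, n, rev_ab, alp_ab in (
        ("pathogenic_truth", config.n_score_pathogenic, sm.revel_pathogenic, sm.alpha_pathogenic),
        ("benign_truth", config.n_score_benign, sm.revel_benign, sm.alpha_benign),
    ):
        revel = rng_scores.beta(*rev_ab, size=n)
        alpha = rng_scores.beta(*alp_ab, size=n)
        for i in range(n):
            rows.append(
                {
                    "variant": f"{label[:4].upper()}{i:04d}",
                    "label": label,
                    "revel": float(revel[i]),
                    "alphamissense": float(alpha[i]),
                }
            )
    return pd.DataFrame(rows)


def carriers_of(
    cases: Sequence[CaseRecord], key: str, key_mode: str = "auto"
) -> list[CaseRecord]:
    """Convenience filter used throughout the tests."""
    return [c for c in cases if c.carries(key, key_mode)]


def write_cohort_tsv(cases: Sequence[CaseRecord], path: str) -> None:
    """Serialise cases in the cohort-table schema (one row per germline
    variant; dual-variant cases span two rows)."""
    rows = []
    for c in cases:
        gvs = c.germline_variants or [None]
        for gv in gvs:
            rows.append(
                {
                    "case_id": c.case_id,
                    "source": c.source.value,
                    "diagnosis": c.diagnosis.value,
                    "ancestry": c.ancestry,
                    "germline_hgvsc": gv.hgvsc if gv else "",
                    "germline_protein": gv.protein_change if gv else "",
                    "variant_type": gv.variant_type.value if gv else "",
                    "germline_confirmed": str(c.germline_confirmed).lower(),
                    "somatic_protein": ";".join(h.protein_change for h in c.somatic_hits),
                    "somatic_vaf": ";".join(
                        "" if h.vaf is None else f"{h.vaf:.4f}" for h in c.somatic_hits
                    ),
                    "somatic_evaluable": str(c.somatic_evaluable).lower(),
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
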
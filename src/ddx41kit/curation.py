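"""ACMG/AMP evidence integration: PVS1/PM2 assignment, the point-based
combiner with its five-tier bands, and single/bulk variant curation with full
provenance.

Strengths map to Bayesian points (supporting 1, moderate 2, strong 4, very
strong 8; benign evidence negative), combined into tiers: pathogenic at >= 10
points, likely pathogenic 6-9, VUS 0-5, likely benign -6..-1, benign <= -7.
The classical 2015 categorical combining rules are available behind
``combiner='categorical'``.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd
import yaml

from .cohort import (
    CaseRecord,
    GermlineVariant,
    HotspotRegistry,
    PatternCounts,
    VariantType,
    tally_patterns,
    variant_key,
)
from .enrichment import AncestryPolicy, Ps4Result, variant_ps4
from .evidence import (
    Classification,
    Direction,
    EvidenceCode,
    EvidenceThresholds,
    Strength,
    Tier,
)
from .insilico import SplicePolicy, assign_pp3_bp4
from .oddspath import MultinomialModel, OddsPathResult, oddspath_result


@dataclass(frozen=True)
class Pvs1Policy:
    """Strength of predicted loss-of-function evidence per variant type."""

    nonsense: Strength = Strength.VERY_STRONG
    frameshift: Strength = Strength.VERY_STRONG
    canonical_splice: Strength = Strength.VERY_STRONG
    start_loss: Strength = Strength.STRONG


def assign_pvs1(variant: GermlineVariant, policy: Pvs1Policy | None = None) -> EvidenceCode:
    """Loss-of-function evidence: nonsense, frameshift and canonical splice
    variants at very strong by default, start-loss at strong, all other
    types not met."""
    policy = policy or Pvs1Policy()
    strength_by_type = {
        VariantType.NONSENSE: policy.nonsense,
        VariantType.FRAMESHIFT: policy.frameshift,
        VariantType.CANONICAL_SPLICE: policy.canonical_splice,
        VariantType.START_LOSS: policy.start_loss,
    }
    s = strength_by_type.get(variant.variant_type, Strength.NOT_MET)
    return EvidenceCode(
        "PVS1", Direction.PATHOGENIC, s,
        rationale=f"variant type {variant.variant_type.value}",
    )


def assign_pm2(
    variant: GermlineVariant,
    af_threshold: float = 2e-5,
    mode: str = "below",
) -> EvidenceCode:
    """Population-rarity evidence at supporting strength.

    mode='absent' requires every population allele count to be zero;
    mode='below' (default) also accepts a highest per-ancestry allele
    frequency at or below ``af_threshold``.
    """
    if mode not in ("absent", "below"):
        raise ValueError(f"unknown PM2 mode {mode!r}")
    max_af = variant.max_af()
    absent = variant.total_ac() == 0 and max_af == 0.0
    met = absent or (mode == "below" and max_af <= af_threshold)
    return EvidenceCode(
        "PM2",
        Direction.PATHOGENIC,
        Strength.SUPPORTING if met else Strength.NOT_MET,
        rationale="absent from population controls" if absent else f"grpmax AF {max_af:g}",
    )


# ---------------------------------------------------------------------------
# Combiners


_TIER_BANDS = ((10, Tier.P), (6, Tier.LP), (0, Tier.VUS), (-6, Tier.LB))


def combine_codes(codes: Sequence[EvidenceCode], combiner: str = "points") -> Classification:
    """Combine evidence codes into a five-tier classification.

    The default point combiner sums the signed points; 'categorical' applies
    the classical ACMG/AMP combining-rule table on the (possibly modified)
    strengths. At most one instance of each code letter is allowed.
    """
    names = [c.code for c in codes]
    if len(names) != len(set(names)):
        raise ValueError(f"duplicate evidence codes: {sorted(names)}")
    total = sum(c.points for c in codes)
    if combiner == "points":
        tier = Tier.B
        for floor, t in _TIER_BANDS:
            if total >= floor:
                tier = t
                break
        return Classification(tier=tier, total_points=total, codes=tuple(codes))
    if combiner == "categorical":
        return Classification(
            tier=_categorical_tier(codes), total_points=total, codes=tuple(codes)
        )
    raise ValueError(f"unknown combiner {combiner!r}")


def _categorical_tier(codes: Sequence[EvidenceCode]) -> Tier:
    """2015-style combining rules evaluated on applied strengths."""
    pvs = sum(
        1 for c in codes
        if c.direction == Direction.PATHOGENIC and c.strength == Strength.VERY_STRONG
    )
    ps = sum(
        1 for c in codes
        if c.direction == Direction.PATHOGENIC and c.strength == Strength.STRONG
    )
    pm = sum(
        1 for c in codes
        if c.direction == Direction.PATHOGENIC and c.strength == Strength.MODERATE
    )
    pp = sum(
        1 for c in codes
        if c.direction == Direction.PATHOGENIC and c.strength == Strength.SUPPORTING
    )
    bs = sum(
        1 for c in codes
        if c.direction == Direction.BENIGN
        and c.strength in (Strength.STRONG, Strength.VERY_STRONG)
    )
    bp = sum(
        1 for c in codes
        if c.direction == Direction.BENIGN
        and c.strength in (Strength.SUPPORTING, Strength.MODERATE)
    )

    pathogenic = (
        (pvs >= 1 and (ps >= 1 or pm >= 2 or (pm == 1 and pp == 1) or pp >= 2))
        or ps >= 2
        or (ps == 1 and (pm >= 3 or (pm == 2 and pp >= 2) or (pm == 1 and pp >= 4)))
    )
    likely_path = (
        (pvs >= 1 and pm == 1)
        or (ps == 1 and pm in (1, 2))
        or (ps == 1 and pp >= 2)
        or pm >= 3
        or (pm == 2 and pp >= 2)
        or (pm == 1 and pp >= 4)
    )
    benign = bs >= 2
    likely_benign = (bs == 1 and bp == 1) or bp >= 2
    has_path = pathogenic or likely_path
    has_benign = benign or likely_benign
    if has_path and has_benign:
        return Tier.VUS
    if pathogenic:
        return Tier.P
    if likely_path:
        return Tier.LP
    if benign:
        return Tier.B
    if likely_benign:
        return Tier.LB
    return Tier.VUS


# ---------------------------------------------------------------------------
# Curation driver


@dataclass
class CurationConfig:
    """Every tunable behind single and bulk curation; serialisable snapshot."""

    thresholds: EvidenceThresholds = field(default_factory=EvidenceThresholds)
    model: MultinomialModel = field(default_factory=MultinomialModel)
    registry: HotspotRegistry = field(default_factory=HotspotRegistry)
    ancestry_policy: AncestryPolicy | None = None
    tool: str = "alphamissense"
    tool_thresholds: tuple[float, float] | None = None
    splice_policy: SplicePolicy = field(default_factory=SplicePolicy)
    pvs1_policy: Pvs1Policy = field(default_factory=Pvs1Policy)
    pm2_af_threshold: float = 2e-5
    pm2_mode: str = "below"
    combiner: str = "points"
    key_mode: str = "auto"
    oddspath_cap: float | None = 1e6

    def snapshot(self) -> dict:
        def _plain(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {k: _plain(v) for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, (frozenset, set)):
                return sorted(obj)
            if isinstance(obj, Mapping):
                return {k: _plain(v) for k, v in obj.items()}
            if isinstance(obj, tuple):
                return list(obj)
            if hasattr(obj, "value"):
                return obj.value
            return obj

        return {
            f.name: _plain(getattr(self, f.name)) for f in dataclasses.fields(self)
        }

    @classmethod
    def from_yaml(cls, path: str) -> "CurationConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs: dict = {}
        if "thresholds" in raw:
            kwargs["thresholds"] = EvidenceThresholds(**raw["thresholds"])
        if "model" in raw:
            m = raw["model"]
            kwargs["model"] = MultinomialModel(
                p_path=tuple(m.get("p_path", MultinomialModel().p_path)),
                p_null=tuple(m.get("p_null", MultinomialModel().p_null)),
                prior=m.get("prior", 0.10),
            )
        if "hotspots" in raw:
            kwargs["registry"] = HotspotRegistry(frozenset(raw["hotspots"]))
        if "ancestry_policy" in raw:
            ap = dict(raw["ancestry_policy"])
            if "reference_ancestries" in ap:
                ap["reference_ancestries"] = frozenset(ap["reference_ancestries"])
            if "diagnoses" in ap:
                from .cohort import Diagnosis

                ap["diagnoses"] = frozenset(Diagnosis(d) for d in ap["diagnoses"])
            kwargs["ancestry_policy"] = AncestryPolicy(**ap)
        if "splice_policy" in raw:
            kwargs["splice_policy"] = SplicePolicy(**raw["splice_policy"])
        if "tool_thresholds" in raw:
            kwargs["tool_thresholds"] = tuple(raw["tool_thresholds"])
        for key in ("tool", "pm2_af_threshold", "pm2_mode", "combiner", "key_mode",
                    "oddspath_cap"):
            if key in raw:
                kwargs[key] = raw[key]
        return cls(**kwargs)


@dataclass
class CurationReport:
    """Full provenance for one curated variant: the applied codes, every
    intermediate statistic, the carrier cases, and the config snapshot."""

    variant_key: str
    classification: Classification
    codes: dict[str, EvidenceCode]
    pattern_counts: PatternCounts
    oddspath: OddsPathResult
    ps4: Ps4Result | None
    carrier_case_ids: list[str]
    somatic_hit_table: list[dict]
    overrides: dict[str, str]
    config_snapshot: dict

    def to_json(self, **kwargs) -> str:
        def _default(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return dataclasses.asdict(obj)
            if hasattr(obj, "value"):
                return obj.value
            if isinstance(obj, (frozenset, set)):
                return sorted(obj)
            return str(obj)

        payload = dataclasses.asdict(self)
        return json.dumps(payload, default=_default, sort_keys=True, **kwargs)


def curate_variant(
    key: str,
    cases: Sequence[CaseRecord],
    controls: pd.DataFrame | None,
    annotations: Mapping[str, GermlineVariant],
    config: CurationConfig | None = None,
    overrides: Mapping[str, Strength] | None = None,
) -> CurationReport:
    """Run the full evidence pipeline for one variant and combine the codes.

    Applies, in order: PS4 (case enrichment with ancestry matching, when a
    control table and policy are available), PP4 (somatic-pattern odds of
    pathogenicity), PP3/BP4 (in-silico), PVS1 and PM2, then the configured
    combiner. ``overrides`` replaces any code's strength with an audit note;
    the report carries every intermediate value and the config snapshot.
    """
    config = config or CurationConfig()
    if key not in annotations:
        raise LookupError(f"variant {key!r} not present in the annotation table")
    variant = annotations[key]

    counts = tally_patterns(key, cases, config.registry, config.key_mode)
    odds = oddspath_result(counts, config.model, config.thresholds, cap=config.oddspath_cap)
    pp4 = EvidenceCode(
        "PP4", Direction.PATHOGENIC, odds.band,
        rationale=f"OddsPath {odds.oddspath:.4g} over {counts.N} evaluable carriers",
    )

    ps4_result: Ps4Result | None = None
    if controls is not None and config.ancestry_policy is not None:
        ps4_result = variant_ps4(
            key, cases, controls, config.ancestry_policy, config.thresholds, config.key_mode
        )
        ps4 = EvidenceCode(
            "PS4", Direction.PATHOGENIC, ps4_result.final_strength,
            rationale=(
                f"OR {ps4_result.overall.or_point:.3g} "
                f"(95% CI {ps4_result.overall.ci_low:.3g}-{ps4_result.overall.ci_high:.3g})"
            ),
        )
    else:
        ps4 = EvidenceCode("PS4", Direction.PATHOGENIC, Strength.NOT_MET, "no control data")

    # missense-prediction tools only apply to missense/in-frame changes
    # (or any variant with a splice score under the override policy)
    if variant.variant_type in (VariantType.MISSENSE, VariantType.INFRAME) or (
        variant.spliceai is not None
    ):
        insilico_code = assign_pp3_bp4(
            variant, config.tool, config.tool_thresholds, config.splice_policy
        )
    else:
        insilico_code = EvidenceCode(
            "PP3", Direction.PATHOGENIC, Strength.NOT_MET,
            rationale=f"not applicable to {variant.variant_type.value} variants",
        )
    pvs1 = assign_pvs1(variant, config.pvs1_policy)
    pm2 = assign_pm2(variant, config.pm2_af_threshold, config.pm2_mode)

    codes: dict[str, EvidenceCode] = {c.code: c for c in (pvs1, ps4, pm2, pp4)}
    codes[insilico_code.code] = insilico_code

    audit: dict[str, str] = {}
    for name, strength in (overrides or {}).items():
        prev = codes.get(name)
        direction = Direction.BENIGN if name.startswith("B") else Direction.PATHOGENIC
        codes[name] = EvidenceCode(
            name, direction, Strength(strength),
            rationale="manual override",
        )
        audit[name] = (
            f"manually set to {Strength(strength).value}"
            + (f" (was {prev.strength.value})" if prev else "")
        )

    classification = combine_codes(list(codes.values()), config.combiner)
    carriers = [c for c in cases if c.carries(key, config.key_mode)]
    hit_table = [
        {
            "case_id": c.case_id,
            "somatic": [h.protein_change for h in c.somatic_hits],
            "vaf": [h.vaf for h in c.somatic_hits],
        }
        for c in carriers
        if c.somatic_hits
    ]
    return CurationReport(
        variant_key=key,
        classification=classification,
        codes=codes,
        pattern_counts=counts,
        oddspath=odds,
        ps4=ps4_result,
        carrier_case_ids=[c.case_id for c in carriers],
        somatic_hit_table=hit_table,
        overrides=audit,
        config_snapshot=config.snapshot(),
    )


def bulk_curate(
    keys: Sequence[str],
    cases: Sequence[CaseRecord],
    controls: pd.DataFrame | None,
    annotations: Mapping[str, GermlineVariant],
    config: CurationConfig | None = None,
) -> tuple[pd.DataFrame, dict[str, CurationReport | str]]:
    """Curate many variants under one config.

    Returns a summary table (one row per input key, in input order) and a
    bundle mapping each key to its full report, or to an error message for
    keys that failed — per-variant errors are collected, not fatal.
    """
    config = config or CurationConfig()
    rows = []
    bundle: dict[str, CurationReport | str] = {}
    for key in keys:
        try:
            report = curate_variant(key, cases, controls, annotations, config)
        except Exception as exc:  # collected per-variant
            bundle[key] = f"{type(exc).__name__}: {exc}"
            rows.append({"variant": key, "tier": "", "points": None, "error": str(exc)})
            continue
        bundle[key] = report
        rows.append(
            {
                "variant": key,
                "tier": report.classification.tier.value,
                "points": report.classification.total_points,
                "oddspath": report.oddspath.oddspath,
                "pp4": report.codes["PP4"].strength.value,
                "ps4": report.codes["PS4"].strength.value,
                "pvs1": report.codes["PVS1"].strength.value,
                "pm2": report.codes["PM2"].strength.value,
                "error": "",
            }
        )
    return pd.DataFrame(rows), bundle
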
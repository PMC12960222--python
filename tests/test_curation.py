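"""Evidence integration: PVS1/PM2, the point combiner, full curation and
bulk runs."""

import pandas as pd
import pytest

from ddx41kit.cohort import GermlineVariant, HotspotRegistry, VariantType
from ddx41kit.curation import (
    CurationConfig,
    assign_pm2,
    assign_pvs1,
    bulk_curate,
    combine_codes,
    curate_variant,
)
from ddx41kit.enrichment import AncestryPolicy
from ddx41kit.evidence import Direction, EvidenceCode, Strength, Tier
from ddx41kit.insilico import assign_pp3_bp4
from ddx41kit.oddspath import oddspath_result
from ddx41kit.cohort import tally_patterns

from conftest import make_case, missense


def code(name, strength, direction=Direction.PATHOGENIC):
    return EvidenceCode(name, direction, strength)


class TestPvs1:
    @pytest.mark.parametrize(
        "vtype,expected",
        [
            (VariantType.FRAMESHIFT, Strength.VERY_STRONG),
            (VariantType.NONSENSE, Strength.VERY_STRONG),
            (VariantType.CANONICAL_SPLICE, Strength.VERY_STRONG),
            (VariantType.START_LOSS, Strength.STRONG),
            (VariantType.MISSENSE, Strength.NOT_MET),
            (VariantType.SYNONYMOUS, Strength.NOT_MET),
        ],
    )
    def test_type_policy(self, vtype, expected):
        v = GermlineVariant("c.1del", "X1fs", vtype)
        assert assign_pvs1(v).strength is expected


class TestPm2:
    def test_absent_from_controls_supports(self):
        v = missense("A1B", pop_ac_an={"NFE": (0, 1_000_000), "EAS": (0, 40_000)})
        assert assign_pm2(v).strength is Strength.SUPPORTING

    def test_m155i_like_frequency_not_met(self):
        v = missense("M155I", pop_af={"NFE": 0.0004})
        assert assign_pm2(v).strength is Strength.NOT_MET

    def test_threshold_boundary_is_inclusive(self):
        v = missense("A1B", pop_af={"NFE": 2e-5})
        assert assign_pm2(v, af_threshold=2e-5).strength is Strength.SUPPORTING

    def test_absent_mode_rejects_nonzero_counts(self):
        v = missense("A1B", pop_ac_an={"NFE": (1, 1_000_000)})
        assert assign_pm2(v, mode="absent").strength is Strength.NOT_MET
        assert assign_pm2(v, mode="below").strength is Strength.SUPPORTING


class TestCombiner:
    def test_pvs1_plus_pm2_supporting_is_lp(self):
        c = combine_codes([code("PVS1", Strength.VERY_STRONG), code("PM2", Strength.SUPPORTING)])
        assert c.total_points == 9 and c.tier is Tier.LP

    def test_no_evidence_is_vus(self):
        assert combine_codes([]).tier is Tier.VUS

    def test_mixed_codes_sum_to_lp(self):
        c = combine_codes(
            [
                code("PS4", Strength.MODERATE),
                code("PP4", Strength.STRONG),
                code("PP3", Strength.SUPPORTING),
            ]
        )
        assert c.total_points == 7 and c.tier is Tier.LP

    def test_ten_points_reach_pathogenic(self):
        c = combine_codes([code("PVS1", Strength.VERY_STRONG), code("PS4", Strength.MODERATE)])
        assert c.total_points == 10 and c.tier is Tier.P

    def test_benign_supporting_subtracts(self):
        c = combine_codes([code("BP4", Strength.SUPPORTING, Direction.BENIGN)])
        assert c.total_points == -1 and c.tier is Tier.LB

    def test_duplicate_codes_rejected(self):
        with pytest.raises(ValueError):
            combine_codes([code("PP3", Strength.SUPPORTING), code("PP3", Strength.SUPPORTING)])

    def test_pathogenic_evidence_never_lowers_tier(self):
        tiers = [Tier.B, Tier.LB, Tier.VUS, Tier.LP, Tier.P]
        base = [code("PS4", Strength.MODERATE), code("BP4", Strength.SUPPORTING, Direction.BENIGN)]
        before = combine_codes(base).tier
        for s in (Strength.SUPPORTING, Strength.MODERATE, Strength.STRONG, Strength.VERY_STRONG):
            after = combine_codes(base + [code("PP4", s)]).tier
            assert tiers.index(after) >= tiers.index(before)

    def test_bp4_never_raises_tier(self):
        tiers = [Tier.B, Tier.LB, Tier.VUS, Tier.LP, Tier.P]
        base = [code("PVS1", Strength.VERY_STRONG), code("PM2", Strength.SUPPORTING)]
        with_bp4 = base + [code("BP4", Strength.SUPPORTING, Direction.BENIGN)]
        assert tiers.index(combine_codes(with_bp4).tier) <= tiers.index(
            combine_codes(base).tier
        )

    def test_categorical_combiner_classics(self):
        assert (
            combine_codes(
                [code("PVS1", Strength.VERY_STRONG), code("PS4", Strength.STRONG)],
                combiner="categorical",
            ).tier
            is Tier.P
        )
        assert (
            combine_codes(
                [code("PS4", Strength.STRONG), code("PM2", Strength.MODERATE)],
                combiner="categorical",
            ).tier
            is Tier.LP
        )


def _fixture_world():
    """Small consistent cohort + annotations + controls for curation tests."""
    trunc = GermlineVariant(
        "c.100del", "F34fs", VariantType.FRAMESHIFT,
        pop_ac_an={"NFE": (0, 1_000_000), "EAS": (0, 40_000)},
    )
    mid = missense(
        "Q4H", hgvsc="c.12G>T", revel=0.5, alphamissense=0.5, pop_af={"NFE": 0.001}
    )
    m155i = missense("M155I", hgvsc="c.465G>C", pop_af={"NFE": 0.0004})
    ann = {"c.100del": trunc, "Q4H": mid, "M155I": m155i}

    cases = [make_case(f"t{i}", germline=[trunc], somatic=["R525H"]) for i in range(3)]
    cases += [make_case(f"m{i}", germline=[m155i], somatic=["L87V"]) for i in range(3)]
    cases += [make_case(f"q{i}", germline=[m155i]) for i in range(36)]

    controls = pd.DataFrame(
        [
            ("c.100del", "NFE", 0, 1_000_000),
            ("c.100del", "EAS", 0, 40_000),
            ("Q4H", "NFE", 1000, 1_000_000),
            ("M155I", "NFE", 400, 1_000_000),
        ],
        columns=["variant", "ancestry", "ac", "an"],
    )
    config = CurationConfig(ancestry_policy=AncestryPolicy(total_cases=34_051))
    return ann, cases, controls, config


class TestCurateVariant:
    def test_truncating_variant_with_hotspots_reaches_pathogenic(self):
        ann, cases, controls, config = _fixture_world()
        report = curate_variant("c.100del", cases, controls, ann, config)
        assert report.classification.tier is Tier.P
        assert report.codes["PVS1"].strength is Strength.VERY_STRONG
        assert report.codes["PM2"].strength is Strength.SUPPORTING
        assert report.codes["PP4"].strength is Strength.VERY_STRONG
        assert report.oddspath.oddspath >= 350

    def test_midrange_missense_without_carriers_is_vus(self):
        ann, cases, controls, config = _fixture_world()
        report = curate_variant("Q4H", cases, controls, ann, config)
        assert report.classification.tier is Tier.VUS
        assert all(
            c.strength is Strength.NOT_MET for c in report.codes.values()
        )

    def test_m155i_like_pattern_is_vus(self):
        ann, cases, controls, config = _fixture_world()
        report = curate_variant("M155I", cases, controls, ann, config)
        assert report.pattern_counts.as_tuple() == (0, 3, 0, 36)
        assert report.codes["PP4"].strength is Strength.NOT_MET
        assert report.codes["PM2"].strength is Strength.NOT_MET
        assert report.classification.tier is Tier.VUS

    def test_equals_manual_composition(self, registry):
        """curate_variant has no hidden state: its codes equal the manual
        composition of the sub-operations."""
        ann, cases, controls, config = _fixture_world()
        report = curate_variant("M155I", cases, controls, ann, config)
        counts = tally_patterns("M155I", cases, config.registry)
        odds = oddspath_result(counts, config.model, config.thresholds)
        assert report.oddspath.oddspath == odds.oddspath
        assert report.codes["PP4"].strength is odds.band
        pp3 = assign_pp3_bp4(ann["M155I"], config.tool, splice_policy=config.splice_policy)
        assert report.codes[pp3.code].strength is pp3.strength
        assert report.codes["PM2"].strength is assign_pm2(ann["M155I"]).strength

    def test_unknown_variant_is_lookup_error(self):
        ann, cases, controls, config = _fixture_world()
        with pytest.raises(LookupError):
            curate_variant("NOPE", cases, controls, ann, config)

    def test_manual_override_with_audit_note(self):
        ann, cases, controls, config = _fixture_world()
        report = curate_variant(
            "M155I", cases, controls, ann, config,
            overrides={"PP4": Strength.STRONG},
        )
        assert report.codes["PP4"].strength is Strength.STRONG
        assert "PP4" in report.overrides and "was not_met" in report.overrides["PP4"]

    def test_report_serializes_to_json(self):
        ann, cases, controls, config = _fixture_world()
        report = curate_variant("c.100del", cases, controls, ann, config)
        payload = report.to_json()
        assert '"tier": "P"' in payload and '"config_snapshot"' in payload


class TestBulkCurate:
    def test_matches_individual_runs(self):
        ann, cases, controls, config = _fixture_world()
        keys = ["c.100del", "Q4H", "M155I"]
        table, bundle = bulk_curate(keys, cases, controls, ann, config)
        assert list(table["variant"]) == keys
        for key in keys:
            solo = curate_variant(key, cases, controls, ann, config)
            assert bundle[key].classification == solo.classification

    def test_empty_list(self):
        ann, cases, controls, config = _fixture_world()
        table, bundle = bulk_curate([], cases, controls, ann, config)
        assert len(table) == 0 and bundle == {}

    def test_errors_collected_not_fatal(self):
        ann, cases, controls, config = _fixture_world()
        table, bundle = bulk_curate(["c.100del", "NOPE"], cases, controls, ann, config)
        assert table.iloc[1]["error"] != ""
        assert isinstance(bundle["NOPE"], str)
        assert bundle["c.100del"].classification.tier is Tier.P

    def test_rerun_is_deterministic(self):
        ann, cases, controls, config = _fixture_world()
        keys = ["c.100del", "M155I"]
        t1, b1 = bulk_curate(keys, cases, controls, ann, config)
        t2, b2 = bulk_curate(keys, cases, controls, ann, config)
        assert t1.equals(t2)
        assert b1["c.100del"].to_json() == b2["c.100del"].to_json()
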
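"""Shared fixtures: small hand-built cohorts and scored sets.

Everything is generated programmatically; no data files.
"""

from __future__ import annotations

import numpy as np
import pytest

from ddx41kit.cohort import (
    CaseRecord,
    Diagnosis,
    GermlineVariant,
    HotspotRegistry,
    SomaticHit,
    Source,
    VariantType,
)
from ddx41kit.insilico import BENIGN_TRUTH, PATHOGENIC_TRUTH, ScoredEntry, ScoredSet


@pytest.fixture(scope="session")
def registry() -> HotspotRegistry:
    return HotspotRegistry()


def make_case(
    case_id: str,
    germline: list[GermlineVariant] | None = None,
    somatic: list[str] | None = None,
    diagnosis: Diagnosis = Diagnosis.MDS_AML,
    ancestry: str = "NFE",
    source: Source = Source.COHORT,
    evaluable: bool = True,
) -> CaseRecord:
    return CaseRecord(
        case_id=case_id,
        source=source,
        diagnosis=diagnosis,
        ancestry=ancestry,
        germline_variants=list(germline or []),
        somatic_hits=[SomaticHit(p) for p in (somatic or [])],
        somatic_evaluable=evaluable,
    )


def missense(protein: str, hgvsc: str | None = None, **kwargs) -> GermlineVariant:
    return GermlineVariant(
        hgvsc=hgvsc or f"c.{protein}", protein_change=protein,
        variant_type=VariantType.MISSENSE, **kwargs
    )


@pytest.fixture
def null_marginal_cases() -> list[CaseRecord]:
    """Non-carrier MDS/AML pool with the published somatic-only marginals:
    74 recurrent single hits, 65 non-recurrent singles, 47 multiples and
    32499 without a somatic variant (32685 cases)."""
    cases = []
    i = 0
    for n, hits in ((74, ["R525H"]), (65, ["L87V"]), (47, ["L87V", "Y451C"])):
        for _ in range(n):
            cases.append(make_case(f"N{i:05d}", somatic=hits))
            i += 1
    for _ in range(32499):
        cases.append(make_case(f"N{i:05d}"))
        i += 1
    return cases


def scored_set_from(pos: list[float], neg: list[float]) -> ScoredSet:
    entries = [
        ScoredEntry(f"P{i}", s, PATHOGENIC_TRUTH) for i, s in enumerate(pos)
    ] + [ScoredEntry(f"B{i}", s, BENIGN_TRUTH) for i, s in enumerate(neg)]
    return ScoredSet(tuple(entries))


def random_scored_pair(
    rng: np.random.Generator, n_pos: int, n_neg: int,
    pos_ab=(6.0, 1.5), neg_ab=(1.5, 6.0), pos2_ab=(4.0, 2.0), neg2_ab=(2.0, 4.0),
) -> tuple[ScoredSet, ScoredSet]:
    """Two tools scored on the same labelled variants (paired design)."""
    keys_p = [f"P{i}" for i in range(n_pos)]
    keys_n = [f"B{i}" for i in range(n_neg)]
    s1 = ScoredSet(
        tuple(
            [ScoredEntry(k, float(x), PATHOGENIC_TRUTH)
             for k, x in zip(keys_p, rng.beta(*pos_ab, n_pos))]
            + [ScoredEntry(k, float(x), BENIGN_TRUTH)
               for k, x in zip(keys_n, rng.beta(*neg_ab, n_neg))]
        )
    )
    s2 = ScoredSet(
        tuple(
            [ScoredEntry(k, float(x), PATHOGENIC_TRUTH)
             for k, x in zip(keys_p, rng.beta(*pos2_ab, n_pos))]
            + [ScoredEntry(k, float(x), BENIGN_TRUTH)
               for k, x in zip(keys_n, rng.beta(*neg2_ab, n_neg))]
        )
    )
    return s1, s2
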
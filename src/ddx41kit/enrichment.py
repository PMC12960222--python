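"""Case-enrichment evidence (PS4): quasi-case-control odds ratios against
population allele counts, with Haldane correction, CI-lower-bound strength
mapping and an ancestry-matching downgrade policy for founder variants.

Affected carriers are compared against population databases (gnomAD-style
per-ancestry allele counts) rather than a recruited control arm. Because
founder variants concentrate in specific ancestry groups, an odds ratio
computed against the pooled control population overestimates enrichment; the
policy therefore recomputes the OR within the dominant ancestry group and
takes the weaker of the two strengths.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests
from statsmodels.stats.proportion import proportion_confint

from .cohort import CaseRecord, Diagnosis
from .evidence import EvidenceThresholds, Strength, min_strength

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 table: a exposed cases, b unexposed cases, c exposed controls,
    d unexposed controls."""

    a: float
    b: float
    c: float
    d: float

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("cell counts must be non-negative")
        if self.a + self.b <= 0 or self.c + self.d <= 0:
            raise ValueError("both margins must be positive")


@dataclass(frozen=True)
class OrResult:
    """Odds ratio with its confidence interval and (optionally) the evidence
    strength derived from the CI lower bound."""

    or_point: float
    ci_low: float
    ci_high: float
    strength: Strength | None = None

    def __post_init__(self) -> None:
        if not self.ci_low <= self.or_point <= self.ci_high:
            raise ValueError("CI must bracket the point estimate")


def haldane_or(
    table: ContingencyTable,
    confidence: float = 0.95,
    correction: str = "always",
) -> OrResult:
    """Odds ratio with Haldane continuity correction and a log-normal CI.

    With correction='always' (default) 0.5 is added to every cell before
    OR = (a+.5)(d+.5) / ((b+.5)(c+.5)); 'on_zero' corrects only when some
    cell is zero; 'none' uses the raw cells (and fails on a zero in b or c).
    The CI is exp(log OR +/- z * SE) with SE = sqrt(sum of reciprocal
    corrected cells).
    """
    if correction not in ("always", "on_zero", "none"):
        raise ValueError(f"unknown correction mode {correction!r}")
    cells = (table.a, table.b, table.c, table.d)
    add = 0.5
    if correction == "none" or (correction == "on_zero" and all(x > 0 for x in cells)):
        add = 0.0
    a, b, c, d = (x + add for x in cells)
    if b == 0 or c == 0:
        raise ZeroDivisionError("odds ratio undefined: zero cell without correction")
    if a == 0 or d == 0:
        # raw table with a zero numerator cell: OR = 0, CI degenerate
        return OrResult(0.0, 0.0, 0.0)
    or_point = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    z = stats.norm.ppf(0.5 + confidence / 2)
    log_or = math.log(or_point)
    return OrResult(
        or_point=or_point,
        ci_low=math.exp(log_or - z * se),
        ci_high=math.exp(log_or + z * se),
    )


def strength_from_lower_ci(
    result: OrResult, thresholds: EvidenceThresholds | None = None
) -> Strength:
    """PS4 strength from the lower bound of the OR confidence interval:
    the half-open bands of the Tavtigian odds scale applied to ci_low."""
    return (thresholds or EvidenceThresholds()).band(result.ci_low)


def prevalence_ci(
    k: int, n: int, confidence: float = 0.95, method: str = "wilson"
) -> tuple[float, float, float]:
    """Point prevalence k/n with a Wilson score interval (default)."""
    if n <= 0:
        raise ValueError("n must be positive")
    if not 0 <= k <= n:
        raise ValueError("k must lie in [0, n]")
    low, high = proportion_confint(k, n, alpha=1 - confidence, method=method)
    return (k / n, float(low), float(high))


def pairwise_fisher_bh(group_counts: Sequence[tuple[int, int]]) -> np.ndarray:
    """Pairwise two-sided Fisher exact tests between (k, n) groups with
    Benjamini-Hochberg adjustment over all pairs.

    The two-sided p follows the probability-mass convention: the sum of
    hypergeometric outcomes no more probable than the observed table.
    Returns a symmetric matrix with unit diagonal.
    """
    g = len(group_counts)
    if g < 2:
        raise ValueError("need at least two groups")
    pairs = list(itertools.combinations(range(g), 2))
    raw = []
    for i, j in pairs:
        ki, ni = group_counts[i]
        kj, nj = group_counts[j]
        _, p = stats.fisher_exact([[ki, ni - ki], [kj, nj - kj]], alternative="two-sided")
        raw.append(min(1.0, float(p)))
    adj = multipletests(raw, method="fdr_bh")[1] if pairs else []
    out = np.ones((g, g))
    for (i, j), p in zip(pairs, adj):
        out[i, j] = out[j, i] = p
    return out


# ---------------------------------------------------------------------------
# Ancestry-matched PS4


@dataclass(frozen=True)
class AncestryPolicy:
    """Denominators and matching rules for the quasi-case-control analysis.

    total_cases: number of screened cases overall (e.g. all MDS/AML patients
    across the aggregated cohorts), from which unexposed cases are derived;
    case_totals optionally gives per-ancestry screened totals (falls back to
    the overall total when a group's is unknown). The downgrade applies when
    at least ``dominant_fraction`` of carriers belong to one ancestry outside
    ``reference_ancestries``.
    """

    total_cases: int
    case_totals: Mapping[str, int] = field(default_factory=dict)
    min_carriers: int = 3
    dominant_fraction: float = 2 / 3
    reference_ancestries: frozenset[str] = frozenset({"NFE"})
    confidence: float = 0.95
    correction: str = "always"
    diagnoses: frozenset[Diagnosis] = frozenset({Diagnosis.MDS_AML})


@dataclass(frozen=True)
class Ps4Result:
    variant_key: str
    overall: OrResult
    by_ancestry: Mapping[str, OrResult]
    final_strength: Strength
    dominant_ancestry: str | None
    dominant_share: float
    n_carriers: int


def _control_cells(ac: float, an: float) -> tuple[float, float]:
    # all-heterozygote assumption: exposed controls = allele count,
    # unexposed = individuals without the allele = AN/2 - AC
    return ac, max(an / 2.0 - ac, 0.0)


def variant_ps4(
    key: str,
    cases: Iterable[CaseRecord],
    controls: pd.DataFrame,
    policy: AncestryPolicy,
    thresholds: EvidenceThresholds | None = None,
    key_mode: str = "auto",
) -> Ps4Result:
    """Case-enrichment evidence for one variant with ancestry matching.

    ``controls`` holds columns variant, ancestry, ac, an. The overall table
    compares all carriers (within the policy's diagnosis groups) against the
    pooled control population; for each ancestry with at least
    ``policy.min_carriers`` carriers and non-zero control AN a matched table
    is added. When one non-reference ancestry holds at least
    ``policy.dominant_fraction`` of carriers, the final strength is the
    weaker of the overall and matched strengths; otherwise it is the overall
    strength. Excluded-diagnosis cases never enter the tables.
    """
    thresholds = thresholds or EvidenceThresholds()
    carriers = [
        c
        for c in cases
        if c.diagnosis in policy.diagnoses
        and c.diagnosis != Diagnosis.EXCLUDED
        and c.carries(key, key_mode)
    ]
    n_car = len(carriers)
    ctl = controls[controls["variant"] == key] if "variant" in controls.columns else controls

    ac_total = float(ctl["ac"].sum())
    an_total = float(ctl["an"].sum())
    if an_total <= 0:
        raise ValueError(f"no control allele numbers available for {key!r}")
    c_cell, d_cell = _control_cells(ac_total, an_total)
    overall_tab = ContingencyTable(n_car, max(policy.total_cases - n_car, 0), c_cell, d_cell)
    overall = haldane_or(overall_tab, policy.confidence, policy.correction)
    overall = OrResult(
        overall.or_point, overall.ci_low, overall.ci_high,
        strength_from_lower_ci(overall, thresholds),
    )

    anc_counts: dict[str, int] = {}
    for c in carriers:
        anc_counts[c.ancestry] = anc_counts.get(c.ancestry, 0) + 1

    by_anc: dict[str, OrResult] = {}
    for anc, k_anc in anc_counts.items():
        if k_anc < policy.min_carriers:
            continue
        sub = ctl[ctl["ancestry"] == anc]
        ac = float(sub["ac"].sum())
        an = float(sub["an"].sum())
        if an <= 0:
            logger.warning("ancestry %s has zero control AN for %s; skipped", anc, key)
            continue
        total_anc = policy.case_totals.get(anc, policy.total_cases)
        cc, dd = _control_cells(ac, an)
        r = haldane_or(
            ContingencyTable(k_anc, max(total_anc - k_anc, 0), cc, dd),
            policy.confidence,
            policy.correction,
        )
        by_anc[anc] = OrResult(
            r.or_point, r.ci_low, r.ci_high, strength_from_lower_ci(r, thresholds)
        )

    final = overall.strength
    dominant, share = None, 0.0
    if n_car > 0:
        dominant = max(anc_counts, key=lambda a: (anc_counts[a], a))
        share = anc_counts[dominant] / n_car
        if (
            share >= policy.dominant_fraction
            and dominant not in policy.reference_ancestries
            and dominant in by_anc
        ):
            final = min_strength(overall.strength, by_anc[dominant].strength)
    return Ps4Result(
        variant_key=key,
        overall=overall,
        by_ancestry=by_anc,
        final_strength=final,
        dominant_ancestry=dominant,
        dominant_share=share,
        n_carriers=n_car,
    )
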
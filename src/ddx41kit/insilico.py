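"""In-silico prediction evidence (PP3/BP4): truth-set construction from
somatic second-hit co-occurrence, ROC/AUC with DeLong confidence intervals,
Youden threshold selection, paired-AUC comparison, and threshold-based
evidence assignment with a splice-impact override.

The pathogenic truth set contains germline missense variants seen with a
single recurrent somatic hotspot in at least one carrier (a pattern almost
exclusive to deleterious alleles), excluding variants near splice junctions
whose effect may be splicing rather than the substitution. The benign truth
set is drawn from population-database missense variants never observed in
the aggregated cohort.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
from scipy import stats
from sklearn.metrics import roc_auc_score

from .cohort import (
    CaseRecord,
    GermlineVariant,
    HotspotRegistry,
    SomaticPattern,
    VariantType,
    classify_somatic_pattern,
    variant_key,
)
from .evidence import Direction, EvidenceCode, Strength

logger = logging.getLogger(__name__)

PATHOGENIC_TRUTH = "pathogenic_truth"
BENIGN_TRUTH = "benign_truth"


class ScoredEntry(NamedTuple):
    variant_key: str
    score: float
    label: str  # PATHOGENIC_TRUTH | BENIGN_TRUTH


@dataclass(frozen=True)
class ScoredSet:
    """Labelled scores for one tool, ready for ROC analysis."""

    entries: tuple[ScoredEntry, ...]

    def __post_init__(self) -> None:
        for e in self.entries:
            if not 0.0 <= e.score <= 1.0:
                raise ValueError(f"score out of [0,1]: {e}")
            if e.label not in (PATHOGENIC_TRUTH, BENIGN_TRUTH):
                raise ValueError(f"unknown label {e.label!r}")

    @property
    def scores(self) -> np.ndarray:
        return np.array([e.score for e in self.entries], dtype=float)

    @property
    def labels(self) -> np.ndarray:
        return np.array([e.label == PATHOGENIC_TRUTH for e in self.entries], dtype=int)

    def positives(self) -> np.ndarray:
        return self.scores[self.labels == 1]

    def negatives(self) -> np.ndarray:
        return self.scores[self.labels == 0]


class RocPoint(NamedTuple):
    threshold: float
    sensitivity: float
    specificity: float


@dataclass(frozen=True)
class RocResult:
    auc: float
    auc_ci: tuple[float, float]
    points: tuple[RocPoint, ...]
    youden_threshold: float
    auc_var: float


@dataclass(frozen=True)
class TruthSets:
    """Per-tool scored sets plus the number of variants dropped for lacking
    each tool's score."""

    sets: Mapping[str, ScoredSet]
    dropped: Mapping[str, int]


def build_truth_sets(
    cases: Iterable[CaseRecord],
    registry: HotspotRegistry,
    population_variants: Sequence[GermlineVariant],
    asc_variant_keys: Iterable[str] | None = None,
    tools: Sequence[str] = ("revel", "alphamissense"),
    key_mode: str = "auto",
) -> TruthSets:
    """Construct pathogenic/benign truth sets for each prediction tool.

    Pathogenic: germline missense variants with at least one evaluable
    carrier whose somatic pattern is a single recurrent hotspot, excluding
    variants flagged near a splice junction. Benign: population missense
    variants whose key is absent from the aggregated cohort's variant set.
    Variants lacking a tool's score are dropped with a logged count.
    """
    cases = list(cases)
    asc_keys = set(asc_variant_keys) if asc_variant_keys is not None else {
        variant_key(gv, key_mode) for c in cases for gv in c.germline_variants
    }

    path_variants: dict[str, GermlineVariant] = {}
    for c in cases:
        if not c.somatic_evaluable:
            continue
        if classify_somatic_pattern(c, registry) is not SomaticPattern.SINGLE_RECURRENT:
            continue
        for gv in c.germline_variants:
            if gv.variant_type is not VariantType.MISSENSE or gv.near_splice_junction:
                continue
            path_variants.setdefault(variant_key(gv, key_mode), gv)

    benign_variants: dict[str, GermlineVariant] = {}
    for gv in population_variants:
        if gv.variant_type is not VariantType.MISSENSE:
            continue
        k = variant_key(gv, key_mode)
        if k in asc_keys:
            continue
        benign_variants.setdefault(k, gv)

    sets: dict[str, ScoredSet] = {}
    dropped: dict[str, int] = {}
    for tool in tools:
        entries: list[ScoredEntry] = []
        n_drop = 0
        for label, pool in (
            (PATHOGENIC_TRUTH, path_variants),
            (BENIGN_TRUTH, benign_variants),
        ):
            for k, gv in pool.items():
                s = gv.score(tool)
                if s is None:
                    n_drop += 1
                else:
                    entries.append(ScoredEntry(k, s, label))
        labels = {e.label for e in entries}
        if PATHOGENIC_TRUTH not in labels or BENIGN_TRUTH not in labels:
            raise ValueError(f"truth set for {tool!r} is missing a class")
        if n_drop:
            logger.info("truth set for %s: dropped %d unscored variants", tool, n_drop)
        sets[tool] = ScoredSet(tuple(entries))
        dropped[tool] = n_drop
    return TruthSets(sets=sets, dropped=dropped)


# ---------------------------------------------------------------------------
# ROC / AUC / DeLong


def _placements(pos: np.ndarray, neg: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Mid-rank placement values: for each positive, the fraction of
    negatives it beats (ties count half), and symmetrically for negatives."""
    cmp = (pos[:, None] > neg[None, :]).astype(float)
    cmp += 0.5 * (pos[:, None] == neg[None, :])
    return cmp.mean(axis=1), 1.0 - cmp.mean(axis=0)


def auc_variance(s: ScoredSet) -> float:
    """DeLong variance of the empirical AUC from placement components."""
    pos, neg = s.positives(), s.negatives()
    v10, v01 = _placements(pos, neg)
    var10 = v10.var(ddof=1) if len(v10) > 1 else 0.0
    var01 = v01.var(ddof=1) if len(v01) > 1 else 0.0
    return var10 / len(v10) + var01 / len(v01)


def roc_auc(s: ScoredSet, confidence: float = 0.95) -> RocResult:
    """Empirical ROC with tie-corrected (Mann-Whitney) AUC, DeLong CI and the
    Youden-index threshold.

    Thresholds are the observed score values (score >= threshold calls
    pathogenic); ties in the Youden index resolve toward the higher
    threshold.
    """
    y = s.labels
    if y.sum() == 0 or y.sum() == len(y):
        raise ValueError("ROC needs at least one entry of each class")
    scores = s.scores
    auc = float(roc_auc_score(y, scores))
    var = auc_variance(s)
    z = stats.norm.ppf(0.5 + confidence / 2)
    half = z * np.sqrt(var)
    ci = (max(0.0, auc - half), min(1.0, auc + half))

    pos, neg = s.positives(), s.negatives()
    thresholds = np.unique(scores)[::-1]  # descending: higher threshold first
    points = []
    best_thr, best_j = float(thresholds[0]), -np.inf
    for thr in thresholds:
        sens = float((pos >= thr).mean())
        spec = float((neg < thr).mean())
        points.append(RocPoint(float(thr), sens, spec))
        j = sens + spec - 1.0
        if j > best_j + 1e-12:  # strict improvement; ties keep higher threshold
            best_j, best_thr = j, float(thr)
    return RocResult(
        auc=auc, auc_ci=ci, points=tuple(points), youden_threshold=best_thr, auc_var=var
    )


def delong_compare(s1: ScoredSet, s2: ScoredSet) -> tuple[float, float]:
    """Paired comparison of two empirical AUCs on the same variants.

    Uses the placement-value (structural component) covariance of the two
    AUCs; returns the z statistic (positive when the first set's AUC is
    larger) and the two-sided p-value. Identical inputs give z = 0, p = 1.
    """
    k1 = [(e.variant_key, e.label) for e in s1.entries]
    k2 = [(e.variant_key, e.label) for e in s2.entries]
    if sorted(k1) != sorted(k2):
        raise ValueError("paired comparison requires the same labelled variants")
    # align s2 to s1's entry order
    idx = {key: i for i, key in enumerate(k2)}
    order = [idx[key] for key in k1]
    e2 = tuple(s2.entries[i] for i in order)
    s2 = ScoredSet(e2)

    mask = s1.labels == 1
    pos1, neg1 = s1.scores[mask], s1.scores[~mask]
    pos2, neg2 = s2.scores[mask], s2.scores[~mask]
    v10_1, v01_1 = _placements(pos1, neg1)
    v10_2, v01_2 = _placements(pos2, neg2)
    m, n = len(pos1), len(neg1)
    auc1, auc2 = v10_1.mean(), v10_2.mean()

    def _cov(x, y):
        return float(np.cov(x, y, ddof=1)[0, 1]) if len(x) > 1 else 0.0

    var = (
        _cov(v10_1, v10_1) / m + _cov(v01_1, v01_1) / n
        + _cov(v10_2, v10_2) / m + _cov(v01_2, v01_2) / n
        - 2 * (_cov(v10_1, v10_2) / m + _cov(v01_1, v01_2) / n)
    )
    diff = auc1 - auc2
    if var <= 1e-16:
        return (0.0, 1.0) if abs(diff) < 1e-12 else (math_inf_sign(diff), 0.0)
    z = float(diff / np.sqrt(var))
    p = float(2 * stats.norm.sf(abs(z)))
    return z, p


def math_inf_sign(x: float) -> float:
    return float("inf") if x > 0 else float("-inf")


# ---------------------------------------------------------------------------
# Evidence assignment


#: Published supporting-evidence cutoffs: call pathogenic-supporting at or
#: above the first value, benign-supporting at or below the second.
DEFAULT_TOOL_THRESHOLDS: dict[str, tuple[float, float]] = {
    "revel": (0.7, 0.3),
    "alphamissense": (0.792, 0.169),
}


@dataclass(frozen=True)
class SplicePolicy:
    """Splice-impact override: a SpliceAI delta score at or above the cutoff
    asserts PP3 regardless of the missense score and suppresses BP4."""

    enabled: bool = True
    spliceai_threshold: float = 0.2


def assign_pp3_bp4(
    variant: GermlineVariant,
    tool: str = "alphamissense",
    thresholds: tuple[float, float] | None = None,
    splice_policy: SplicePolicy | None = None,
) -> EvidenceCode:
    """Computational-prediction evidence at supporting strength.

    Score >= upper cutoff -> PP3; score <= lower cutoff -> BP4; in between ->
    not met. With the splice policy enabled, a SpliceAI score at or above its
    cutoff yields PP3 and suppresses BP4 irrespective of the missense score.
    Without any usable score the result is not_met with a warning.
    """
    upper, lower = thresholds or DEFAULT_TOOL_THRESHOLDS[tool]
    splice_policy = splice_policy or SplicePolicy()

    if (
        splice_policy.enabled
        and variant.spliceai is not None
        and variant.spliceai >= splice_policy.spliceai_threshold
    ):
        return EvidenceCode(
            "PP3",
            Direction.PATHOGENIC,
            Strength.SUPPORTING,
            rationale=f"SpliceAI {variant.spliceai:.3f} >= {splice_policy.spliceai_threshold}",
        )
    score = variant.score(tool)
    if score is None:
        warnings.warn(
            f"no usable {tool} or splice score for {variant.protein_change}", stacklevel=2
        )
        return EvidenceCode("PP3", Direction.PATHOGENIC, Strength.NOT_MET, "no usable score")
    if score >= upper:
        return EvidenceCode(
            "PP3", Direction.PATHOGENIC, Strength.SUPPORTING,
            rationale=f"{tool} {score:.3f} >= {upper}",
        )
    if score <= lower:
        return EvidenceCode(
            "BP4", Direction.BENIGN, Strength.SUPPORTING,
            rationale=f"{tool} {score:.3f} <= {lower}",
        )
    return EvidenceCode(
        "PP3", Direction.PATHOGENIC, Strength.NOT_MET,
        rationale=f"{tool} {score:.3f} between cutoffs",
    )
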
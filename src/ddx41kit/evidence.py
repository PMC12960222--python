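"""Evidence strengths, strength thresholds and ACMG/AMP code/classification types.

The same four-band odds scale (supporting >= 2.08, moderate >= 4.33,
strong >= 18.7, very strong >= 350) is used in two places: banding an
odds-of-pathogenicity likelihood ratio (PP4) and banding the lower bound of a
case-enrichment odds-ratio confidence interval (PS4).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum


class Strength(str, Enum):
    """Evidence strength on the Tavtigian odds scale."""

    VERY_STRONG = "very_strong"
    STRONG = "strong"
    MODERATE = "moderate"
    SUPPORTING = "supporting"
    NOT_MET = "not_met"


_STRENGTH_ORDER = (
    Strength.NOT_MET,
    Strength.SUPPORTING,
    Strength.MODERATE,
    Strength.STRONG,
    Strength.VERY_STRONG,
)


def strength_rank(s: Strength) -> int:
    """0 for not_met up to 4 for very_strong."""
    return _STRENGTH_ORDER.index(Strength(s))


def min_strength(a: Strength, b: Strength) -> Strength:
    """The weaker of two strengths (used by ancestry downgrades)."""
    return a if strength_rank(a) <= strength_rank(b) else b


@dataclass(frozen=True)
class EvidenceThresholds:
    """Odds thresholds delimiting half-open evidence bands.

    A value v maps to: not_met for v < supporting, supporting on
    [supporting, moderate), moderate on [moderate, strong), strong on
    [strong, very_strong) and very_strong for v >= very_strong.
    """

    supporting: float = 2.08
    moderate: float = 4.33
    strong: float = 18.7
    very_strong: float = 350.0

    def __post_init__(self) -> None:
        seq = (self.supporting, self.moderate, self.strong, self.very_strong)
        if not all(x < y for x, y in zip(seq, seq[1:])):
            raise ValueError(f"thresholds must be strictly increasing, got {seq}")

    def band(self, value: float) -> Strength:
        if value >= self.very_strong:
            return Strength.VERY_STRONG
        if value >= self.strong:
            return Strength.STRONG
        if value >= self.moderate:
            return Strength.MODERATE
        if value >= self.supporting:
            return Strength.SUPPORTING
        return Strength.NOT_MET


class Direction(str, Enum):
    PATHOGENIC = "pathogenic"
    BENIGN = "benign"


#: Bayesian point scale: pathogenic supporting/moderate/strong/very strong
#: score +1/+2/+4/+8; benign evidence mirrors with negative sign.
_POINTS = {
    Strength.VERY_STRONG: 8,
    Strength.STRONG: 4,
    Strength.MODERATE: 2,
    Strength.SUPPORTING: 1,
    Strength.NOT_MET: 0,
}


@dataclass(frozen=True)
class EvidenceCode:
    """One applied ACMG/AMP evidence item (e.g. PS4 at moderate strength)."""

    code: str  # PVS1 | PS4 | PM2 | PP3 | PP4 | BP4
    direction: Direction
    strength: Strength
    rationale: str = ""

    @property
    def points(self) -> int:
        pts = _POINTS[Strength(self.strength)]
        return -pts if self.direction == Direction.BENIGN else pts


class Tier(str, Enum):
    P = "P"
    LP = "LP"
    VUS = "VUS"
    LB = "LB"
    B = "B"


@dataclass(frozen=True)
class Classification:
    """Five-tier call with the total points and the codes behind it."""

    tier: Tier
    total_points: int
    codes: tuple[EvidenceCode, ...] = field(default_factory=tuple)
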
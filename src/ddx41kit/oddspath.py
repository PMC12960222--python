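"""Odds of pathogenicity (PP4) from somatic second-hit patterns.

For a germline variant observed in N somatically evaluable carriers, the
pattern counts (n1 single recurrent hotspot, n2 single non-recurrent, n3
multiple, n0 none) are modelled as a multinomial draw under two hypotheses:
the variant is a deleterious germline allele (category probabilities p_path,
estimated from carriers of established pathogenic variants) or it is not
(p_null, estimated from cases without any germline DDX41 variant). The
likelihood ratio

    OddsPath = prod_k (p_path[k] / p_null[k]) ** n_k

(the multinomial coefficient cancels) is the odds of pathogenicity, mapped to
evidence bands on the Tavtigian scale and converted to a posterior with
Post = OddsPath * prior / ((OddsPath - 1) * prior + 1).
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .cohort import (
    CaseRecord,
    HotspotRegistry,
    PatternCounts,
    classify_somatic_pattern,
)
from .evidence import EvidenceThresholds, Strength

#: Default category probabilities under a deleterious germline variant:
#: single recurrent 58%, single non-recurrent 10%, multiple 0.7%, none the
#: complement — the empirical pattern among carriers of the three most common
#: pathogenic variants (start-loss c.3G>A, D140fs, A500fs).
DEFAULT_P_PATH = (0.58, 0.10, 0.007, 0.313)

#: Default category probabilities among MDS/AML cases without a germline
#: DDX41 variant: 0.23% recurrent single hit, 0.20% non-recurrent single,
#: 0.14% multiple, complement none.
DEFAULT_P_NULL = (0.0023, 0.0020, 0.0014, 0.9943)


class InfiniteEvidenceError(ValueError):
    """A null-category probability is zero for an observed category."""


@dataclass(frozen=True)
class MultinomialModel:
    """Category probability vectors under the two hypotheses plus the prior
    probability of pathogenicity used for posterior conversion."""

    p_path: tuple[float, float, float, float] = DEFAULT_P_PATH
    p_null: tuple[float, float, float, float] = DEFAULT_P_NULL
    prior: float = 0.10

    def __post_init__(self) -> None:
        for name, vec in (("p_path", self.p_path), ("p_null", self.p_null)):
            if len(vec) != 4:
                raise ValueError(f"{name} must have 4 categories")
            if abs(sum(vec) - 1.0) > 1e-9:
                raise ValueError(f"{name} must sum to 1 within 1e-9, got {sum(vec)!r}")
            if any(not 0.0 <= p <= 1.0 for p in vec):
                raise ValueError(f"{name} entries must lie in [0,1]")
        if not 0.0 < self.prior < 1.0:
            raise ValueError(f"prior must lie in (0,1), got {self.prior}")


@dataclass(frozen=True)
class OddsPathResult:
    oddspath: float
    posterior: float
    band: Strength


def likelihood_ratio(
    counts: PatternCounts,
    model: MultinomialModel | None = None,
    cap: float | None = 1e6,
) -> float:
    """Multinomial likelihood ratio of the observed pattern counts.

    Computed in log space; returns 1 for an empty tally (N = 0). Because the
    null-category probabilities are small empirical frequencies, the ratio is
    capped at ``cap`` (default 1e6) with a warning; pass ``cap=None`` for the
    uncapped value. A zero null probability paired with a positive count
    raises :class:`InfiniteEvidenceError`.
    """
    model = model or MultinomialModel()
    n = counts.as_tuple()
    if counts.N == 0:
        return 1.0
    log_lr = 0.0
    for k, nk in enumerate(n):
        if nk == 0:
            continue
        if model.p_null[k] == 0.0:
            raise InfiniteEvidenceError(
                f"null probability for category {k} is 0 with count {nk}"
            )
        if model.p_path[k] == 0.0:
            return 0.0
        log_lr += nk * (math.log(model.p_path[k]) - math.log(model.p_null[k]))
    lr = math.exp(log_lr)
    if cap is not None and lr > cap:
        warnings.warn(
            f"odds of pathogenicity {lr:.3g} capped at {cap:g}", stacklevel=2
        )
        return cap
    return lr


def posterior_from_oddspath(oddspath: float, prior: float = 0.10) -> float:
    """Posterior probability of pathogenicity given a likelihood ratio and a
    prior; equals the prior when the ratio is 1."""
    if oddspath <= 0:
        raise ValueError("oddspath must be positive")
    if not 0.0 < prior < 1.0:
        raise ValueError("prior must lie in (0,1)")
    return (oddspath * prior) / ((oddspath - 1.0) * prior + 1.0)


def oddspath_from_posterior(posterior: float, prior: float = 0.10) -> float:
    """Inverse of :func:`posterior_from_oddspath`."""
    if not 0.0 < posterior < 1.0:
        raise ValueError("posterior must lie in (0,1)")
    return posterior * (1.0 - prior) / (prior * (1.0 - posterior))


def band_from_oddspath(
    oddspath: float, thresholds: EvidenceThresholds | None = None
) -> Strength:
    """Evidence band of a likelihood ratio on the half-open Tavtigian bands."""
    if oddspath <= 0:
        raise ValueError("oddspath must be positive")
    return (thresholds or EvidenceThresholds()).band(oddspath)


def oddspath_result(
    counts: PatternCounts,
    model: MultinomialModel | None = None,
    thresholds: EvidenceThresholds | None = None,
    cap: float | None = 1e6,
) -> OddsPathResult:
    """Likelihood ratio, posterior and band for one tally."""
    model = model or MultinomialModel()
    lr = likelihood_ratio(counts, model, cap=cap)
    return OddsPathResult(
        oddspath=lr,
        posterior=posterior_from_oddspath(lr, model.prior),
        band=band_from_oddspath(lr, thresholds),
    )


def oddspath_grid(
    max_n: int,
    model: MultinomialModel | None = None,
    thresholds: EvidenceThresholds | None = None,
) -> pd.DataFrame:
    """Exhaustive OddsPath table over every pattern composition with at most
    ``max_n`` evaluable carriers (one row per (N, n1, n2, n3), n0 implied),
    including the N = 0 baseline. Row count is C(max_n + 4, 4)."""
    if max_n < 1:
        raise ValueError("max_n must be >= 1")
    model = model or MultinomialModel()
    rows = []
    for N in range(max_n + 1):
        for n1, n2, n3 in itertools.product(range(N + 1), repeat=3):
            if n1 + n2 + n3 > N:
                continue
            counts = PatternCounts(n1, n2, n3, N - n1 - n2 - n3)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = oddspath_result(counts, model, thresholds)
            rows.append(
                {
                    "N": N,
                    "n1": n1,
                    "n2": n2,
                    "n3": n3,
                    "n0": counts.n0,
                    "oddspath": res.oddspath,
                    "posterior": res.posterior,
                    "band": res.band.value,
                }
            )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class OriginalRule:
    """Presence-based comparator rule: any recurrent hotspot hit is strong
    evidence; any other somatic hit is moderate; otherwise not met.
    The strengths are configurable because the exact historical rule table
    varies between groups."""

    recurrent_strength: Strength = Strength.STRONG
    other_strength: Strength = Strength.MODERATE


def original_pp4(counts: PatternCounts, rule: OriginalRule | None = None) -> Strength:
    """Evidence strength under the presence-based comparator approach, for
    side-by-side comparison with the multinomial OddsPath banding."""
    rule = rule or OriginalRule()
    if counts.n1 >= 1:
        return rule.recurrent_strength
    if counts.n2 >= 1 or counts.n3 >= 1:
        return rule.other_strength
    return Strength.NOT_MET


@dataclass(frozen=True)
class ModelEstimate:
    """An estimated pattern model with the raw tallies behind it and the
    smoothing pseudo-count that was applied (0 = plain frequencies)."""

    model: MultinomialModel
    path_counts: PatternCounts
    null_counts: PatternCounts
    smoothing: float = 0.0


def _frequencies(counts: PatternCounts, smoothing: float) -> tuple[float, ...]:
    raw = np.asarray(counts.as_tuple(), dtype=float) + smoothing
    total = raw.sum()
    if total == 0:
        raise ValueError("cannot estimate frequencies from an empty tally")
    vec = raw / total
    # renormalise exactly so the model's 1e-9 sum invariant holds
    return tuple(float(x) for x in vec / vec.sum())


def estimate_model_from_cohort(
    cases: Iterable[CaseRecord],
    anchor_variants: Sequence[str],
    registry: HotspotRegistry,
    smoothing: float = 0.0,
    prior: float = 0.10,
    key_mode: str = "auto",
) -> ModelEstimate:
    """Re-derive the category probability vectors from a cohort.

    p_path comes from the pattern frequencies among evaluable carriers of the
    anchor variants (established pathogenic alleles); p_null from evaluable
    cases carrying no germline variant. Optional additive smoothing adds the
    given pseudo-count to every category before normalising.
    """
    path = PatternCounts()
    null = PatternCounts()
    n_anchor = 0
    for case in cases:
        if not case.somatic_evaluable:
            continue
        pattern = classify_somatic_pattern(case, registry)
        one = PatternCounts(
            **{
                {"single_recurrent": "n1", "single_nonrecurrent": "n2",
                 "multiple": "n3", "none": "n0"}[pattern.value]: 1
            }
        )
        if any(case.carries(k, key_mode) for k in anchor_variants):
            path = path + one
            n_anchor += 1
        elif not case.germline_variants:
            null = null + one
    if n_anchor == 0:
        raise ValueError("no evaluable carriers of the anchor variants in the cohort")
    if null.N == 0:
        raise ValueError("no evaluable non-carrier cases in the cohort")
    model = MultinomialModel(
        p_path=_frequencies(path, smoothing),
        p_null=_frequencies(null, smoothing),
        prior=prior,
    )
    return ModelEstimate(model=model, path_counts=path, null_counts=null, smoothing=smoothing)
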
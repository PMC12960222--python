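"""Cohort domain model: case records, variant annotations, hotspot registry,
somatic-pattern classification and cohort/non-cohort merging.

The aggregated cohort is a table of patients carrying germline DDX41 variants,
each possibly with acquired (somatic) DDX41 second hits in the malignant clone.
The classical second hit is the missense hotspot R525H; the pattern of second
hits (single recurrent hotspot, single non-recurrent, multiple, none) is the
observable that downstream likelihood-ratio evidence is built on.
"""

from __future__ import annotations

import io
import logging
import re
from collections import Counter
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, NamedTuple, Sequence

import pandas as pd

logger = logging.getLogger(__name__)


class VariantType(str, Enum):
    MISSENSE = "missense"
    NONSENSE = "nonsense"
    FRAMESHIFT = "frameshift"
    CANONICAL_SPLICE = "canonical_splice"
    START_LOSS = "start_loss"
    INFRAME = "inframe"
    SYNONYMOUS = "synonymous"
    INTRONIC = "intronic"
    STRUCTURAL = "structural"
    UTR = "utr"


class Source(str, Enum):
    COHORT = "cohort"
    NON_COHORT = "non_cohort"
    CENTER = "center"


class Diagnosis(str, Enum):
    MDS_AML = "mds_aml"
    OTHER_MYELOID = "other_myeloid"
    CYTOPENIA = "cytopenia"
    LYMPHOID = "lymphoid"
    EXCLUDED = "excluded"


class SomaticPattern(str, Enum):
    SINGLE_RECURRENT = "single_recurrent"
    SINGLE_NONRECURRENT = "single_nonrecurrent"
    MULTIPLE = "multiple"
    NONE = "none"


#: Order of the four pattern categories as used by count vectors (n1,n2,n3,n0).
PATTERN_ORDER = (
    SomaticPattern.SINGLE_RECURRENT,
    SomaticPattern.SINGLE_NONRECURRENT,
    SomaticPattern.MULTIPLE,
    SomaticPattern.NONE,
)

_DIAGNOSIS_ALIASES = {
    "mds": Diagnosis.MDS_AML,
    "aml": Diagnosis.MDS_AML,
    "mds/aml": Diagnosis.MDS_AML,
    "mds_aml": Diagnosis.MDS_AML,
    "other_myeloid": Diagnosis.OTHER_MYELOID,
    "mpn": Diagnosis.OTHER_MYELOID,
    "mds/mpn": Diagnosis.OTHER_MYELOID,
    "cytopenia": Diagnosis.CYTOPENIA,
    "cytopenias": Diagnosis.CYTOPENIA,
    "lymphoid": Diagnosis.LYMPHOID,
    "aplastic anemia": Diagnosis.EXCLUDED,
    "aplastic_anemia": Diagnosis.EXCLUDED,
    "unspecified": Diagnosis.EXCLUDED,
    "excluded": Diagnosis.EXCLUDED,
}


def normalize_protein(p: str) -> str:
    """Canonical protein-change token: strip a leading 'p.'/'p.(...)' wrapper
    and uppercase. Matching is exact string comparison after this step; no
    HGVS grammar is applied."""
    p = p.strip()
    p = re.sub(r"^p\.", "", p, flags=re.IGNORECASE)
    p = p.strip("()")
    return p.upper()


class SchemaError(ValueError):
    """A required column is missing from an input table."""


class ValidationError(ValueError):
    """Input rows are mutually inconsistent (e.g. conflicting diagnoses)."""


class ContractViolation(RuntimeError):
    """An operation was called outside its stated precondition."""


@dataclass(frozen=True)
class GermlineVariant:
    """One distinct germline DDX41 variant with population and score annotations.

    ``pop_af``/``pop_ac_an`` are keyed by ancestry-group label (NFE, EAS, ...).
    Two distinct cDNA descriptions (hgvsc) may share one protein change; the
    aggregation key is chosen via :func:`variant_key`.
    """

    hgvsc: str
    protein_change: str
    variant_type: VariantType
    pop_af: Mapping[str, float] = field(default_factory=dict)
    pop_ac_an: Mapping[str, tuple[int, int]] = field(default_factory=dict)
    revel: float | None = None
    alphamissense: float | None = None
    spliceai: float | None = None
    near_splice_junction: bool = False

    def __post_init__(self) -> None:
        for anc, af in self.pop_af.items():
            if not 0.0 <= af <= 1.0:
                raise ValidationError(f"allele frequency out of [0,1] for {anc}: {af}")
        for anc, (ac, an) in self.pop_ac_an.items():
            if ac < 0 or an < 0 or ac > an:
                raise ValidationError(f"invalid AC/AN for {anc}: {ac}/{an}")
        for name in ("revel", "alphamissense", "spliceai"):
            v = getattr(self, name)
            if v is not None and not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} score out of [0,1]: {v}")
        object.__setattr__(self, "protein_change", normalize_protein(self.protein_change))

    def score(self, tool: str) -> float | None:
        if tool not in ("revel", "alphamissense"):
            raise ValueError(f"unknown tool {tool!r}")
        return getattr(self, tool)

    def max_af(self) -> float:
        """Highest per-ancestry allele frequency (grpmax); 0 if none recorded."""
        afs = dict(self.pop_af)
        for anc, (ac, an) in self.pop_ac_an.items():
            if an > 0 and anc not in afs:
                afs[anc] = ac / an
        return max(afs.values(), default=0.0)

    def total_ac(self) -> int:
        return sum(ac for ac, _ in self.pop_ac_an.values())


def variant_key(variant: GermlineVariant, mode: str = "auto") -> str:
    """Aggregation key for a germline variant.

    mode='auto' uses the protein change for missense/in-frame variants (so
    e.g. a substitution reachable through two codon changes aggregates to one
    key) and the cDNA description otherwise; 'protein' and 'hgvsc' force one
    representation.
    """
    if mode == "protein":
        return variant.protein_change
    if mode == "hgvsc":
        return variant.hgvsc
    if mode != "auto":
        raise ValueError(f"unknown key mode {mode!r}")
    if variant.variant_type in (VariantType.MISSENSE, VariantType.INFRAME):
        return variant.protein_change
    return variant.hgvsc


@dataclass(frozen=True)
class SomaticHit:
    """One acquired DDX41 variant with its variant allele fraction."""

    protein_change: str
    vaf: float | None = None

    def __post_init__(self) -> None:
        if self.vaf is not None and not 0.0 < self.vaf <= 1.0:
            raise ValidationError(f"VAF out of (0,1]: {self.vaf}")
        object.__setattr__(self, "protein_change", normalize_protein(self.protein_change))


@dataclass
class CaseRecord:
    """One patient: diagnosis context, ancestry, germline variant(s) and
    somatic second hit(s).

    ``somatic_evaluable`` records whether somatic testing was performed; a
    non-evaluable case never contributes to pattern tallies.
    """

    case_id: str
    source: Source = Source.COHORT
    diagnosis: Diagnosis = Diagnosis.MDS_AML
    ancestry: str = "unknown"
    germline_variants: list[GermlineVariant] = field(default_factory=list)
    germline_confirmed: bool = False
    somatic_hits: list[SomaticHit] = field(default_factory=list)
    somatic_evaluable: bool = True

    def carries(self, key: str, key_mode: str = "auto") -> bool:
        return any(variant_key(v, key_mode) == key for v in self.germline_variants)


DEFAULT_HOTSPOTS = frozenset(
    {"R525H", "G530D", "P321L", "T227M", "E345D", "G530S", "D344E"}
)


@dataclass(frozen=True)
class HotspotRegistry:
    """Recurrent somatic missense hotspots; R525H dominates empirically."""

    hotspots: frozenset[str] = DEFAULT_HOTSPOTS

    def __post_init__(self) -> None:
        if not self.hotspots:
            raise ValidationError("hotspot registry must be non-empty")
        object.__setattr__(
            self, "hotspots", frozenset(normalize_protein(h) for h in self.hotspots)
        )

    def __contains__(self, protein_change: str) -> bool:
        return normalize_protein(protein_change) in self.hotspots

    @classmethod
    def from_file(cls, path: str) -> "HotspotRegistry":
        with open(path) as fh:
            names = [ln.strip() for ln in fh if ln.strip() and not ln.startswith("#")]
        return cls(frozenset(names))


@dataclass(frozen=True)
class PatternCounts:
    """Tally of somatic-pattern categories among N evaluable carriers:
    n1 single recurrent, n2 single non-recurrent, n3 multiple, n0 none."""

    n1: int = 0
    n2: int = 0
    n3: int = 0
    n0: int = 0

    def __post_init__(self) -> None:
        if min(self.n1, self.n2, self.n3, self.n0) < 0:
            raise ValidationError("pattern counts must be non-negative")

    @property
    def N(self) -> int:
        return self.n1 + self.n2 + self.n3 + self.n0

    def as_tuple(self) -> tuple[int, int, int, int]:
        return (self.n1, self.n2, self.n3, self.n0)

    def __add__(self, other: "PatternCounts") -> "PatternCounts":
        return PatternCounts(
            self.n1 + other.n1, self.n2 + other.n2, self.n3 + other.n3, self.n0 + other.n0
        )


# ---------------------------------------------------------------------------
# Table schemas and readers


@dataclass(frozen=True)
class CohortSchema:
    """Column map for the cohort table (versioned; v1 is the default layout).

    Multi-valued columns (somatic_protein, somatic_vaf) are semicolon-
    separated within a cell. Rows sharing case_id describe one patient with
    several germline variants.
    """

    case_id: str = "case_id"
    source: str = "source"
    diagnosis: str = "diagnosis"
    ancestry: str = "ancestry"
    germline_hgvsc: str = "germline_hgvsc"
    germline_protein: str = "germline_protein"
    germline_confirmed: str = "germline_confirmed"
    somatic_protein: str = "somatic_protein"
    somatic_vaf: str = "somatic_vaf"
    somatic_evaluable: str = "somatic_evaluable"
    version: str = "v1"

    def required(self) -> tuple[str, ...]:
        return (self.case_id, self.diagnosis, self.ancestry)


class RowError(NamedTuple):
    """One malformed input row kept for the error report."""

    case_id: str
    row_index: int
    message: str


class ReadResult(NamedTuple):
    cases: list[CaseRecord]
    errors: list[RowError]


def _parse_fraction(text: str) -> float | None:
    """Accept '0.23', '23%' or blank."""
    text = text.strip()
    if not text or text.lower() in ("na", "nan", "none", "."):
        return None
    if text.endswith("%"):
        return float(text[:-1]) / 100.0
    return float(text)


def _parse_bool(text: str, default: bool) -> bool:
    text = str(text).strip().lower()
    if not text or text in ("na", "nan", "none", "."):
        return default
    return text in ("1", "true", "t", "yes", "y")


def parse_diagnosis(text: str) -> Diagnosis:
    """Map free-text diagnosis labels onto the analysis groups; aplastic
    anemia and unspecified malignancies fall into the excluded group."""
    key = str(text).strip().lower()
    if key in _DIAGNOSIS_ALIASES:
        return _DIAGNOSIS_ALIASES[key]
    try:
        return Diagnosis(key)
    except ValueError:
        return Diagnosis.EXCLUDED


def _read_table(stream) -> pd.DataFrame:
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    return pd.read_csv(stream, sep=None, engine="python", dtype=str).fillna("")


def read_cohort(stream, schema: CohortSchema | None = None) -> ReadResult:
    """Parse a delimited cohort table into case records.

    Rows sharing a case_id are merged into one record (their germline
    variants accumulate); the somatic hits of a case are taken from its first
    row. Malformed rows are collected into the returned error report rather
    than silently dropped. A duplicate case_id with a conflicting diagnosis
    raises :class:`ValidationError`.
    """
    schema = schema or CohortSchema()
    df = _read_table(stream)
    missing = [c for c in schema.required() if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {missing}")

    cases: dict[str, CaseRecord] = {}
    errors: list[RowError] = []
    for idx, row in df.iterrows():
        cid = str(row.get(schema.case_id, "")).strip()
        try:
            diagnosis = parse_diagnosis(row[schema.diagnosis])
            ancestry = str(row.get(schema.ancestry, "")).strip() or "unknown"
            if ancestry.lower() in ("", "na", "nan", "none", "."):
                ancestry = "unknown"
            source_txt = str(row.get(schema.source, "")).strip().lower() or "cohort"
            source = Source(source_txt)
            # somatic testing defaults to performed for cohort-style sources
            evaluable = _parse_bool(row.get(schema.somatic_evaluable, ""), default=True)
            confirmed = _parse_bool(row.get(schema.germline_confirmed, ""), default=False)

            gv: list[GermlineVariant] = []
            hgvsc = str(row.get(schema.germline_hgvsc, "")).strip()
            protein = str(row.get(schema.germline_protein, "")).strip()
            vtype_txt = str(row.get("variant_type", "")).strip().lower()
            if hgvsc or protein:
                vtype = VariantType(vtype_txt) if vtype_txt else VariantType.MISSENSE
                gv.append(GermlineVariant(hgvsc or protein, protein or hgvsc, vtype))

            hits: list[SomaticHit] = []
            prot_cell = str(row.get(schema.somatic_protein, "")).strip()
            vaf_cell = str(row.get(schema.somatic_vaf, "")).strip()
            if prot_cell:
                prots = [p.strip() for p in prot_cell.split(";") if p.strip()]
                vafs = [v.strip() for v in vaf_cell.split(";")] if vaf_cell else []
                vafs += [""] * (len(prots) - len(vafs))
                hits = [
                    SomaticHit(p, _parse_fraction(v)) for p, v in zip(prots, vafs)
                ]

            if cid in cases:
                existing = cases[cid]
                if existing.diagnosis != diagnosis:
                    raise ValidationError(
                        f"case {cid!r}: conflicting diagnoses "
                        f"{existing.diagnosis.value} vs {diagnosis.value}"
                    )
                existing.germline_variants.extend(gv)
                if not existing.somatic_hits:
                    existing.somatic_hits = hits
            else:
                cases[cid] = CaseRecord(
                    case_id=cid,
                    source=source,
                    diagnosis=diagnosis,
                    ancestry=ancestry,
                    germline_variants=gv,
                    germline_confirmed=confirmed,
                    somatic_hits=hits,
                    somatic_evaluable=evaluable,
                )
        except ValidationError:
            raise
        except (ValueError, KeyError) as exc:
            errors.append(RowError(cid, int(idx), str(exc)))
    return ReadResult(list(cases.values()), errors)


_ANC_COL = re.compile(r"^(AC|AN|AF)_(.+)$", re.IGNORECASE)


def read_annotations(stream) -> dict[str, GermlineVariant]:
    """Parse the variant annotation table into a key -> variant map.

    Expected columns: hgvsc, protein, variant_type, optional per-ancestry
    AC_<anc>/AN_<anc> (or AF_<anc>) pairs, revel, alphamissense, spliceai and
    an optional near_splice_junction flag. Keys follow :func:`variant_key`
    with mode='auto'.
    """
    df = _read_table(stream)
    for col in ("hgvsc", "protein", "variant_type"):
        if col not in df.columns:
            raise SchemaError(f"annotation table missing column {col!r}")

    anc_cols: dict[str, dict[str, str]] = {}
    for col in df.columns:
        m = _ANC_COL.match(col)
        if m:
            anc_cols.setdefault(m.group(2), {})[m.group(1).upper()] = col

    out: dict[str, GermlineVariant] = {}
    for _, row in df.iterrows():
        pop_ac_an: dict[str, tuple[int, int]] = {}
        pop_af: dict[str, float] = {}
        for anc, cols in anc_cols.items():
            if "AC" in cols and "AN" in cols and str(row[cols["AN"]]).strip():
                ac = int(float(row[cols["AC"]] or 0))
                an = int(float(row[cols["AN"]] or 0))
                pop_ac_an[anc] = (ac, an)
            if "AF" in cols and str(row[cols["AF"]]).strip():
                pop_af[anc] = float(row[cols["AF"]])
        v = GermlineVariant(
            hgvsc=str(row["hgvsc"]).strip(),
            protein_change=str(row["protein"]).strip(),
            variant_type=VariantType(str(row["variant_type"]).strip().lower()),
            pop_af=pop_af,
            pop_ac_an=pop_ac_an,
            revel=_parse_fraction(str(row.get("revel", ""))),
            alphamissense=_parse_fraction(str(row.get("alphamissense", ""))),
            spliceai=_parse_fraction(str(row.get("spliceai", ""))),
            near_splice_junction=_parse_bool(str(row.get("near_splice_junction", "")), False),
        )
        out[variant_key(v)] = v
    return out


# ---------------------------------------------------------------------------
# Pattern classification and tallies


def classify_somatic_pattern(case: CaseRecord, registry: HotspotRegistry) -> SomaticPattern:
    """Deterministic four-way pattern of a case's somatic second hits.

    Zero hits -> NONE; one hit that is a registry hotspot -> SINGLE_RECURRENT;
    one non-hotspot hit -> SINGLE_NONRECURRENT; two or more hits -> MULTIPLE
    regardless of which hits they are.
    """
    if not case.somatic_evaluable:
        raise ContractViolation(
            f"case {case.case_id!r} is not somatically evaluable"
        )
    hits = case.somatic_hits
    if len(hits) == 0:
        return SomaticPattern.NONE
    if len(hits) >= 2:
        return SomaticPattern.MULTIPLE
    if hits[0].protein_change in registry:
        return SomaticPattern.SINGLE_RECURRENT
    return SomaticPattern.SINGLE_NONRECURRENT


def tally_patterns(
    key: str,
    cases: Iterable[CaseRecord],
    registry: HotspotRegistry,
    key_mode: str = "auto",
) -> PatternCounts:
    """Pattern tally over all evaluable carriers of a germline variant,
    across all diagnoses. A case carrying two germline variants contributes
    its pattern to each variant's tally. Zero carriers give an all-zero tally.
    """
    counts = Counter()
    for case in cases:
        if not case.somatic_evaluable:
            continue
        if case.carries(key, key_mode):
            counts[classify_somatic_pattern(case, registry)] += 1
    return PatternCounts(
        n1=counts[SomaticPattern.SINGLE_RECURRENT],
        n2=counts[SomaticPattern.SINGLE_NONRECURRENT],
        n3=counts[SomaticPattern.MULTIPLE],
        n0=counts[SomaticPattern.NONE],
    )


class MergeDecision(NamedTuple):
    case_id: str
    retained: bool
    reason: str


def merge_noncohort(
    cohort_cases: Sequence[CaseRecord],
    noncohort_cases: Sequence[CaseRecord],
    key_mode: str = "auto",
) -> tuple[list[CaseRecord], list[MergeDecision]]:
    """Fold non-cohort case reports into the cohort without double counting.

    All non-cohort cases lacking somatic hits are retained. A non-cohort case
    with somatic hits is retained only if no cohort case with the same
    germline variant key reports the identical somatic protein-change set.
    Cases whose case_id is already present are skipped, which makes the merge
    idempotent. Every decision is returned in the log.
    """
    seen_ids = {c.case_id for c in cohort_cases}
    # (variant_key, frozen somatic set) combinations already in the cohort
    reported: set[tuple[str, frozenset[str]]] = set()
    for c in cohort_cases:
        if not c.somatic_hits:
            continue
        hitset = frozenset(h.protein_change for h in c.somatic_hits)
        for gv in c.germline_variants:
            reported.add((variant_key(gv, key_mode), hitset))

    merged = list(cohort_cases)
    log: list[MergeDecision] = []
    for c in noncohort_cases:
        if c.case_id in seen_ids:
            log.append(MergeDecision(c.case_id, False, "duplicate case_id"))
            continue
        if not c.somatic_hits:
            merged.append(c)
            seen_ids.add(c.case_id)
            log.append(MergeDecision(c.case_id, True, "no somatic hit"))
            continue
        hitset = frozenset(h.protein_change for h in c.somatic_hits)
        dup = any(
            (variant_key(gv, key_mode), hitset) in reported for gv in c.germline_variants
        )
        if dup:
            log.append(
                MergeDecision(c.case_id, False, "somatic hit set already reported in cohort")
            )
        else:
            merged.append(c)
            seen_ids.add(c.case_id)
            for gv in c.germline_variants:
                reported.add((variant_key(gv, key_mode), hitset))
            log.append(MergeDecision(c.case_id, True, "unique somatic hit set"))
    for d in log:
        logger.debug("merge_noncohort: %s retained=%s (%s)", d.case_id, d.retained, d.reason)
    return merged, log
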
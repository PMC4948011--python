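"""Core domain types shared across the pipeline.

All genomic coordinates are 0-based half-open (BED convention). Conversion
from 1-based closed conventions (GFF3, BLAST tabular) happens once, at the
parser boundary, and back again only when serializing to such a format.
Identity and coverage are stored as fractions in [0, 1], never percentages.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence


class ValidationError(ValueError):
    """A record violates one of its declared invariants."""


@dataclass(frozen=True)
class AnchorHit:
    """One filtered alignment of a query (CDS / marker / primer) to a target genome.

    ``strand`` refers to the orientation of the alignment on the *target*
    genome only; a genetic-map query has no strand of its own. ``query_*``
    coordinates are base pairs for sequence queries and centimorgan
    (scaled) units when the query axis is a genetic map; they may be absent
    for unplaced queries.
    """

    query_id: str
    target_chrom: str
    target_start: int
    target_end: int
    strand: str = "+"
    identity: Optional[float] = None
    coverage: Optional[float] = None
    aligned_length: int = 0
    match_bp: int = 0
    mismatch_bp: int = 0
    query_chrom: Optional[str] = None
    query_start: Optional[float] = None
    query_end: Optional[float] = None

    def __post_init__(self) -> None:
        if self.target_start >= self.target_end:
            raise ValidationError(
                f"{self.query_id}: target interval "
                f"[{self.target_start}, {self.target_end}) is empty or inverted"
            )
        if self.strand not in ("+", "-"):
            raise ValidationError(f"{self.query_id}: bad strand {self.strand!r}")
        if self.identity is not None and not (0.0 <= self.identity <= 1.0):
            raise ValidationError(f"{self.query_id}: identity {self.identity} not in [0,1]")
        if self.coverage is not None and not (0.0 <= self.coverage <= 1.0):
            raise ValidationError(f"{self.query_id}: coverage {self.coverage} not in [0,1]")
        if self.match_bp > self.aligned_length:
            raise ValidationError(
                f"{self.query_id}: match_bp {self.match_bp} exceeds "
                f"aligned_length {self.aligned_length}"
            )

    @property
    def target_span(self) -> int:
        return self.target_end - self.target_start

    @property
    def target_mid(self) -> float:
        return (self.target_start + self.target_end) / 2.0

    @property
    def query_mid(self) -> Optional[float]:
        if self.query_start is None or self.query_end is None:
            return None
        return (self.query_start + self.query_end) / 2.0


@dataclass(frozen=True)
class FilterPolicy:
    """Alignment-quality thresholds; absent thresholds are not applied.

    All thresholds are inclusive: a hit sitting exactly on a threshold is
    retained, so printed boundary values like 80% identity pass.
    """

    min_identity: Optional[float] = None
    min_coverage: Optional[float] = None
    min_aligned_length: Optional[int] = None
    min_match_bp: Optional[int] = None
    max_mismatch_bp: Optional[int] = None
    name: str = ""

    def __post_init__(self) -> None:
        for attr in ("min_identity", "min_coverage"):
            v = getattr(self, attr)
            if v is not None and not (0.0 <= v <= 1.0):
                raise ValidationError(f"{attr}={v} not a fraction in [0,1]")
        for attr in ("min_aligned_length", "min_match_bp", "max_mismatch_bp"):
            v = getattr(self, attr)
            if v is not None and v < 0:
                raise ValidationError(f"{attr}={v} is negative")

    def passes(self, hit: AnchorHit) -> bool:
        if self.min_identity is not None:
            if hit.identity is None or hit.identity < self.min_identity:
                return False
        if self.min_coverage is not None:
            if hit.coverage is None or hit.coverage < self.min_coverage:
                return False
        if self.min_aligned_length is not None and hit.aligned_length < self.min_aligned_length:
            return False
        if self.min_match_bp is not None and hit.match_bp < self.min_match_bp:
            return False
        if self.max_mismatch_bp is not None and hit.mismatch_bp > self.max_mismatch_bp:
            return False
        return True


@dataclass(frozen=True)
class GeneticMapMarker:
    marker_id: str
    linkage_group: str
    cM: float

    def __post_init__(self) -> None:
        if self.cM < 0:
            raise ValidationError(f"{self.marker_id}: negative cM {self.cM}")


@dataclass(frozen=True)
class QTLRecord:
    """A QTL on a genetic map: peak and LOD confidence interval in cM.

    ``per_environment_cis`` holds one (lo, hi) pair per trial environment
    when the mapping study reported environment-specific support intervals;
    they are averaged element-wise before projection.
    """

    qtl_id: str
    trait: str
    linkage_group: str
    peak_cM: float
    ci_lo_cM: float
    ci_hi_cM: float
    pve: float = 0.0
    per_environment_cis: tuple = ()

    def __post_init__(self) -> None:
        if not (self.ci_lo_cM <= self.peak_cM <= self.ci_hi_cM):
            raise ValidationError(
                f"{self.qtl_id}: peak {self.peak_cM} outside CI "
                f"[{self.ci_lo_cM}, {self.ci_hi_cM}]"
            )
        if self.pve < 0:
            raise ValidationError(f"{self.qtl_id}: negative PVE {self.pve}")


@dataclass(frozen=True)
class MarkerAnchor:
    """A genetic-map marker placed on a physical genome."""

    marker_id: str
    linkage_group: str
    cM: float
    target_chrom: str
    target_bp: int


@dataclass(frozen=True)
class PhysicalQTL:
    """A QTL confidence interval expressed in target-genome base pairs."""

    qtl_id: str
    trait: str
    species: str
    chrom: str
    start_bp: int
    end_bp: int
    peak_bp: int
    pve: float = 0.0

    def __post_init__(self) -> None:
        if not (self.start_bp <= self.peak_bp <= self.end_bp):
            raise ValidationError(
                f"{self.qtl_id}: peak {self.peak_bp} outside "
                f"[{self.start_bp}, {self.end_bp}]"
            )


@dataclass
class SyntenyBlock:
    """A maximal run of order-consistent anchors linking two chromosome intervals.

    ``orientation`` is '+' when query positions increase with target
    position along the block, '-' when they decrease.
    """

    query_chrom: str
    query_start: float
    query_end: float
    target_chrom: str
    target_start: int
    target_end: int
    orientation: str
    anchors: list = field(default_factory=list)

    @property
    def anchor_count(self) -> int:
        return len(self.anchors)

    @property
    def target_span(self) -> int:
        return self.target_end - self.target_start

    @property
    def target_mid(self) -> float:
        return (self.target_start + self.target_end) / 2.0

    @property
    def query_mid(self) -> float:
        return (self.query_start + self.query_end) / 2.0


@dataclass
class RearrangementCall:
    """A classified structural difference between the two genomes."""

    kind: str  # inversion | translocation | transposition | duplication
    query_chrom: str
    target_chrom: str
    query_start: float
    query_end: float
    target_start: int
    target_end: int
    target_span_bp: int
    n_anchors: int
    orientation: str
    blocks: list = field(default_factory=list)


@dataclass(frozen=True)
class ChainParams:
    """Anchor-chaining and rearrangement-calling parameters.

    ``min_span_bp`` implements the rule that translocations and inversions
    are only reported when the involved target-genome region spans at least
    0.5 Mb. ``max_gap_query`` defaults to ``max_gap_bp``; set it separately
    (e.g. in cM-scaled units) when the query axis is a genetic map.
    """

    max_gap_bp: int = 3_000_000
    min_anchors: int = 3
    min_span_bp: int = 500_000
    max_gap_query: Optional[float] = None
    duplication_overlap: float = 0.5

    def __post_init__(self) -> None:
        if self.max_gap_bp <= 0 or self.min_anchors <= 0 or self.min_span_bp <= 0:
            raise ValidationError("ChainParams fields must be positive")

    @property
    def query_gap(self) -> float:
        return self.max_gap_bp if self.max_gap_query is None else self.max_gap_query


@dataclass(frozen=True)
class ColocationGroup:
    """Two or more distinct queries whose best hits share one target locus."""

    target_chrom: str
    start: int
    end: int
    member_query_ids: frozenset

    def __post_init__(self) -> None:
        if len(self.member_query_ids) < 2:
            raise ValidationError("a colocation group needs at least two members")


@dataclass
class OrthologyCluster:
    """Co-localized QTL intervals, possibly from two species."""

    cluster_id: str
    chrom: str
    start_bp: int
    end_bp: int
    members_a: list = field(default_factory=list)
    members_b: list = field(default_factory=list)

    @property
    def trait_classes(self) -> set:
        return {q.trait for q in self.members_a} | {q.trait for q in self.members_b}

    @property
    def orthologous(self) -> bool:
        return bool(self.members_a) and bool(self.members_b)

    @property
    def n_members(self) -> int:
        return len(self.members_a) + len(self.members_b)


def interval_gap(a_start: float, a_end: float, b_start: float, b_end: float) -> float:
    """Gap between two half-open intervals; 0 when they overlap or touch."""
    return max(0.0, max(a_start, b_start) - min(a_end, b_end))


def reciprocal_overlap(a_start: float, a_end: float, b_start: float, b_end: float) -> float:
    """Overlap length divided by the longer interval length (0 when disjoint)."""
    ov = min(a_end, b_end) - max(a_start, b_start)
    if ov <= 0:
        return 0.0
    return ov / max(a_end - a_start, b_end - b_start)


def clone(obj, **changes):
    """dataclasses.replace re-exported for terse call sites."""
    return replace(obj, **changes)
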
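"""Marker anchoring from primer-pair alignments (COSII-style).

A COSII marker is defined by a forward/reverse primer pair and a known
amplicon (COS) length. Short primers hit a genome thousands of times; a
marker is anchored only when some forward hit and some reverse hit land on
the same chromosome, on opposite strands, at an outer-edge distance
consistent with the expected amplicon length.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence

from .model import AnchorHit

#: reason codes for unpaired markers
NO_COMMON_CHROM = "no-common-chrom"
STRAND_INCOMPATIBLE = "strand-incompatible"
NO_SPAN_MATCH = "no-span-match"


@dataclass
class PrimerPair:
    marker_id: str
    fwd_hits: List[AnchorHit] = field(default_factory=list)
    rev_hits: List[AnchorHit] = field(default_factory=list)
    expected_length_bp: int = 0
    length_tolerance: float = 0.25  # relative slack unless slack_bp given
    slack_bp: Optional[int] = None

    def __post_init__(self) -> None:
        if self.expected_length_bp <= 0:
            raise ValueError(f"{self.marker_id}: expected_length_bp must be positive")


@dataclass
class PairingResult:
    marker_id: str
    anchor: Optional[AnchorHit]
    reason: Optional[str] = None  # set when anchor is None
    span_bp: Optional[int] = None


def pair_primers(pair: PrimerPair, require_opposite_strands: bool = True) -> PairingResult:
    """Retain a marker when its primers bracket a plausible amplicon.

    Enumerates (forward, reverse) hit combinations on a common chromosome
    with (by default) opposite strands, whose outer-edge span falls within
    the slack window around the expected amplicon length. Among valid
    combinations the one with span closest to the expected length wins and
    is synthesized into a single marker anchor spanning both primer hits.
    Intron-length divergence between species makes exact spans unrealistic,
    hence the default ±25% relative slack.
    """
    if pair.slack_bp is not None:
        lo = pair.expected_length_bp - pair.slack_bp
        hi = pair.expected_length_bp + pair.slack_bp
    else:
        lo = pair.expected_length_bp * (1.0 - pair.length_tolerance)
        hi = pair.expected_length_bp * (1.0 + pair.length_tolerance)

    fwd_chroms = {h.target_chrom for h in pair.fwd_hits}
    rev_chroms = {h.target_chrom for h in pair.rev_hits}
    if not (fwd_chroms & rev_chroms):
        return PairingResult(pair.marker_id, None, reason=NO_COMMON_CHROM)

    best = None
    best_err = None
    saw_strand_compatible = False
    for f in pair.fwd_hits:
        for r in pair.rev_hits:
            if f.target_chrom != r.target_chrom:
                continue
            if require_opposite_strands and f.strand == r.strand:
                continue
            saw_strand_compatible = True
            start = min(f.target_start, r.target_start)
            end = max(f.target_end, r.target_end)
            span = end - start
            if not (lo <= span <= hi):
                continue
            err = abs(span - pair.expected_length_bp)
            cand = (f, r, start, end, span)
            # deterministic tie-break on genomic position
            if best is None or err < best_err or (
                err == best_err and (cand[2], cand[3]) < (best[2], best[3])
            ):
                best, best_err = cand, err
    if best is None:
        reason = NO_SPAN_MATCH if saw_strand_compatible else STRAND_INCOMPATIBLE
        return PairingResult(pair.marker_id, None, reason=reason)

    f, r, start, end, span = best
    assert lo <= span <= hi  # post-condition: the span predicate holds
    anchor = AnchorHit(
        query_id=pair.marker_id,
        target_chrom=f.target_chrom,
        target_start=start,
        target_end=end,
        strand=f.strand,
        identity=_mean_opt(f.identity, r.identity),
        coverage=_mean_opt(f.coverage, r.coverage),
        aligned_length=f.aligned_length + r.aligned_length,
        match_bp=f.match_bp + r.match_bp,
        mismatch_bp=f.mismatch_bp + r.mismatch_bp,
    )
    return PairingResult(pair.marker_id, anchor, span_bp=span)


def pair_all(pairs: Sequence[PrimerPair], **kwargs) -> List[PairingResult]:
    return [pair_primers(p, **kwargs) for p in pairs]


def _mean_opt(a: Optional[float], b: Optional[float]) -> Optional[float]:
    vals = [v for v in (a, b) if v is not None]
    return sum(vals) / len(vals) if vals else None
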
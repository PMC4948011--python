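"""Alignment-hit filtering, best-hit selection and co-location grouping.

The six shipped policy presets reproduce the per-dataset filters used for
the Solanaceae CDS and marker alignments: tomato-CDS-on-pepper and
pepper-CDS-on-tomato share one policy (80% identity, 75% coverage, 200 bp
minimum alignment), the pepper-marker and eggplant-marker self-alignments
use match/mismatch base-pair thresholds, and the cross-species
eggplant-marker alignments relax identity and coverage because intergenic
marker sequences are poorly conserved between genera.
"""

from __future__ import annotations

from typing import Dict, Iterable, List, Sequence

from .model import AnchorHit, ColocationGroup, FilterPolicy, interval_gap

#: Per-dataset filter presets, keyed by the dataset's conventional name
#: (query/target): e.g. ``tocds-peg`` = tomato CDS aligned to pepper genome.
PRESETS: Dict[str, FilterPolicy] = {
    "tocds-peg": FilterPolicy(min_identity=0.80, min_coverage=0.75,
                              min_aligned_length=200, name="tocds-peg"),
    "pecds-tog": FilterPolicy(min_identity=0.80, min_coverage=0.75,
                              min_aligned_length=200, name="pecds-tog"),
    "pem-peg": FilterPolicy(min_identity=0.98, min_match_bp=200,
                            max_mismatch_bp=50, name="pem-peg"),
    "egm-egg": FilterPolicy(min_identity=0.75, min_match_bp=100,
                            max_mismatch_bp=50, name="egm-egg"),
    "egm-tog": FilterPolicy(min_identity=0.75, min_coverage=0.40,
                            min_aligned_length=200, name="egm-tog"),
    "egm-peg": FilterPolicy(min_identity=0.75, min_coverage=0.40,
                            min_aligned_length=200, name="egm-peg"),
}


def filter_hits(hits: Iterable[AnchorHit], policy: FilterPolicy) -> List[AnchorHit]:
    """Keep exactly the hits meeting every threshold present in ``policy``.

    Thresholds are inclusive; input order is preserved; the operation is
    idempotent. An empty result is legal.
    """
    return [h for h in hits if policy.passes(h)]


def select_best_hit(hits_of_one_query: Sequence[AnchorHit]) -> AnchorHit:
    """Resolve a multi-hit query to its single best hit.

    Ranking is strict lexicographic on (match_bp, identity, coverage) —
    highest first — with a deterministic positional tie-break: lowest
    target chromosome name, then lowest target start.
    """
    if not hits_of_one_query:
        raise ValueError("select_best_hit: empty hit list")
    qids = {h.query_id for h in hits_of_one_query}
    if len(qids) > 1:
        raise ValueError(f"select_best_hit: mixed query ids {sorted(qids)}")

    def key(h: AnchorHit):
        return (
            -h.match_bp,
            -(h.identity if h.identity is not None else -1.0),
            -(h.coverage if h.coverage is not None else -1.0),
            h.target_chrom,
            h.target_start,
        )

    return min(hits_of_one_query, key=key)


def best_hits(hits: Iterable[AnchorHit]) -> List[AnchorHit]:
    """One best hit per query_id, in order of each query's first appearance."""
    by_query: Dict[str, List[AnchorHit]] = {}
    for h in hits:
        by_query.setdefault(h.query_id, []).append(h)
    return [select_best_hit(group) for group in by_query.values()]


def find_colocated_queries(
    hits: Sequence[AnchorHit], tolerance_bp: int = 25
) -> List[ColocationGroup]:
    """Detect groups of distinct queries aligned to the same target locus.

    Two hits are linked when they lie on the same target chromosome and
    their intervals overlap or are separated by at most ``tolerance_bp``
    (gap distance between interval hulls, so partial alignments still
    group). Groups are the connected components of this relation;
    singletons are not reported. Members of multi-member groups are the
    "non-unique match" queries.
    """
    if tolerance_bp < 0:
        raise ValueError("tolerance_bp must be non-negative")
    order = sorted(range(len(hits)), key=lambda i: (
        hits[i].target_chrom, hits[i].target_start, hits[i].target_end, hits[i].query_id))
    groups: List[ColocationGroup] = []
    cur: List[AnchorHit] = []
    cur_end = None
    cur_chrom = None

    def flush():
        if len(cur) >= 2:
            groups.append(
                ColocationGroup(
                    target_chrom=cur_chrom,
                    start=min(h.target_start for h in cur),
                    end=max(h.target_end for h in cur),
                    member_query_ids=frozenset(h.query_id for h in cur),
                )
            )

    # sweep: components of the "gap <= tolerance" relation on one axis are
    # exactly the runs where each hit starts within tolerance of the
    # running maximum end
    for i in order:
        h = hits[i]
        if cur and h.target_chrom == cur_chrom and h.target_start - cur_end <= tolerance_bp:
            cur.append(h)
            cur_end = max(cur_end, h.target_end)
        else:
            flush()
            cur = [h]
            cur_end = h.target_end
            cur_chrom = h.target_chrom
    flush()
    groups.sort(key=lambda g: (g.target_chrom, g.start, g.end))
    return groups


def colocation_summary(hits: Sequence[AnchorHit], groups: Sequence[ColocationGroup]) -> dict:
    """Counts mirroring how such screens are usually reported: total queries,
    queries in multi-member groups (non-unique matches), and unique queries."""
    grouped = set()
    for g in groups:
        grouped |= g.member_query_ids
    total = len({h.query_id for h in hits})
    return {
        "total_queries": total,
        "non_unique_queries": len(grouped),
        "unique_queries": total - len(grouped),
        "n_groups": len(groups),
    }
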
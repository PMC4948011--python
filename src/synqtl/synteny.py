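"""Anchor chaining into syntenic blocks and rearrangement classification.

Rearrangements between two genomes manifest as characteristic patterns in
the anchor dot plot: a run of anchors with reversed local slope is an
inversion, a block whose query chromosome disagrees with the
chromosome-level orthology is a translocation, an in-place block displaced
out of rank order along its chromosome is a transposition, and two blocks
covering the same query interval at disjoint target loci indicate a
duplication. This module formalizes that visual reading: greedy
single-linkage chaining of order-consistent anchors, then per-block
classification against the anchor-weighted majority behaviour of each
chromosome pair. Translocations and inversions (and the other kinds) are
only reported when the involved target region spans at least
``ChainParams.min_span_bp`` (default 0.5 Mb).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.stats import kendalltau

from .model import (
    AnchorHit,
    ChainParams,
    RearrangementCall,
    SyntenyBlock,
    interval_gap,
    reciprocal_overlap,
)


@dataclass
class OrthologyAssignment:
    """Chromosome-level orthology inferred from anchor pluralities."""

    mapping: Dict[str, str]               # target_chrom -> query_chrom
    counts: pd.DataFrame                  # target_chrom x query_chrom anchor counts
    same_chromosome_fraction: float       # fraction of anchors on a plurality pair


def assign_chromosome_orthology(hits: Sequence[AnchorHit]) -> OrthologyAssignment:
    """Map each target chromosome to the query chromosome contributing the
    plurality of its anchors.

    Also returns the full anchor-count matrix and the fraction of anchors
    that lie on their target chromosome's plurality pairing — the analogue
    of counting how many aligned sequences land "on the same chromosome".
    Ties break on query chromosome name for determinism.
    """
    placed = [h for h in hits if h.query_chrom is not None]
    if not placed:
        return OrthologyAssignment({}, pd.DataFrame(), 0.0)
    df = pd.DataFrame(
        {"t": [h.target_chrom for h in placed], "q": [h.query_chrom for h in placed]}
    )
    counts = df.groupby(["t", "q"]).size().unstack(fill_value=0).sort_index()
    counts = counts[sorted(counts.columns)]
    mapping = {}
    on_plurality = 0
    for t, row in counts.iterrows():
        best = row.max()
        winner = sorted(c for c in row.index if row[c] == best)[0]
        mapping[t] = winner
        on_plurality += int(row[winner])
    return OrthologyAssignment(mapping, counts, on_plurality / len(placed))


@dataclass
class ChainResult:
    blocks: List[SyntenyBlock]
    dropped: List[AnchorHit]  # anchors in sub-minimum runs or lacking query coords


def chain_anchors(hits: Sequence[AnchorHit], params: ChainParams) -> ChainResult:
    """Greedy single-linkage chaining per (query_chrom, target_chrom) pair.

    Anchors are sorted by target position; the current block extends while
    the next anchor is within the gap limits on both genomes and keeps the
    block's query-order direction (set by the first step). Runs shorter
    than ``min_anchors`` are dropped but reported, so every input anchor is
    accounted for. Orientation is the sign of the Kendall rank correlation
    between query and target positions over the block, which the direction
    rule makes exactly ±1.
    """
    blocks: List[SyntenyBlock] = []
    dropped: List[AnchorHit] = []
    usable: Dict[Tuple[str, str], List[AnchorHit]] = {}
    for h in hits:
        if h.query_chrom is None or h.query_mid is None:
            dropped.append(h)
            continue
        usable.setdefault((h.query_chrom, h.target_chrom), []).append(h)

    for (qc, tc) in sorted(usable):
        group = sorted(usable[(qc, tc)], key=lambda h: (h.target_start, h.target_end, h.query_id))
        run: List[AnchorHit] = [group[0]]
        direction = 0

        def close_run(run: List[AnchorHit], direction: int) -> None:
            # sub-minimum runs stay provisional: boundary refinement may
            # still hand them back anchors absorbed by a neighbouring run
            blocks.append(
                SyntenyBlock(
                    query_chrom=qc,
                    query_start=min(h.query_start for h in run),
                    query_end=max(h.query_end for h in run),
                    target_chrom=tc,
                    target_start=min(h.target_start for h in run),
                    target_end=max(h.target_end for h in run),
                    orientation="-" if direction < 0 else "+",
                    anchors=list(run),
                )
            )

        for h in group[1:]:
            prev = run[-1]
            tgap = max(0, h.target_start - prev.target_end)
            qgap = interval_gap(prev.query_start, prev.query_end, h.query_start, h.query_end)
            step = np.sign(h.query_mid - prev.query_mid)
            ok = (
                tgap <= params.max_gap_bp
                and qgap <= params.query_gap
                and (step == 0 or direction == 0 or step == direction)
            )
            if ok:
                run.append(h)
                if direction == 0:
                    direction = int(step)
            else:
                close_run(run, direction)
                run = [h]
                direction = 0
        close_run(run, direction)

    _refine_boundaries(blocks, params)
    kept_blocks: List[SyntenyBlock] = []
    for b in blocks:
        _trim_block_edges(b, params, dropped)
        if b.anchor_count >= params.min_anchors:
            kept_blocks.append(b)
        else:
            dropped.extend(b.anchors)
    blocks = kept_blocks
    blocks.sort(key=lambda b: (b.target_chrom, b.target_start, b.query_chrom))
    return ChainResult(blocks, dropped)


def _trim_block_edges(b: SyntenyBlock, params: ChainParams,
                      dropped: List[AnchorHit]) -> None:
    """Drop boundary anchors that sit far off the block's own diagonal.

    A spurious hit can legally join the head or tail of a run (its random
    query position may land within the gap limit in the right direction),
    stretching the block's query hull by megabases and corrupting every
    hull-based classification downstream. An edge anchor is trimmed when
    its query step to the adjacent anchor exceeds five times the block's
    median query-per-target step ratio over that distance. The ratio test
    is scale-free, so it applies equally when the query axis is a genetic
    map in cM.
    """
    while b.anchor_count > max(params.min_anchors, 3):
        q = [a.query_mid for a in b.anchors]
        t = [a.target_mid for a in b.anchors]
        dts = [max(abs(t[i + 1] - t[i]), 1.0) for i in range(len(t) - 1)]
        dqs = [abs(q[i + 1] - q[i]) for i in range(len(q) - 1)]
        med_r = float(np.median([dq / dt for dq, dt in zip(dqs, dts)]))
        med_t = float(np.median(dts))
        floor = 5.0 * max(med_r, 1e-12) * med_t

        def outlier(i: int) -> bool:
            return dqs[i] > max(5.0 * med_r * max(dts[i], med_t), floor)

        if outlier(0):
            dropped.append(b.anchors.pop(0))
        elif outlier(len(dqs) - 1):
            dropped.append(b.anchors.pop())
        else:
            break
        _hull_update(b)


def _hull_update(b: SyntenyBlock) -> None:
    b.anchors.sort(key=lambda a: (a.target_start, a.target_end))
    b.query_start = min(a.query_start for a in b.anchors)
    b.query_end = max(a.query_end for a in b.anchors)
    b.target_start = min(a.target_start for a in b.anchors)
    b.target_end = max(a.target_end for a in b.anchors)


def _hull_dist(x: float, lo: float, hi: float) -> float:
    return max(lo - x, x - hi, 0.0)


def _refine_boundaries(blocks: List[SyntenyBlock], params: ChainParams) -> None:
    """Reassign boundary anchors between target-adjacent blocks.

    Greedy chaining can absorb the first anchor of a reversed (or
    displaced) run into the preceding block, because the jump to that
    anchor still respects gap and direction rules; the anchor then belongs
    to the wrong block and can shave a rearrangement below the reporting
    span. An anchor at a block edge moves to the neighbouring block when
    its query position is strictly closer to the neighbour's query hull
    than to its own next-door anchor, provided the move keeps the
    neighbour's direction rule and gap limit and the donor retains
    ``min_anchors`` anchors.
    """
    by_pair: Dict[Tuple[str, str], List[SyntenyBlock]] = {}
    for b in blocks:
        by_pair.setdefault((b.query_chrom, b.target_chrom), []).append(b)
    for pair_blocks in by_pair.values():
        pair_blocks.sort(key=lambda b: b.target_start)
        for a, b in zip(pair_blocks, pair_blocks[1:]):
            moved = True
            guard = 0
            while moved and guard < 25:
                moved = False
                guard += 1
                # tail of a -> head of b
                if a.anchor_count >= 2:
                    x = a.anchors[-1]
                    d_own = abs(x.query_mid - a.anchors[-2].query_mid)
                    d_other = _hull_dist(x.query_mid, b.query_start, b.query_end)
                    first = b.anchors[0]
                    dir_ok = (x.query_mid >= first.query_mid) if b.orientation == "-" \
                        else (x.query_mid <= first.query_mid)
                    qgap = interval_gap(x.query_start, x.query_end,
                                        first.query_start, first.query_end)
                    if d_other < d_own and dir_ok and qgap <= params.query_gap:
                        b.anchors.insert(0, a.anchors.pop())
                        _hull_update(a)
                        _hull_update(b)
                        moved = True
                        continue
                # head of b -> tail of a
                if b.anchor_count >= 2:
                    y = b.anchors[0]
                    d_own = abs(y.query_mid - b.anchors[1].query_mid)
                    d_other = _hull_dist(y.query_mid, a.query_start, a.query_end)
                    last = a.anchors[-1]
                    dir_ok = (y.query_mid <= last.query_mid) if a.orientation == "-" \
                        else (y.query_mid >= last.query_mid)
                    qgap = interval_gap(y.query_start, y.query_end,
                                        last.query_start, last.query_end)
                    if d_other < d_own and dir_ok and qgap <= params.query_gap:
                        a.anchors.append(b.anchors.pop(0))
                        _hull_update(a)
                        _hull_update(b)
                        moved = True


def block_orientation_kendall(block: SyntenyBlock) -> Optional[str]:
    """Orientation via the Kendall tau sign over the block's anchors
    (independent of the direction rule; used as a cross-check)."""
    if block.anchor_count < 2:
        return None
    q = [a.query_mid for a in block.anchors]
    t = [a.target_mid for a in block.anchors]
    tau = kendalltau(q, t).statistic
    if tau is None or np.isnan(tau) or tau == 0:
        return None
    return "+" if tau > 0 else "-"


def dominant_orientations(blocks: Sequence[SyntenyBlock]) -> Dict[Tuple[str, str], str]:
    """Anchor-weighted majority orientation per chromosome pair, so one
    large inversion on a small arm cannot flip the pair's reference
    orientation. Ties resolve to '+'."""
    weight: Dict[Tuple[str, str], int] = {}
    for b in blocks:
        key = (b.query_chrom, b.target_chrom)
        w = b.anchor_count if b.orientation == "+" else -b.anchor_count
        weight[key] = weight.get(key, 0) + w
    return {k: ("+" if w >= 0 else "-") for k, w in weight.items()}


def _is_displaced(block: SyntenyBlock, prev: Optional[SyntenyBlock],
                  nxt: Optional[SyntenyBlock], dominant: str,
                  max_gap_query: float) -> bool:
    """True when the block's query interval deviates from the colinear
    diagonal through its flanking anchors.

    Along an undisturbed chromosome pair, query position tracks target
    position ('+' dominant) or its mirror ('-'), so the query offset
    between a block edge and a flanking anchor should match the target
    offset between them. A transposed segment deviates by its jump
    distance. Every available flank must deviate by more than the chaining
    query-gap limit — any smaller jump would have been chained through
    rather than split into its own block.
    """
    sign = 1.0 if dominant == "+" else -1.0
    deviations = []
    if prev is not None:
        f = prev.anchors[-1]
        dt = block.target_start - f.target_mid
        dq = (block.query_start if dominant == "+" else block.query_end) - f.query_mid
        deviations.append(abs(dq - sign * dt))
    if nxt is not None:
        f = nxt.anchors[0]
        dt = f.target_mid - block.target_end
        dq = f.query_mid - (block.query_end if dominant == "+" else block.query_start)
        deviations.append(abs(dq - sign * dt))
    if not deviations:
        return False
    return min(deviations) > max_gap_query


def _mirrored_fraction(small: SyntenyBlock, other: SyntenyBlock) -> float:
    """Fraction of ``small``'s anchors whose query interval is mirrored by
    an anchor of ``other`` (query midpoint inside ``small``'s query hull).

    Anchor-level support distinguishes a duplication from a transposition:
    after a duplication the backbone still carries anchors over the
    duplicated query segment (the source copy), whereas after a
    transposition the backbone block's query *hull* spans the vacated
    segment but contains no anchors there.
    """
    lo, hi = small.query_start, small.query_end
    n_in = sum(1 for a in other.anchors
               if a.query_mid is not None and lo <= a.query_mid <= hi)
    return n_in / small.anchor_count if small.anchor_count else 0.0


def _duplication_groups(blocks: Sequence[SyntenyBlock], params: ChainParams) -> List[List[int]]:
    """Connected components of duplication links.

    Two blocks on one query chromosome are linked when their target
    intervals are disjoint (different chromosome or non-overlapping) and
    the larger block's anchors mirror at least ``duplication_overlap`` of
    the smaller block's anchors over its query interval.
    """
    n = len(blocks)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            a, b = blocks[i], blocks[j]
            if a.query_chrom != b.query_chrom:
                continue
            small, other = (a, b) if a.anchor_count <= b.anchor_count else (b, a)
            if _mirrored_fraction(small, other) < params.duplication_overlap:
                continue
            disjoint = a.target_chrom != b.target_chrom or interval_gap(
                a.target_start, a.target_end, b.target_start, b.target_end) > 0
            if disjoint:
                parent[find(i)] = find(j)
    comps: Dict[int, List[int]] = {}
    for i in range(n):
        comps.setdefault(find(i), []).append(i)
    return [sorted(c) for c in comps.values() if len(c) >= 2]


def call_rearrangements(
    blocks: Sequence[SyntenyBlock],
    orthology: Dict[str, str],
    params: ChainParams,
) -> List[RearrangementCall]:
    """Classify blocks into rearrangement calls.

    Per block with target span ≥ ``min_span_bp``:
      translocation — the block's query chromosome differs from the
        orthologous partner of its target chromosome;
      inversion — chromosomes agree but the block's orientation opposes the
        pair's anchor-weighted dominant orientation;
      transposition — chromosomes and orientation agree but the block falls
        outside the maximum-weight rank-consistent set of blocks along its
        target chromosome (it has jumped past at least one other block).
    Independently, groups of blocks covering the same query interval at
    disjoint target loci yield one duplication call per group; members of a
    duplication group are exempt from the transposition rule, since the
    displaced copy is explained by the duplication itself. The span filter
    applies only at reporting time, so lowering ``min_span_bp`` can only
    add calls.
    """
    blocks = list(blocks)
    calls: List[RearrangementCall] = []
    dom = dominant_orientations(blocks)

    dup_groups = _duplication_groups(blocks, params)
    dup_members = {i for grp in dup_groups for i in grp}
    for grp in dup_groups:
        grp_blocks = [blocks[i] for i in grp]
        # report at the displaced copy's locus: the smallest-span member
        # (the embedded source copy lives inside the backbone block)
        copy = min(grp_blocks, key=lambda b: (b.target_span, b.target_chrom, b.target_start))
        if copy.target_span >= params.min_span_bp:
            calls.append(_call_from_block("duplication", copy, extra_blocks=grp_blocks))

    # translocations and inversions
    classified: Dict[int, str] = {}
    for i, b in enumerate(blocks):
        expected_q = orthology.get(b.target_chrom)
        if expected_q is not None and b.query_chrom != expected_q:
            classified[i] = "translocation"
        elif b.orientation != dom[(b.query_chrom, b.target_chrom)]:
            classified[i] = "inversion"

    # transpositions: in-place, orientation-consistent blocks displaced
    # relative to their flanking blocks along the target chromosome
    by_pair: Dict[Tuple[str, str], List[int]] = {}
    for i, b in enumerate(blocks):
        if classified.get(i) == "translocation":
            continue
        by_pair.setdefault((b.query_chrom, b.target_chrom), []).append(i)
    for (qc, tc), idxs in sorted(by_pair.items()):
        idxs = sorted(idxs, key=lambda i: blocks[i].target_mid)
        # flanks are drawn from "trusted" backbone blocks only: unclassified,
        # outside duplication groups, and holding a substantial share of the
        # pair's anchors — a displaced segment must not anchor the rank test
        # for its own neighbours
        max_w = max(blocks[i].anchor_count for i in idxs)
        trusted = [i for i in idxs
                   if i not in dup_members and i not in classified
                   and blocks[i].anchor_count >= 0.25 * max_w]
        for pos, i in enumerate(idxs):
            if i in dup_members or i in classified:
                continue
            prev_i = next((j for j in reversed(idxs[:pos]) if j in trusted and j != i), None)
            next_i = next((j for j in idxs[pos + 1:] if j in trusted and j != i), None)
            prev = blocks[prev_i] if prev_i is not None else None
            nxt = blocks[next_i] if next_i is not None else None
            if _is_displaced(blocks[i], prev, nxt, dom[(qc, tc)], params.query_gap):
                classified[i] = "transposition"

    for i in sorted(classified):
        b = blocks[i]
        if b.target_span >= params.min_span_bp:
            calls.append(_call_from_block(classified[i], b))

    calls.sort(key=lambda c: (c.target_chrom, c.target_start, c.kind, c.query_chrom))
    return calls


def _call_from_block(kind: str, b: SyntenyBlock, extra_blocks=None) -> RearrangementCall:
    return RearrangementCall(
        kind=kind,
        query_chrom=b.query_chrom,
        target_chrom=b.target_chrom,
        query_start=b.query_start,
        query_end=b.query_end,
        target_start=b.target_start,
        target_end=b.target_end,
        target_span_bp=b.target_span,
        n_anchors=b.anchor_count,
        orientation=b.orientation,
        blocks=list(extra_blocks) if extra_blocks else [b],
    )


# ---------------------------------------------------------------------------
# dot plots

def dotplot_table(hits: Sequence[AnchorHit],
                  calls: Sequence[RearrangementCall] = ()) -> pd.DataFrame:
    """Tidy table of dot-plot points: one row per anchor with target (x)
    and query (y) midpoints, flagged when covered by a rearrangement call."""
    called = set()
    for c in calls:
        for b in c.blocks:
            for a in b.anchors:
                called.add(id(a))
    rows = []
    for h in hits:
        if h.query_chrom is None or h.query_mid is None:
            continue
        rows.append({
            "target_chrom": h.target_chrom,
            "query_chrom": h.query_chrom,
            "x": h.target_mid,
            "y": h.query_mid,
            "strand": h.strand,
            "in_call": id(h) in called,
        })
    return pd.DataFrame(
        rows, columns=["target_chrom", "query_chrom", "x", "y", "strand", "in_call"]
    )


def dotplot(
    hits: Sequence[AnchorHit],
    out_prefix: str,
    calls: Sequence[RearrangementCall] = (),
    orthology: Optional[Dict[str, str]] = None,
    fmt: str = "png",
) -> Tuple[pd.DataFrame, List[str]]:
    """Write one dot-plot panel per retained chromosome pair (query on the
    vertical axis, target on the horizontal) plus a tidy TSV twin.

    Returns the point table and the list of files written. When an
    orthology map is given, only plurality pairs plus pairs appearing in
    calls are drawn; otherwise every pair with anchors gets a panel.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    table = dotplot_table(hits, calls)
    tsv = f"{out_prefix}points.tsv"
    table.to_csv(tsv, sep="\t", index=False)
    written = [tsv]
    if table.empty:
        return table, written

    if orthology:
        keep_pairs = {(q, t) for t, q in orthology.items()}
        keep_pairs |= {(c.query_chrom, c.target_chrom) for c in calls}
    else:
        keep_pairs = {(q, t) for q, t in zip(table.query_chrom, table.target_chrom)}

    for (qc, tc) in sorted(keep_pairs):
        sub = table[(table.query_chrom == qc) & (table.target_chrom == tc)]
        if sub.empty:
            continue
        fig, ax = plt.subplots(figsize=(4, 4))
        plain = sub[~sub.in_call]
        hot = sub[sub.in_call]
        ax.plot(plain.x / 1e6, plain.y / 1e6, ".", ms=2, color="steelblue")
        if not hot.empty:
            ax.plot(hot.x / 1e6, hot.y / 1e6, ".", ms=3, color="crimson")
        ax.set_xlabel(f"{tc} (Mb)")
        ax.set_ylabel(f"{qc} (Mb)")
        ax.set_title(f"{qc} vs {tc}")
        fig.tight_layout()
        fname = f"{out_prefix}{qc}_{tc}.{fmt}"
        fig.savefig(fname, dpi=120)
        plt.close(fig)
        written.append(fname)
    return table, written
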
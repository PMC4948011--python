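"""Cross-species QTL orthology: trait-aware interval matching and clustering.

Two QTL from different species are candidate orthologues when their
physical confidence intervals lie on the same reference chromosome, within
a proximity window of each other, and their traits are declared related in
an explicit equivalence table (never inferred by string matching — trait
grouping is expert judgment). Co-localized QTL are then merged into
clusters by single-linkage; clusters holding both species are flagged
orthologous, while one-species clusters are first-class results in their
own right (co-localization of several same-trait QTL with no counterpart).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Sequence, Set, Tuple

import yaml
from intervaltree import IntervalTree

from .model import OrthologyCluster, PhysicalQTL, interval_gap

log = logging.getLogger(__name__)


class TraitEquivalence:
    """Symmetric relation over trait names.

    Built from a mapping ``trait -> [related traits]``; the symmetric
    closure is applied at load time and every trait relates to itself.
    """

    def __init__(self, mapping: Dict[str, Iterable[str]]):
        self._rel: Dict[str, Set[str]] = {}
        for a, bs in mapping.items():
            self._rel.setdefault(a, set()).add(a)
            for b in bs:
                self._rel.setdefault(a, set()).add(b)
                self._rel.setdefault(b, set()).add(b)
                self._rel[b].add(a)

    @classmethod
    def from_yaml(cls, path) -> "TraitEquivalence":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls({str(k): [str(v) for v in vs or []] for k, vs in raw.items()})

    def known(self, trait: str) -> bool:
        return trait in self._rel

    def related(self, a: str, b: str) -> bool:
        if a == b:
            return True
        return b in self._rel.get(a, ())


def filter_major(qtls: Sequence[PhysicalQTL], threshold: float = 10.0) -> List[PhysicalQTL]:
    """Keep major QTL: percentage of variance explained ≥ threshold (inclusive)."""
    return [q for q in qtls if q.pve >= threshold]


@dataclass
class PairingReport:
    pairs: List[Tuple[PhysicalQTL, PhysicalQTL]] = field(default_factory=list)
    n_skipped_unknown_trait: int = 0


def find_orthologous_pairs(
    qtls_a: Sequence[PhysicalQTL],
    qtls_b: Sequence[PhysicalQTL],
    traits: TraitEquivalence,
    proximity_bp: int = 1_000_000,
) -> PairingReport:
    """Emit (A, B) pairs of same-chromosome, trait-related QTL whose
    intervals overlap or lie within ``proximity_bp`` of each other.

    QTL whose trait is absent from the equivalence table are skipped with a
    warning and counted. Output order is deterministic: by chromosome, then
    A start, then B start.
    """
    report = PairingReport()

    def usable(qtls):
        kept = []
        for q in qtls:
            if not traits.known(q.trait):
                log.warning("QTL %s: trait %r not in equivalence table; skipped",
                            q.qtl_id, q.trait)
                report.n_skipped_unknown_trait += 1
            else:
                kept.append(q)
        return kept

    a_use, b_use = usable(qtls_a), usable(qtls_b)
    trees: Dict[str, IntervalTree] = {}
    for q in b_use:
        # pad the B interval by the proximity window so a stabbing query
        # retrieves every candidate within the gap limit
        trees.setdefault(q.chrom, IntervalTree()).addi(
            q.start_bp - proximity_bp, q.end_bp + proximity_bp + 1, q)
    for qa in a_use:
        tree = trees.get(qa.chrom)
        if tree is None:
            continue
        for iv in tree.overlap(qa.start_bp, qa.end_bp + 1):
            qb = iv.data
            if not traits.related(qa.trait, qb.trait):
                continue
            if interval_gap(qa.start_bp, qa.end_bp, qb.start_bp, qb.end_bp) <= proximity_bp:
                report.pairs.append((qa, qb))
    report.pairs.sort(key=lambda p: (p[0].chrom, p[0].start_bp, p[1].start_bp,
                                     p[0].qtl_id, p[1].qtl_id))
    return report


def cluster_qtl(
    qtls_a: Sequence[PhysicalQTL],
    qtls_b: Sequence[PhysicalQTL],
    merge_gap_bp: int = 1_000_000,
) -> List[OrthologyCluster]:
    """Single-linkage merge of physical QTL intervals from both species.

    Intervals on one chromosome separated by at most ``merge_gap_bp`` join
    the same cluster (connected components of the proximity graph, realized
    by a coordinate sweep). Each cluster's interval is the hull of its
    members; clusters containing both species are ``orthologous``, while
    one-species clusters are retained and flagged.
    """
    tagged = [(q, "a") for q in qtls_a] + [(q, "b") for q in qtls_b]
    tagged.sort(key=lambda t: (t[0].chrom, t[0].start_bp, t[0].end_bp, t[0].qtl_id))
    clusters: List[OrthologyCluster] = []
    cur: List[Tuple[PhysicalQTL, str]] = []
    cur_end = None
    cur_chrom = None

    def flush():
        if not cur:
            return
        cid = f"cluster{len(clusters) + 1:03d}"
        clusters.append(
            OrthologyCluster(
                cluster_id=cid,
                chrom=cur_chrom,
                start_bp=min(q.start_bp for q, _ in cur),
                end_bp=max(q.end_bp for q, _ in cur),
                members_a=[q for q, s in cur if s == "a"],
                members_b=[q for q, s in cur if s == "b"],
            )
        )

    for q, s in tagged:
        if cur and q.chrom == cur_chrom and q.start_bp - cur_end <= merge_gap_bp:
            cur.append((q, s))
            cur_end = max(cur_end, q.end_bp)
        else:
            flush()
            cur = [(q, s)]
            cur_end = q.end_bp
            cur_chrom = q.chrom
    flush()
    return clusters


def clusters_table(clusters: Sequence[OrthologyCluster]):
    """Tidy per-cluster table (chrom, interval, members per species, traits)."""
    import pandas as pd

    rows = []
    for c in clusters:
        rows.append({
            "cluster_id": c.cluster_id,
            "chrom": c.chrom,
            "start_bp": c.start_bp,
            "end_bp": c.end_bp,
            "orthologous": c.orthologous,
            "n_members_a": len(c.members_a),
            "n_members_b": len(c.members_b),
            "members_a": ";".join(q.qtl_id for q in c.members_a),
            "members_b": ";".join(q.qtl_id for q in c.members_b),
            "traits": ";".join(sorted(c.trait_classes)),
        })
    return pd.DataFrame(rows, columns=[
        "cluster_id", "chrom", "start_bp", "end_bp", "orthologous",
        "n_members_a", "n_members_b", "members_a", "members_b", "traits",
    ])
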
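"""Ground-truth synthetic data: genome pairs, genetic maps and QTL.

The generator emulates the inputs of a Solanaceae-style comparative
analysis without any sequence data: anchors are coordinate objects
(mimicking filtered GMAP/BLAST hits of CDS or markers), placed uniformly on
a 12-chromosome query genome and carried to the target genome through a
known history of inversions, reciprocal arm translocations, transpositions
and segmental duplications. Noise layers (spurious hits, missing anchors,
paralogous extra hits, positional jitter, low-quality contaminant
alignments) are applied after the events. Genetic maps use a monotone
cM→bp function per linkage group — linear, or sigmoid to mimic centromeric
recombination suppression — with markers on a regular cM grid and QTL whose
true physical intervals are recorded.

All randomness flows from a single seed through one named
``numpy.random.Generator``; no global state is touched.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .model import AnchorHit, GeneticMapMarker, MarkerAnchor, PhysicalQTL, QTLRecord


# ---------------------------------------------------------------------------
# configuration

@dataclass(frozen=True)
class NoiseConfig:
    """Post-event corruption rates.

    Defaults are the generator's documented operating point: 5% spurious
    uniform hits, 5% randomly missing anchors, 1% paralogous extra hits,
    ±5 kb positional jitter, and 5% of anchors carrying sub-threshold
    alignment quality so that hit filtering has real work to do.
    """

    spurious_hit_rate: float = 0.05
    missing_anchor_rate: float = 0.05
    paralog_rate: float = 0.01
    positional_jitter_bp: int = 5_000
    low_quality_rate: float = 0.05

    @classmethod
    def none(cls) -> "NoiseConfig":
        return cls(0.0, 0.0, 0.0, 0, 0.0)


@dataclass(frozen=True)
class MapConfig:
    markers_per_lg: int = 51
    cM_length: float = 100.0
    rate_function: str = "linear"  # linear | sigmoid


@dataclass(frozen=True)
class QTLConfig:
    count: int = 20
    ci_width_cM: Tuple[float, float] = (4.0, 12.0)
    pve_range: Tuple[float, float] = (2.0, 25.0)
    fraction_orthologous: float = 0.5


@dataclass(frozen=True)
class SimConfig:
    """Genome-pair simulation parameters.

    Twelve 50 Mb chromosomes with 400 anchors each give an inter-anchor
    spacing of ~125 kb, so rearrangements of 0.6–2.5 Mb contain a handful
    of anchors — the same order of anchor density per event as a
    ~20k-anchor, ~3 Gb genome comparison.
    """

    n_chrom: int = 12
    chrom_length_bp: int = 50_000_000
    anchors_per_chrom: int = 400
    n_inversions: int = 4
    n_translocations: int = 2
    n_transpositions: int = 1
    n_duplications: int = 1
    min_event_span_bp: int = 600_000
    max_event_span_bp: int = 2_500_000
    min_anchors_per_event: int = 4
    event_displacement_bp: int = 8_000_000  # transposition/duplication jump distance
    noise: NoiseConfig = field(default_factory=NoiseConfig)
    map: MapConfig = field(default_factory=MapConfig)
    qtl: QTLConfig = field(default_factory=QTLConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        used = self.n_inversions + self.n_transpositions + self.n_duplications \
            + 2 * self.n_translocations
        if used > self.n_chrom:
            raise ValueError(
                f"{used} event chromosomes requested but only {self.n_chrom} available "
                "(each chromosome hosts at most one event)")
        if self.max_event_span_bp >= self.chrom_length_bp // 4:
            raise ValueError("event span too large for chromosome length")


# ---------------------------------------------------------------------------
# truth records

@dataclass(frozen=True)
class TruthSignature:
    """One detectable footprint of a planted event on the target genome."""

    kind: str
    target_chrom: str
    start: int
    end: int


@dataclass(frozen=True)
class PlannedEvent:
    kind: str
    chroms: Tuple[str, ...]
    signatures: Tuple[TruthSignature, ...]


@dataclass
class RearrangementHistory:
    events: List[PlannedEvent] = field(default_factory=list)

    @property
    def signatures(self) -> List[TruthSignature]:
        return [s for e in self.events for s in e.signatures]


@dataclass
class GenomePairSim:
    hits: List[AnchorHit]
    truth: RearrangementHistory
    chrom_lengths: Dict[str, int]
    n_placed: int = 0
    n_deleted: int = 0
    n_paralog_copies: int = 0
    n_spurious: int = 0


# internal mutable anchor record used while events are applied
@dataclass
class _Anc:
    query_id: str
    q_chrom: str
    q_start: int
    q_end: int
    t_chrom: str
    t_start: int
    t_end: int
    strand: str = "+"


def _qname(i: int) -> str:
    return f"Q{i + 1:02d}"


def _tname(i: int) -> str:
    return f"T{i + 1:02d}"


# ---------------------------------------------------------------------------
# event geometry (pure coordinate transforms, individually testable)

def apply_inversion(anchors: Sequence[_Anc], chrom: str, start: int, end: int) -> None:
    """Reflect target coordinates inside [start, end) and flip strands.

    An involution: applying it twice restores the original coordinates.
    """
    for a in anchors:
        if a.t_chrom == chrom and a.t_start >= start and a.t_end <= end:
            ns = start + (end - a.t_end)
            ne = start + (end - a.t_start)
            a.t_start, a.t_end = ns, ne
            a.strand = "-" if a.strand == "+" else "+"


def apply_transposition(anchors: Sequence[_Anc], chrom: str, start: int, end: int,
                        dest: int) -> Tuple[int, int]:
    """Cut [start, end) out and reinsert it at ``dest``; returns the final
    interval occupied by the moved segment."""
    length = end - start
    if start < dest < end:
        raise ValueError("destination inside the moved segment")
    for a in anchors:
        if a.t_chrom != chrom:
            continue
        if start <= a.t_start and a.t_end <= end:
            shift = (dest - end) if dest > end else (dest - start)
            a.t_start += shift
            a.t_end += shift
        elif dest > end and end <= a.t_start and a.t_end <= dest:
            a.t_start -= length
            a.t_end -= length
        elif dest < start and dest <= a.t_start and a.t_end <= start:
            a.t_start += length
            a.t_end += length
    return (dest - length, dest) if dest > end else (dest, dest + length)


def apply_translocation(anchors: Sequence[_Anc], chrom1: str, bp1: int,
                        chrom2: str, bp2: int) -> None:
    """Reciprocal exchange of the distal segments beyond bp1/bp2."""
    for a in anchors:
        if a.t_chrom == chrom1 and a.t_start >= bp1:
            a.t_chrom = chrom2
            a.t_start = bp2 + (a.t_start - bp1)
            a.t_end = bp2 + (a.t_end - bp1)
        elif a.t_chrom == chrom2 and a.t_start >= bp2:
            a.t_chrom = chrom1
            a.t_start = bp1 + (a.t_start - bp2)
            a.t_end = bp1 + (a.t_end - bp2)


def apply_duplication(anchors: List[_Anc], chrom: str, start: int, end: int,
                      dest: int) -> List[_Anc]:
    """Insert a copy of [start, end) at ``dest`` (same chromosome); anchors
    downstream of the insertion shift right. Returns the new copy anchors,
    which carry distinct query ids but the same query interval (distinct
    query genes from one region matching both target copies)."""
    length = end - start
    segment = [a for a in anchors
               if a.t_chrom == chrom and start <= a.t_start and a.t_end <= end]
    copies = []
    for a in anchors:
        if a.t_chrom == chrom and a.t_start >= dest:
            a.t_start += length
            a.t_end += length
    for a in segment:
        copies.append(_Anc(
            query_id=a.query_id + "_dup",
            q_chrom=a.q_chrom, q_start=a.q_start, q_end=a.q_end,
            t_chrom=chrom,
            t_start=dest + (a.t_start - start),
            t_end=dest + (a.t_end - start),
            strand=a.strand,
        ))
    anchors.extend(copies)
    return copies


# ---------------------------------------------------------------------------
# genome-pair simulation

def _pick_event_window(rng: np.random.Generator, starts: np.ndarray, ends: np.ndarray,
                       cfg: SimConfig, lo_frac: float = 0.1, hi_frac: float = 0.9
                       ) -> Tuple[int, int, int, int]:
    """Choose a run of consecutive anchors whose hull spans between the
    configured event-span bounds, and return (first_idx, last_idx,
    interval_start, interval_end) with interval endpoints placed in the
    anchor gaps so no anchor straddles an event boundary."""
    n = len(starts)
    for _ in range(200):
        j = int(rng.integers(int(lo_frac * n), int(hi_frac * n)))
        k = j
        while k + 1 < n and (
            ends[k] - starts[j] < cfg.min_event_span_bp
            or k - j + 1 < cfg.min_anchors_per_event
        ):
            k += 1
        if k + 1 >= n:
            continue
        hull = ends[k] - starts[j]
        if hull > cfg.max_event_span_bp:
            continue
        s = int((ends[j - 1] + starts[j]) // 2) if j > 0 else max(0, int(starts[j]) - 1000)
        e = int((ends[k] + starts[k + 1]) // 2)
        return j, k, s, e
    raise RuntimeError("could not place an event window; anchors too sparse "
                       "for the configured event span")


def _gap_point(rng: np.random.Generator, starts: np.ndarray, ends: np.ndarray,
               lo: int, hi: int) -> int:
    """A point inside an anchor gap within [lo, hi]."""
    mids = (ends[:-1] + starts[1:]) // 2
    ok = mids[(mids >= lo) & (mids <= hi)]
    if len(ok) == 0:
        raise RuntimeError("no anchor gap available in the requested range")
    return int(ok[int(rng.integers(len(ok)))])


def simulate_genome_pair(config: SimConfig) -> GenomePairSim:
    """Generate anchor hits between a query genome and a rearranged target.

    Anchors are placed uniformly per query chromosome; the planted event
    history is applied to the target copies; noise is layered on last. The
    output reconciles exactly: ``len(hits) = n_placed − n_deleted +
    n_paralog_copies + n_spurious`` (``n_placed`` includes duplication
    copies). Fully reproducible from ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    L = config.chrom_length_bp
    anchors: List[_Anc] = []
    per_chrom: Dict[str, List[_Anc]] = {}
    for ci in range(config.n_chrom):
        n = config.anchors_per_chrom
        lengths = rng.integers(500, 3000, size=n)
        starts = np.sort(rng.integers(10_000, L - 10_000, size=n))
        # enforce disjoint anchors so event boundaries always fall in gaps
        for i in range(1, n):
            starts[i] = max(starts[i], starts[i - 1] + lengths[i - 1] + 100)
        chrom_anchors = []
        for i in range(n):
            a = _Anc(
                query_id=f"g{ci + 1:02d}_{i:04d}",
                q_chrom=_qname(ci), q_start=int(starts[i]),
                q_end=int(starts[i] + lengths[i]),
                t_chrom=_tname(ci), t_start=int(starts[i]),
                t_end=int(starts[i] + lengths[i]),
            )
            chrom_anchors.append(a)
        anchors.extend(chrom_anchors)
        per_chrom[_tname(ci)] = chrom_anchors

    chrom_lengths = {_tname(ci): L for ci in range(config.n_chrom)}

    # assign each event its own chromosome(s)
    order = rng.permutation(config.n_chrom)
    cursor = 0

    def next_chrom() -> int:
        nonlocal cursor
        ci = int(order[cursor])
        cursor += 1
        return ci

    history = RearrangementHistory()

    for _ in range(config.n_inversions):
        ci = next_chrom()
        tc = _tname(ci)
        ca = per_chrom[tc]
        st = np.array([a.t_start for a in ca]); en = np.array([a.t_end for a in ca])
        j, k, s, e = _pick_event_window(rng, st, en, config)
        apply_inversion(anchors, tc, s, e)
        history.events.append(PlannedEvent(
            "inversion", (tc,), (TruthSignature("inversion", tc, s, e),)))

    for _ in range(config.n_transpositions):
        ci = next_chrom()
        tc = _tname(ci)
        ca = per_chrom[tc]
        st = np.array([a.t_start for a in ca]); en = np.array([a.t_end for a in ca])
        j, k, s, e = _pick_event_window(rng, st, en, config, lo_frac=0.05, hi_frac=0.5)
        dest = _gap_point(rng, st, en, e + config.event_displacement_bp,
                          L - config.max_event_span_bp)
        fs, fe = apply_transposition(anchors, tc, s, e, dest)
        history.events.append(PlannedEvent(
            "transposition", (tc,), (TruthSignature("transposition", tc, fs, fe),)))

    for _ in range(config.n_duplications):
        ci = next_chrom()
        tc = _tname(ci)
        ca = per_chrom[tc]
        st = np.array([a.t_start for a in ca]); en = np.array([a.t_end for a in ca])
        j, k, s, e = _pick_event_window(rng, st, en, config, lo_frac=0.05, hi_frac=0.5)
        dest = _gap_point(rng, st, en, e + config.event_displacement_bp,
                          L - config.max_event_span_bp)
        apply_duplication(anchors, tc, s, e, dest)
        chrom_lengths[tc] += e - s
        history.events.append(PlannedEvent(
            "duplication", (tc,), (TruthSignature("duplication", tc, dest, dest + (e - s)),)))

    for _ in range(config.n_translocations):
        c1, c2 = next_chrom(), next_chrom()
        t1, t2 = _tname(c1), _tname(c2)
        bps = []
        for tc in (t1, t2):
            ca = per_chrom[tc]
            st = np.array([a.t_start for a in ca]); en = np.array([a.t_end for a in ca])
            frac = rng.uniform(0.55, 0.75)
            bps.append(_gap_point(rng, st, en, int(frac * L), int((frac + 0.1) * L)))
        b1, b2 = bps
        apply_translocation(anchors, t1, b1, t2, b2)
        chrom_lengths[t1], chrom_lengths[t2] = b1 + (L - b2), b2 + (L - b1)
        history.events.append(PlannedEvent(
            "translocation", (t1, t2),
            (TruthSignature("translocation", t1, b1, b1 + (L - b2)),
             TruthSignature("translocation", t2, b2, b2 + (L - b1))),
        ))

    n_placed = len(anchors)

    # --- noise ---
    noise = config.noise
    kept: List[_Anc] = []
    n_deleted = 0
    for a in anchors:
        if noise.missing_anchor_rate > 0 and rng.random() < noise.missing_anchor_rate:
            n_deleted += 1
            continue
        kept.append(a)

    paralogs: List[_Anc] = []
    if noise.paralog_rate > 0:
        for a in kept:
            if rng.random() < noise.paralog_rate:
                ci = int(rng.integers(config.n_chrom))
                pos = int(rng.integers(10_000, L - 10_000))
                paralogs.append(replace(
                    a, t_chrom=_tname(ci), t_start=pos,
                    t_end=pos + (a.t_end - a.t_start)))

    spurious: List[_Anc] = []
    n_spur = rng.binomial(n_placed, noise.spurious_hit_rate) if noise.spurious_hit_rate else 0
    for i in range(int(n_spur)):
        qi, ti = int(rng.integers(config.n_chrom)), int(rng.integers(config.n_chrom))
        qp = int(rng.integers(10_000, L - 10_000))
        tp = int(rng.integers(10_000, L - 10_000))
        ln = int(rng.integers(300, 1500))
        spurious.append(_Anc(
            query_id=f"spur_{i:05d}", q_chrom=_qname(qi), q_start=qp, q_end=qp + ln,
            t_chrom=_tname(ti), t_start=tp, t_end=tp + ln,
            strand="+" if rng.random() < 0.5 else "-"))

    final = kept + paralogs + spurious
    if noise.positional_jitter_bp > 0:
        j = noise.positional_jitter_bp
        for a in final:
            dt = max(int(rng.integers(-j, j + 1)), -a.t_start)
            dq = max(int(rng.integers(-j, j + 1)), -a.q_start)
            a.t_start += dt
            a.t_end += dt
            a.q_start += dq
            a.q_end += dq

    # --- alignment-quality metrics ---
    paralog_ids = {id(a) for a in paralogs}
    hits: List[AnchorHit] = []
    for a in final:
        length = a.t_end - a.t_start
        if noise.low_quality_rate > 0 and rng.random() < noise.low_quality_rate:
            identity = float(rng.uniform(0.40, 0.78))
            coverage = float(rng.uniform(0.20, 0.70))
        else:
            identity = float(rng.uniform(0.82, 0.995))
            coverage = float(rng.uniform(0.76, 1.0))
        if id(a) in paralog_ids:
            identity = max(0.40, identity - 0.05)  # the true locus always outranks
        match = int(round(identity * length))
        hits.append(AnchorHit(
            query_id=a.query_id, query_chrom=a.q_chrom,
            query_start=float(a.q_start), query_end=float(a.q_end),
            target_chrom=a.t_chrom, target_start=a.t_start, target_end=a.t_end,
            strand=a.strand, identity=identity, coverage=coverage,
            aligned_length=length, match_bp=match, mismatch_bp=length - match,
        ))

    return GenomePairSim(
        hits=hits, truth=history, chrom_lengths=chrom_lengths,
        n_placed=n_placed, n_deleted=n_deleted,
        n_paralog_copies=len(paralogs), n_spurious=len(spurious),
    )


def random_history_config(seed: int, noise: Optional[NoiseConfig] = None,
                          **overrides) -> SimConfig:
    """A randomized 3–8 event history for benchmark sweeps: event counts are
    drawn from the seed, then the same seed drives the simulation."""
    rng = np.random.default_rng(seed)
    n_trl = int(rng.integers(1, 3))
    remaining_chroms = 12 - 2 * n_trl
    n_inv = int(rng.integers(1, 5))
    n_trp = int(rng.integers(0, 2))
    n_dup = int(rng.integers(0, 2))
    # keep totals in the 3..8 range and within the chromosome budget
    while n_inv + n_trp + n_dup > remaining_chroms or n_inv + n_trp + n_dup + n_trl > 8:
        n_inv -= 1
    while n_inv + n_trp + n_dup + n_trl < 3:
        n_inv += 1
    cfg = dict(
        n_inversions=n_inv, n_translocations=n_trl,
        n_transpositions=n_trp, n_duplications=n_dup,
        seed=seed,
    )
    if noise is not None:
        cfg["noise"] = noise
    cfg.update(overrides)
    return SimConfig(**cfg)


def score_calls(calls, truth: RearrangementHistory) -> Dict[str, float]:
    """Precision/recall of rearrangement calls against planted signatures.

    A call matches a signature when kinds agree, target chromosomes agree
    and target intervals overlap. A signature found by several calls (e.g.
    an inversion split into two blocks by noise) counts once for recall;
    each of those calls is a true positive for precision.
    """
    sigs = truth.signatures
    matched_sigs = set()
    n_true_calls = 0
    for c in calls:
        hit_any = False
        for i, s in enumerate(sigs):
            if (c.kind == s.kind and c.target_chrom == s.target_chrom
                    and c.target_start < s.end and s.start < c.target_end):
                matched_sigs.add(i)
                hit_any = True
        if hit_any:
            n_true_calls += 1
    precision = n_true_calls / len(calls) if calls else 1.0
    recall = len(matched_sigs) / len(sigs) if sigs else 1.0
    return {"precision": precision, "recall": recall,
            "n_calls": len(calls), "n_truth": len(sigs)}


# ---------------------------------------------------------------------------
# genetic maps and QTL

def _cm_to_bp_function(rate_function: str, chrom_len: int, cm_len: float):
    if rate_function == "linear":
        return lambda c: chrom_len * (np.asarray(c, dtype=float) / cm_len)
    if rate_function == "sigmoid":
        k = 8.0

        def g(c):
            return 1.0 / (1.0 + np.exp(-k * (np.asarray(c, dtype=float) / cm_len - 0.5)))

        g0, g1 = g(0.0), g(cm_len)
        return lambda c: chrom_len * (g(c) - g0) / (g1 - g0)
    raise ValueError(f"unknown rate function {rate_function!r}")


@dataclass
class MapSim:
    markers: List[GeneticMapMarker]
    anchors: List[MarkerAnchor]
    qtls: List[QTLRecord]
    truth: List[PhysicalQTL]            # true physical intervals of `qtls`
    other_species_qtls: List[PhysicalQTL]
    trait_map: Dict[str, List[str]]     # equivalence table for the two species


def simulate_map_and_qtl(config: SimConfig) -> MapSim:
    """Generate genetic maps with anchored markers and QTL with known
    physical truth, plus a second species' physical QTL set of which
    ``fraction_orthologous`` co-localize with the first species' loci under
    related traits.

    Per-environment CIs are produced in symmetric pairs around the true CI,
    so their element-wise mean reproduces it exactly.
    """
    rng = np.random.default_rng(config.seed + 1)
    mc, qc = config.map, config.qtl
    L, C = config.chrom_length_bp, mc.cM_length
    markers: List[GeneticMapMarker] = []
    anchors: List[MarkerAnchor] = []
    funcs = {}
    for ci in range(config.n_chrom):
        lg = f"E{ci + 1:02d}"
        chrom = f"P{ci + 1:02d}"
        f = _cm_to_bp_function(mc.rate_function, L, C)
        funcs[lg] = (chrom, f)
        grid = np.linspace(0.0, C, mc.markers_per_lg)
        for mi, cm in enumerate(grid):
            mid = f"{lg}_m{mi:03d}"
            markers.append(GeneticMapMarker(mid, lg, float(cm)))
            anchors.append(MarkerAnchor(mid, lg, float(cm), chrom, int(round(float(f(cm))))))

    trait_pool = [f"trait{k:02d}" for k in range(max(8, qc.count // 2))]
    trait_map = {f"{t}_a": [f"{t}_b"] for t in trait_pool}

    qtls: List[QTLRecord] = []
    truth: List[PhysicalQTL] = []
    others: List[PhysicalQTL] = []
    n_orth = int(round(qc.fraction_orthologous * qc.count))
    for qi in range(qc.count):
        ci = int(rng.integers(config.n_chrom))
        lg = f"E{ci + 1:02d}"
        chrom, f = funcs[lg]
        w = float(rng.uniform(*qc.ci_width_cM))
        peak = float(rng.uniform(0.15 * C, 0.85 * C))
        lo = max(0.0, peak - w * float(rng.uniform(0.3, 0.7)))
        hi = min(C, lo + w)
        peak = min(max(peak, lo), hi)
        pve = float(rng.uniform(*qc.pve_range))
        trait = trait_pool[int(rng.integers(len(trait_pool)))]
        d_lo, d_hi = float(rng.uniform(0, 1.5)), float(rng.uniform(0, 1.5))
        env = ((lo - d_lo, hi - d_hi), (lo + d_lo, hi + d_hi))
        qtls.append(QTLRecord(
            qtl_id=f"egg_q{qi:03d}", trait=f"{trait}_a", linkage_group=lg,
            peak_cM=peak, ci_lo_cM=lo, ci_hi_cM=hi, pve=pve,
            per_environment_cis=env))
        t_lo, t_peak, t_hi = (int(round(float(f(x)))) for x in (lo, peak, hi))
        truth.append(PhysicalQTL(
            qtl_id=f"egg_q{qi:03d}", trait=f"{trait}_a", species="eggplant",
            chrom=chrom, start_bp=t_lo, end_bp=t_hi, peak_bp=t_peak, pve=pve))
        if qi < n_orth:
            shift = int(rng.integers(-200_000, 200_001))
            start = max(0, t_lo + shift)
            end = max(start + 50_000, t_hi + shift)
            pk = min(max(t_peak + shift, start), end)
            others.append(PhysicalQTL(
                qtl_id=f"pep_q{qi:03d}", trait=f"{trait}_b", species="pepper",
                chrom=chrom, start_bp=start, end_bp=end, peak_bp=pk,
                pve=float(rng.uniform(10.0, 30.0))))
    return MapSim(markers, anchors, qtls, truth, others, trait_map)


# ---------------------------------------------------------------------------
# planted QTL-cluster scenario

@dataclass
class ClusterSim:
    qtls_a: List[PhysicalQTL]
    qtls_b: List[PhysicalQTL]
    trait_map: Dict[str, List[str]]
    truth_two_species: int
    truth_one_species: int
    assignments: Dict[str, int]  # qtl_id -> planted cluster index


def simulate_qtl_clusters(
    n_two_species: int = 8,
    n_one_species: int = 6,
    seed: int = 0,
    n_chrom: int = 12,
    chrom_length_bp: int = 260_000_000,
    cluster_spacing_bp: int = 40_000_000,
    member_width_bp: Tuple[int, int] = (500_000, 2_000_000),
) -> ClusterSim:
    """Plant co-localized QTL clusters on a reference genome: a configurable
    number with members from both species and a remainder carried by one
    species only (the default 8-vs-6 split mirrors the structure commonly
    seen in cross-species QTL screens). Cluster centres are spaced far
    enough apart that single-linkage merging cannot fuse them."""
    rng = np.random.default_rng(seed)
    total = n_two_species + n_one_species
    qtls_a: List[PhysicalQTL] = []
    qtls_b: List[PhysicalQTL] = []
    assignments: Dict[str, int] = {}
    trait_map: Dict[str, List[str]] = {}
    kinds = ["both"] * n_two_species + ["single"] * n_one_species
    for k, kind in enumerate(kinds):
        chrom = f"P{(k % n_chrom) + 1:02d}"
        slot = k // n_chrom
        center = 20_000_000 + slot * cluster_spacing_bp \
            + int(rng.integers(0, 5_000_000))
        trait = f"class{k:02d}"
        trait_map[f"{trait}_egg"] = [f"{trait}_pep"]

        def member(species: str, idx: int) -> PhysicalQTL:
            w = int(rng.integers(*member_width_bp))
            off = int(rng.integers(-300_000, 300_001))
            start = max(0, center + off - w // 2)
            end = start + w
            peak = int(rng.integers(start, end + 1))
            suffix = "egg" if species == "eggplant" else "pep"
            qid = f"{suffix}_c{k:02d}_{idx}"
            assignments[qid] = k
            return PhysicalQTL(
                qtl_id=qid, trait=f"{trait}_{suffix}", species=species,
                chrom=chrom, start_bp=start, end_bp=end, peak_bp=peak,
                pve=float(rng.uniform(10.0, 30.0)))

        n_a = int(rng.integers(1, 4)) if kind == "both" else int(rng.integers(2, 4))
        for i in range(n_a):
            qtls_a.append(member("eggplant", i))
        if kind == "both":
            for i in range(int(rng.integers(1, 3))):
                qtls_b.append(member("pepper", i))
    return ClusterSim(qtls_a, qtls_b, trait_map, n_two_species, n_one_species, assignments)
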
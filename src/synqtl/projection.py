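"""Genetic-to-physical projection of map positions and QTL intervals.

The conversion rate between a genetic map and a physical genome is the
local ratio Δbp/ΔcM between neighbouring anchored markers. A QTL peak is
interpolated between its flanking anchors, and the physical confidence
interval is obtained by multiplying the LOD interval width in cM by that
local rate (``local_rate`` mode, the default), or by interpolating each of
the peak and the two interval bounds through the full monotone anchor
scaffold (``piecewise`` mode, more faithful when recombination rate varies
across a wide interval).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .model import MarkerAnchor, PhysicalQTL, QTLRecord

#: reasons a QTL cannot be projected
TOO_FEW_ANCHORS = "too-few-anchors"
NO_LINKAGE_GROUP = "no-anchors-on-linkage-group"


class ProjectionError(ValueError):
    pass


def local_rate(a: MarkerAnchor, b: MarkerAnchor) -> float:
    """bp per cM between two neighbouring anchored markers: |Δbp| / ΔcM."""
    if a.linkage_group != b.linkage_group:
        raise ProjectionError(
            f"{a.marker_id}/{b.marker_id}: different linkage groups")
    if a.target_chrom != b.target_chrom:
        raise ProjectionError(
            f"{a.marker_id}/{b.marker_id}: different target chromosomes "
            "(pair spans a rearrangement)")
    dcm = abs(b.cM - a.cM)
    if dcm == 0:
        raise ProjectionError(
            f"{a.marker_id}/{b.marker_id}: co-segregating pair (ΔcM = 0)")
    return abs(b.target_bp - a.target_bp) / dcm


def average_environment_ci(qtl: QTLRecord) -> Tuple[float, float]:
    """Element-wise mean of per-environment confidence intervals.

    With a single environment that interval is returned unchanged; with no
    per-environment intervals the QTL's own (ci_lo, ci_hi) is the fallback.
    """
    cis = qtl.per_environment_cis
    if not cis:
        return (qtl.ci_lo_cM, qtl.ci_hi_cM)
    lo = sum(c[0] for c in cis) / len(cis)
    hi = sum(c[1] for c in cis) / len(cis)
    return (lo, hi)


@dataclass
class Scaffold:
    """A monotone cM→bp interpolation scaffold for one linkage group."""

    linkage_group: str
    target_chrom: str
    cM: np.ndarray                     # strictly increasing
    bp: np.ndarray                     # monotone (increasing or decreasing)
    excluded: List[MarkerAnchor] = field(default_factory=list)

    @property
    def reversed(self) -> bool:
        return bool(len(self.bp) >= 2 and self.bp[-1] < self.bp[0])


def build_scaffold(anchors: Sequence[MarkerAnchor], linkage_group: str) -> Optional[Scaffold]:
    """Assemble the usable anchor scaffold for one linkage group.

    Anchors whose target chromosome disagrees with the linkage group's
    majority chromosome lie on translocated segments and are excluded (and
    reported). Co-segregating duplicate cM positions keep only the first
    anchor. Residual non-monotone placements (local inversions) are
    resolved by keeping the longest monotone subsequence in the dominant
    direction, so the interpolant stays a function.
    """
    lg = [a for a in anchors if a.linkage_group == linkage_group]
    if not lg:
        return None
    chrom_counts: Dict[str, int] = {}
    for a in lg:
        chrom_counts[a.target_chrom] = chrom_counts.get(a.target_chrom, 0) + 1
    majority = sorted(chrom_counts, key=lambda c: (-chrom_counts[c], c))[0]
    excluded = [a for a in lg if a.target_chrom != majority]
    kept = sorted((a for a in lg if a.target_chrom == majority),
                  key=lambda a: (a.cM, a.target_bp, a.marker_id))
    uniq: List[MarkerAnchor] = []
    for a in kept:
        if uniq and a.cM == uniq[-1].cM:
            excluded.append(a)
            continue
        uniq.append(a)
    if len(uniq) < 2:
        return Scaffold(linkage_group, majority,
                        np.array([a.cM for a in uniq]),
                        np.array([float(a.target_bp) for a in uniq]), excluded)
    bp = [a.target_bp for a in uniq]
    increasing = _dominant_direction(bp)
    keep_idx = _longest_monotone(bp, increasing)
    excluded.extend(a for i, a in enumerate(uniq) if i not in keep_idx)
    sel = [uniq[i] for i in sorted(keep_idx)]
    return Scaffold(
        linkage_group, majority,
        np.array([a.cM for a in sel], dtype=float),
        np.array([float(a.target_bp) for a in sel], dtype=float),
        excluded,
    )


def _dominant_direction(bp: Sequence[float]) -> bool:
    diffs = np.diff(np.asarray(bp, dtype=float))
    return bool(np.sum(diffs > 0) >= np.sum(diffs < 0))


def _longest_monotone(values: Sequence[float], increasing: bool) -> set:
    v = list(values) if increasing else [-x for x in values]
    n = len(v)
    best = [1] * n
    prev = [-1] * n
    for i in range(n):
        for j in range(i):
            if v[j] <= v[i] and best[j] + 1 > best[i]:
                best[i] = best[j] + 1
                prev[i] = j
    i = max(range(n), key=lambda k: (best[k], -k))
    keep = set()
    while i != -1:
        keep.add(i)
        i = prev[i]
    return keep


@dataclass
class ProjectionResult:
    qtl_id: str
    physical: Optional[PhysicalQTL]
    extrapolated: bool = False
    reason: Optional[str] = None
    excluded_anchors: List[MarkerAnchor] = field(default_factory=list)


def project_position(scaffold: Scaffold, cM: float, mode: str = "piecewise") -> Tuple[float, bool]:
    """Project one cM position through the scaffold.

    Returns (bp, extrapolated). ``piecewise`` interpolates through every
    scaffold segment; ``local_rate`` uses only the segment containing (or,
    outside the anchored range, nearest to) the position. At anchor
    positions both modes return the anchor's own bp exactly.
    """
    cms, bps = scaffold.cM, scaffold.bp
    if len(cms) < 2:
        raise ProjectionError("scaffold has fewer than two usable anchors")
    extrapolated = cM < cms[0] or cM > cms[-1]
    if mode == "piecewise":
        if extrapolated:
            seg = 0 if cM < cms[0] else len(cms) - 2
            bp = _segment_interp(cms, bps, seg, cM)
        else:
            bp = float(np.interp(cM, cms, bps))
        return bp, extrapolated
    if mode == "local_rate":
        seg = _flanking_segment(cms, cM)
        return _segment_interp(cms, bps, seg, cM), extrapolated
    raise ValueError(f"unknown projection mode {mode!r}")


def _flanking_segment(cms: np.ndarray, cM: float) -> int:
    if cM <= cms[0]:
        return 0
    if cM >= cms[-1]:
        return len(cms) - 2
    return int(np.searchsorted(cms, cM, side="right") - 1)


def _segment_interp(cms, bps, seg: int, cM: float) -> float:
    slope = (bps[seg + 1] - bps[seg]) / (cms[seg + 1] - cms[seg])
    return float(bps[seg] + (cM - cms[seg]) * slope)


def project_qtl(
    qtl: QTLRecord,
    anchors: Sequence[MarkerAnchor],
    mode: str = "local_rate",
    species: str = "",
    chrom_length: Optional[int] = None,
) -> ProjectionResult:
    """Project a QTL's peak and confidence interval into base pairs.

    ``local_rate`` (default): the peak is interpolated between its flanking
    anchors and the CI bounds are placed around it using that single local
    Δbp/ΔcM rate, so the physical CI width is exactly (hi_cM − lo_cM) ×
    rate. ``piecewise``: peak and both bounds are interpolated through the
    full scaffold independently. Per-environment CIs are averaged first.
    Positions outside the anchored range use the terminal segment's rate
    and flag the projection as extrapolated. The interval is clipped at 0
    (and at ``chrom_length`` when known).
    """
    scaffold = build_scaffold(anchors, qtl.linkage_group)
    if scaffold is None:
        return ProjectionResult(qtl.qtl_id, None, reason=NO_LINKAGE_GROUP)
    if len(scaffold.cM) < 2:
        return ProjectionResult(qtl.qtl_id, None, reason=TOO_FEW_ANCHORS,
                                excluded_anchors=scaffold.excluded)
    lo_cM, hi_cM = average_environment_ci(qtl)
    peak_bp, extrapolated = project_position(scaffold, qtl.peak_cM, mode)
    if mode == "local_rate":
        seg = _flanking_segment(scaffold.cM, qtl.peak_cM)
        slope = (scaffold.bp[seg + 1] - scaffold.bp[seg]) / (
            scaffold.cM[seg + 1] - scaffold.cM[seg])
        lo_bp = peak_bp + (lo_cM - qtl.peak_cM) * slope
        hi_bp = peak_bp + (hi_cM - qtl.peak_cM) * slope
    elif mode == "piecewise":
        lo_bp, ex_lo = project_position(scaffold, lo_cM, mode)
        hi_bp, ex_hi = project_position(scaffold, hi_cM, mode)
        extrapolated = extrapolated or ex_lo or ex_hi
    else:
        raise ValueError(f"unknown projection mode {mode!r}")
    start, end = sorted((lo_bp, hi_bp))
    start = max(0.0, start)
    peak_bp = min(max(peak_bp, start), end)
    if chrom_length is not None:
        end = min(end, float(chrom_length))
        peak_bp = min(peak_bp, end)
    physical = PhysicalQTL(
        qtl_id=qtl.qtl_id, trait=qtl.trait, species=species,
        chrom=scaffold.target_chrom,
        start_bp=int(round(start)), end_bp=int(round(end)),
        peak_bp=int(round(peak_bp)), pve=qtl.pve,
    )
    return ProjectionResult(qtl.qtl_id, physical, extrapolated=extrapolated,
                            excluded_anchors=scaffold.excluded)


def project_all(qtls: Sequence[QTLRecord], anchors: Sequence[MarkerAnchor],
                mode: str = "local_rate", species: str = "") -> List[ProjectionResult]:
    return [project_qtl(q, anchors, mode=mode, species=species) for q in qtls]
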
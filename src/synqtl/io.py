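"""Readers and writers for every external file the pipeline touches.

Parsers normalize into the internal convention (0-based half-open
coordinates, fractional identity/coverage) and return a :class:`ParseResult`
carrying both the records and the count of skipped malformed records, so
that ``skipped + parsed == input records`` always reconciles.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, List, Optional, Sequence

import gffutils
import pandas as pd
import yaml

from .model import (
    AnchorHit,
    FilterPolicy,
    GeneticMapMarker,
    MarkerAnchor,
    PhysicalQTL,
    QTLRecord,
    RearrangementCall,
    SyntenyBlock,
    ValidationError,
)

log = logging.getLogger(__name__)


@dataclass
class ParseResult:
    """Parsed records plus bookkeeping on skipped input lines."""

    hits: List[AnchorHit] = field(default_factory=list)
    n_skipped: int = 0

    def __iter__(self):
        return iter(self.hits)

    def __len__(self):
        return len(self.hits)


# GMAP GFF3 dialect: which feature types carry one alignment each, and the
# attribute names holding the quality metrics (these drifted across GMAP
# releases, hence configurable).
GMAP_DIALECT = {
    "feature_types": ("mRNA", "cDNA_match"),
    "identity_attr": "identity",
    "coverage_attr": "coverage",
    "matches_attr": "matches",
    "mismatches_attr": "mismatches",
}


def _attr_float(feature, name: str) -> Optional[float]:
    vals = feature.attributes.get(name)
    if not vals:
        return None
    try:
        return float(vals[0])
    except (TypeError, ValueError):
        return None


def parse_gmap_gff3(path, dialect: Optional[dict] = None) -> ParseResult:
    """Parse a GMAP-style alignment GFF3 into anchor hits.

    One :class:`AnchorHit` per top-level alignment feature (``mRNA`` /
    ``cDNA_match`` by default). GFF3 1-based closed coordinates become
    0-based half-open; percentage identity/coverage attributes become
    fractions. Features missing identity or coverage, and malformed lines,
    are skipped and counted.
    """
    d = dict(GMAP_DIALECT)
    if dialect:
        d.update(dialect)
    feature_types = set(d["feature_types"])
    result = ParseResult()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            try:
                feat = gffutils.feature.feature_from_line(line)
            except Exception:
                log.warning("%s:%d: malformed GFF3 line skipped", path, lineno)
                result.n_skipped += 1
                continue
            if feat.featuretype not in feature_types:
                continue
            identity = _attr_float(feat, d["identity_attr"])
            coverage = _attr_float(feat, d["coverage_attr"])
            if identity is None or coverage is None:
                log.warning(
                    "%s:%d: alignment lacks %s/%s attribute, skipped",
                    path, lineno, d["identity_attr"], d["coverage_attr"],
                )
                result.n_skipped += 1
                continue
            target_start = feat.start - 1  # 1-based closed -> 0-based half-open
            target_end = feat.end
            matches = _attr_float(feat, d["matches_attr"])
            mismatches = _attr_float(feat, d["mismatches_attr"])
            query_id = feat.attributes.get("Name", [None])[0]
            qs = qe = None
            target_attr = feat.attributes.get("Target")
            if target_attr:
                parts = target_attr[0].split()
                if query_id is None:
                    query_id = parts[0]
                if len(parts) >= 3:
                    try:
                        qs, qe = int(parts[1]) - 1, int(parts[2])
                    except ValueError:
                        qs = qe = None
            if query_id is None:
                query_id = feat.attributes.get("ID", [f"line{lineno}"])[0]
            identity /= 100.0
            coverage /= 100.0
            if matches is not None and mismatches is not None:
                match_bp = int(matches)
                mismatch_bp = int(mismatches)
                aligned_length = match_bp + mismatch_bp
            else:
                # older GMAP output without match counts: approximate from
                # identity over the aligned target span
                aligned_length = target_end - target_start
                match_bp = int(round(identity * aligned_length))
                mismatch_bp = aligned_length - match_bp
            try:
                result.hits.append(
                    AnchorHit(
                        query_id=query_id,
                        target_chrom=feat.seqid,
                        target_start=target_start,
                        target_end=target_end,
                        strand=feat.strand if feat.strand in "+-" else "+",
                        identity=identity,
                        coverage=coverage,
                        aligned_length=aligned_length,
                        match_bp=match_bp,
                        mismatch_bp=mismatch_bp,
                        query_start=qs,
                        query_end=qe,
                    )
                )
            except ValidationError:
                log.warning("%s:%d: invalid alignment record skipped", path, lineno)
                result.n_skipped += 1
    return result


BLAST6_COLUMNS = (
    "qseqid sseqid pident length mismatch gapopen "
    "qstart qend sstart send evalue bitscore"
).split()


def parse_blast_tab(path) -> ParseResult:
    """Parse 12-column tabular BLAST (outfmt 6) into anchor hits.

    Subject coordinates with start > end indicate a minus-strand alignment:
    the coordinates are swapped and the hit carries strand '-'. BLAST
    reports no query coverage, so ``coverage`` is left unset.
    """
    result = ParseResult()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 12:
                log.warning("%s:%d: expected 12 columns, got %d; skipped",
                            path, lineno, len(fields))
                result.n_skipped += 1
                continue
            try:
                qseqid, sseqid = fields[0], fields[1]
                pident = float(fields[2])
                length = int(fields[3])
                mismatch = int(fields[4])
                qstart, qend = int(fields[6]), int(fields[7])
                sstart, send = int(fields[8]), int(fields[9])
            except ValueError:
                log.warning("%s:%d: unparsable BLAST row skipped", path, lineno)
                result.n_skipped += 1
                continue
            if sstart > send:
                strand = "-"
                sstart, send = send, sstart
            else:
                strand = "+"
            try:
                result.hits.append(
                    AnchorHit(
                        query_id=qseqid,
                        target_chrom=sseqid,
                        target_start=sstart - 1,
                        target_end=send,
                        strand=strand,
                        identity=pident / 100.0,
                        coverage=None,
                        aligned_length=length,
                        match_bp=length - mismatch,
                        mismatch_bp=mismatch,
                        query_start=min(qstart, qend) - 1,
                        query_end=max(qstart, qend),
                    )
                )
            except ValidationError:
                log.warning("%s:%d: invalid BLAST record skipped", path, lineno)
                result.n_skipped += 1
    return result


# ---------------------------------------------------------------------------
# tabular hits (the pipeline's own TSV interchange format)

HIT_COLUMNS = [
    "query_id", "query_chrom", "query_start", "query_end",
    "target_chrom", "target_start", "target_end", "strand",
    "identity", "coverage", "aligned_length", "match_bp", "mismatch_bp",
]


def write_hits_tsv(hits: Iterable[AnchorHit], path) -> None:
    rows = []
    for h in hits:
        rows.append({c: getattr(h, c) for c in HIT_COLUMNS})
    df = pd.DataFrame(rows, columns=HIT_COLUMNS)
    # %.17g survives a write/read cycle bit-exactly for doubles
    df.to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%.17g")


def read_hits_tsv(path) -> List[AnchorHit]:
    df = pd.read_csv(path, sep="\t", na_values=["NA"], float_precision="round_trip")
    _require(df, ["query_id", "target_chrom", "target_start", "target_end"], path)
    hits = []
    for row in df.itertuples(index=False):
        hits.append(
            AnchorHit(
                query_id=str(row.query_id),
                query_chrom=None if pd.isna(row.query_chrom) else str(row.query_chrom),
                query_start=None if pd.isna(row.query_start) else float(row.query_start),
                query_end=None if pd.isna(row.query_end) else float(row.query_end),
                target_chrom=str(row.target_chrom),
                target_start=int(row.target_start),
                target_end=int(row.target_end),
                strand=str(row.strand),
                identity=None if pd.isna(row.identity) else float(row.identity),
                coverage=None if pd.isna(row.coverage) else float(row.coverage),
                aligned_length=int(row.aligned_length),
                match_bp=int(row.match_bp),
                mismatch_bp=int(row.mismatch_bp),
            )
        )
    return hits


def _require(df: pd.DataFrame, cols: Sequence[str], path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing required column(s): {', '.join(missing)}")


# ---------------------------------------------------------------------------
# genetic maps and QTL tables

def read_genetic_map(path) -> List[GeneticMapMarker]:
    """Read a marker/linkage_group/cM TSV, ordered by (linkage_group, cM).

    Co-segregating markers (tied cM within a linkage group) are legal but
    flagged with a warning, since they carry no rate information.
    """
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    _require(df, ["marker_id", "linkage_group", "cM"], path)
    df = df.sort_values(["linkage_group", "cM"], kind="mergesort")
    markers = [
        GeneticMapMarker(str(r.marker_id), str(r.linkage_group), float(r.cM))
        for r in df.itertuples(index=False)
    ]
    by_lg = {}
    for m in markers:
        by_lg.setdefault(m.linkage_group, []).append(m.cM)
    for lg, cms in by_lg.items():
        if len(cms) != len(set(cms)):
            warnings.warn(f"{path}: linkage group {lg} has co-segregating markers (tied cM)")
    return markers


def write_genetic_map(markers: Iterable[GeneticMapMarker], path) -> None:
    df = pd.DataFrame(
        [(m.marker_id, m.linkage_group, m.cM) for m in markers],
        columns=["marker_id", "linkage_group", "cM"],
    )
    df.to_csv(path, sep="\t", index=False)


def read_qtl_table(path) -> List[QTLRecord]:
    """Read a QTL TSV. Optional column ``env_cis`` holds per-environment
    confidence intervals encoded ``lo:hi;lo:hi``."""
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    _require(df, ["qtl_id", "trait", "linkage_group", "peak_cM", "ci_lo_cM", "ci_hi_cM"], path)
    out = []
    for r in df.itertuples(index=False):
        env = ()
        if "env_cis" in df.columns and not pd.isna(getattr(r, "env_cis", float("nan"))):
            env = tuple(
                tuple(float(x) for x in pair.split(":"))
                for pair in str(r.env_cis).split(";")
                if pair
            )
        out.append(
            QTLRecord(
                qtl_id=str(r.qtl_id),
                trait=str(r.trait),
                linkage_group=str(r.linkage_group),
                peak_cM=float(r.peak_cM),
                ci_lo_cM=float(r.ci_lo_cM),
                ci_hi_cM=float(r.ci_hi_cM),
                pve=float(getattr(r, "pve", 0.0) or 0.0),
                per_environment_cis=env,
            )
        )
    return out


def write_qtl_table(qtls: Iterable[QTLRecord], path) -> None:
    rows = []
    for q in qtls:
        rows.append({
            "qtl_id": q.qtl_id, "trait": q.trait, "linkage_group": q.linkage_group,
            "peak_cM": q.peak_cM, "ci_lo_cM": q.ci_lo_cM, "ci_hi_cM": q.ci_hi_cM,
            "pve": q.pve,
            "env_cis": ";".join(f"{lo}:{hi}" for lo, hi in q.per_environment_cis),
        })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_marker_anchors(path) -> List[MarkerAnchor]:
    df = pd.read_csv(path, sep="\t")
    _require(df, ["marker_id", "linkage_group", "cM", "target_chrom", "target_bp"], path)
    return [
        MarkerAnchor(str(r.marker_id), str(r.linkage_group), float(r.cM),
                     str(r.target_chrom), int(r.target_bp))
        for r in df.itertuples(index=False)
    ]


def write_marker_anchors(anchors: Iterable[MarkerAnchor], path) -> None:
    df = pd.DataFrame(
        [(a.marker_id, a.linkage_group, a.cM, a.target_chrom, a.target_bp) for a in anchors],
        columns=["marker_id", "linkage_group", "cM", "target_chrom", "target_bp"],
    )
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# blocks, calls and physical QTL

def write_blocks_bed(blocks: Iterable[SyntenyBlock], path) -> None:
    """BED6: the name field encodes query interval and anchor count as
    ``q=<chrom>:<start>-<end>;n=<anchors>`` so the record round-trips."""
    with open(path, "w") as fh:
        for b in blocks:
            name = f"q={b.query_chrom}:{b.query_start:g}-{b.query_end:g};n={b.anchor_count}"
            fh.write(
                f"{b.target_chrom}\t{b.target_start}\t{b.target_end}\t"
                f"{name}\t{b.anchor_count}\t{b.orientation}\n"
            )


def read_blocks_bed(path) -> List[SyntenyBlock]:
    blocks = []
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            chrom, start, end, name, score, strand = line.rstrip("\n").split("\t")
            qpart, npart = name.split(";")
            qchrom, qiv = qpart[2:].rsplit(":", 1)
            qs, qe = qiv.split("-")
            blocks.append(
                SyntenyBlock(
                    query_chrom=qchrom, query_start=float(qs), query_end=float(qe),
                    target_chrom=chrom, target_start=int(start), target_end=int(end),
                    orientation=strand,
                    anchors=[None] * int(npart[2:]),
                )
            )
    return blocks


CALL_COLUMNS = [
    "kind", "query_chrom", "query_start", "query_end",
    "target_chrom", "target_start", "target_end",
    "span_bp", "n_anchors", "orientation",
]


def write_calls_tsv(calls: Iterable[RearrangementCall], path) -> None:
    rows = [
        {
            "kind": c.kind, "query_chrom": c.query_chrom,
            "query_start": c.query_start, "query_end": c.query_end,
            "target_chrom": c.target_chrom,
            "target_start": c.target_start, "target_end": c.target_end,
            "span_bp": c.target_span_bp, "n_anchors": c.n_anchors,
            "orientation": c.orientation,
        }
        for c in calls
    ]
    pd.DataFrame(rows, columns=CALL_COLUMNS).to_csv(path, sep="\t", index=False)


def read_calls_tsv(path) -> List[RearrangementCall]:
    df = pd.read_csv(path, sep="\t")
    _require(df, CALL_COLUMNS, path)
    return [
        RearrangementCall(
            kind=str(r.kind), query_chrom=str(r.query_chrom),
            query_start=float(r.query_start), query_end=float(r.query_end),
            target_chrom=str(r.target_chrom),
            target_start=int(r.target_start), target_end=int(r.target_end),
            target_span_bp=int(r.span_bp), n_anchors=int(r.n_anchors),
            orientation=str(r.orientation),
        )
        for r in df.itertuples(index=False)
    ]


def write_physical_qtl_bed(qtls: Iterable[PhysicalQTL], path) -> None:
    """BED6+3: chrom, start, end, qtl_id, pve score, '.', peak_bp, trait, species."""
    with open(path, "w") as fh:
        for q in qtls:
            fh.write(
                f"{q.chrom}\t{q.start_bp}\t{q.end_bp}\t{q.qtl_id}\t{q.pve:g}\t.\t"
                f"{q.peak_bp}\t{q.trait}\t{q.species}\n"
            )


def read_physical_qtl_bed(path) -> List[PhysicalQTL]:
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            chrom, start, end, qid, pve, _, peak, trait, species = line.rstrip("\n").split("\t")
            out.append(
                PhysicalQTL(
                    qtl_id=qid, trait=trait, species=species, chrom=chrom,
                    start_bp=int(start), end_bp=int(end), peak_bp=int(peak),
                    pve=float(pve),
                )
            )
    return out


# ---------------------------------------------------------------------------
# filter-policy YAML

def load_policy(path_or_dict, name: str = "") -> FilterPolicy:
    """Load a FilterPolicy from YAML (or a dict). A ``units: percent`` key
    declares that identity/coverage thresholds are given as percentages."""
    if isinstance(path_or_dict, dict):
        raw = dict(path_or_dict)
    else:
        with open(path_or_dict) as fh:
            raw = yaml.safe_load(fh) or {}
    units = raw.pop("units", "fraction")
    raw.pop("name", None)
    known = {"min_identity", "min_coverage", "min_aligned_length",
             "min_match_bp", "max_mismatch_bp"}
    unknown = set(raw) - known
    if unknown:
        raise ValidationError(f"unknown policy key(s): {', '.join(sorted(unknown))}")
    if units == "percent":
        for k in ("min_identity", "min_coverage"):
            if raw.get(k) is not None:
                raw[k] = raw[k] / 100.0
    elif units != "fraction":
        raise ValidationError(f"unknown units {units!r} (use 'fraction' or 'percent')")
    return FilterPolicy(name=name, **raw)
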
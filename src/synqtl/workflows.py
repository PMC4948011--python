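"""End-to-end workflows with run manifests.

Four workflows chain the pipeline stages the way the three Solanaceae
analyses were run, plus a simulation-validation loop:

* ``cds-synteny``   — parse → filter → best-hit → dedupe → chain → call
* ``map-synteny``   — genetic-map markers anchored on a physical genome,
                      chained with the cM axis as the query coordinate
* ``qtl-orthology`` — project QTL to bp → PVE filter → pairs → clusters
* ``simulate-validate`` — simulate a genome pair with known truth, run the
                      synteny pipeline, score precision/recall

Each run writes a JSON manifest of parameters and per-stage record counts
(input hits, filtered, unique, colocated-group members, blocks, calls),
because count tallies are the natural unit in which such screens are
reported and compared.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
import time
from dataclasses import dataclass, field
from typing import Dict, List, Optional

import yaml

from . import filtering, io, orthology, projection, simulate, synteny
from .model import ChainParams, MarkerAnchor, ValidationError

log = logging.getLogger(__name__)

WORKFLOWS = ("cds-synteny", "map-synteny", "qtl-orthology", "simulate-validate")

_KNOWN_KEYS = {
    "workflow", "seed", "out_dir", "inputs", "filter", "dedupe",
    "chain", "projection", "orthology", "simulate", "dotplot",
}


@dataclass
class RunConfig:
    workflow: str
    seed: int = 0
    out_dir: str = "."
    inputs: Dict[str, str] = field(default_factory=dict)
    filter: Dict = field(default_factory=dict)
    dedupe: Dict = field(default_factory=dict)
    chain: Dict = field(default_factory=dict)
    projection: Dict = field(default_factory=dict)
    orthology: Dict = field(default_factory=dict)
    simulate: Dict = field(default_factory=dict)
    dotplot: bool = False

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: Dict) -> "RunConfig":
        unknown = set(raw) - _KNOWN_KEYS
        if unknown:
            raise ValidationError(f"unknown config key(s): {', '.join(sorted(unknown))}")
        if raw.get("workflow") not in WORKFLOWS:
            raise ValidationError(
                f"workflow must be one of {', '.join(WORKFLOWS)}; got {raw.get('workflow')!r}")
        cfg = cls(**raw)
        for key, path in cfg.inputs.items():
            if not os.path.exists(path):
                raise ValidationError(f"input {key!r}: no such file {path}")
        return cfg


def _checksum(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


def _chain_params(cfg: RunConfig) -> ChainParams:
    return ChainParams(**cfg.chain) if cfg.chain else ChainParams()


def _resolve_policy(cfg: RunConfig):
    spec = cfg.filter.get("policy") if cfg.filter else None
    if spec is None:
        return filtering.PRESETS["tocds-peg"]
    if spec in filtering.PRESETS:
        return filtering.PRESETS[spec]
    return io.load_policy(spec, name=str(spec))


def run_workflow(config: RunConfig) -> Dict:
    """Execute one workflow; returns (and writes) the run manifest.

    A fatal error in any stage raises, naming the failing stage; the CLI
    maps this to a non-zero exit status.
    """
    os.makedirs(config.out_dir, exist_ok=True)
    t0 = time.time()
    manifest: Dict = {
        "workflow": config.workflow,
        "seed": config.seed,
        "parameters": {
            "filter": config.filter, "dedupe": config.dedupe, "chain": config.chain,
            "projection": config.projection, "orthology": config.orthology,
            "simulate": config.simulate,
        },
        "inputs": {k: {"path": v, "sha256": _checksum(v)}
                   for k, v in config.inputs.items()},
        "counts": {},
        "outputs": {},
    }
    stage = "setup"
    try:
        if config.workflow == "simulate-validate":
            _run_simulate_validate(config, manifest)
        elif config.workflow == "cds-synteny":
            _run_cds_synteny(config, manifest)
        elif config.workflow == "map-synteny":
            _run_map_synteny(config, manifest)
        elif config.workflow == "qtl-orthology":
            _run_qtl_orthology(config, manifest)
    except Exception as exc:  # annotate with the failing stage and re-raise
        stage = manifest.get("last_stage", stage)
        raise RuntimeError(f"workflow {config.workflow} failed at stage {stage}: {exc}") from exc
    manifest["runtime_s"] = round(time.time() - t0, 3)
    out = os.path.join(config.out_dir, "manifest.json")
    with open(out, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    manifest["manifest_path"] = out
    return manifest


def _synteny_stages(hits, config: RunConfig, manifest: Dict):
    """Shared filter → best-hit → dedupe → chain → call stages."""
    counts = manifest["counts"]
    counts["parsed_hits"] = len(hits)

    manifest["last_stage"] = "filter"
    policy = _resolve_policy(config)
    filtered = filtering.filter_hits(hits, policy)
    counts["filtered_hits"] = len(filtered)
    manifest["parameters"]["filter_policy"] = policy.name or "custom"

    manifest["last_stage"] = "best-hit"
    unique = filtering.best_hits(filtered)
    counts["unique_hits"] = len(unique)

    manifest["last_stage"] = "dedupe"
    tol = int(config.dedupe.get("tolerance_bp", 25)) if config.dedupe else 25
    groups = filtering.find_colocated_queries(unique, tolerance_bp=tol)
    counts.update(filtering.colocation_summary(unique, groups))

    manifest["last_stage"] = "chain"
    params = _chain_params(config)
    chained = synteny.chain_anchors(unique, params)
    counts["blocks"] = len(chained.blocks)
    counts["dropped_anchors"] = len(chained.dropped)

    manifest["last_stage"] = "orthology-assignment"
    assignment = synteny.assign_chromosome_orthology(unique)
    counts["same_chromosome_fraction"] = round(assignment.same_chromosome_fraction, 4)

    manifest["last_stage"] = "call"
    calls = synteny.call_rearrangements(chained.blocks, assignment.mapping, params)
    counts["calls"] = len(calls)
    counts["calls_by_kind"] = {
        k: sum(1 for c in calls if c.kind == k)
        for k in ("inversion", "translocation", "transposition", "duplication")
    }

    manifest["last_stage"] = "write"
    blocks_path = os.path.join(config.out_dir, "blocks.bed")
    calls_path = os.path.join(config.out_dir, "calls.tsv")
    hits_path = os.path.join(config.out_dir, "unique_hits.tsv")
    io.write_blocks_bed(chained.blocks, blocks_path)
    io.write_calls_tsv(calls, calls_path)
    io.write_hits_tsv(unique, hits_path)
    manifest["outputs"].update(blocks=blocks_path, calls=calls_path, unique_hits=hits_path)
    if config.dotplot:
        manifest["last_stage"] = "dotplot"
        prefix = os.path.join(config.out_dir, "dotplot_")
        _, files = synteny.dotplot(unique, prefix, calls=calls,
                                   orthology=assignment.mapping)
        manifest["outputs"]["dotplots"] = files
    return unique, chained, assignment, calls


def _run_cds_synteny(config: RunConfig, manifest: Dict) -> None:
    manifest["last_stage"] = "parse"
    path = config.inputs.get("hits")
    if path is None:
        raise ValidationError("cds-synteny needs inputs.hits (GFF3, BLAST tab or hits TSV)")
    if path.endswith((".gff", ".gff3")):
        parsed = io.parse_gmap_gff3(path)
        hits, skipped = parsed.hits, parsed.n_skipped
    elif path.endswith((".blast", ".b6", ".tab")):
        parsed = io.parse_blast_tab(path)
        hits, skipped = parsed.hits, parsed.n_skipped
    else:
        hits, skipped = io.read_hits_tsv(path), 0
    manifest["counts"]["skipped_records"] = skipped
    _synteny_stages(hits, config, manifest)


def _run_map_synteny(config: RunConfig, manifest: Dict) -> None:
    """Genetic-map vs physical-genome synteny: the query axis is the cM
    position of each marker, so gap limits on the query side are in cM."""
    manifest["last_stage"] = "parse"
    markers = io.read_genetic_map(config.inputs["map"])
    hits_in = io.read_hits_tsv(config.inputs["hits"])
    manifest["counts"]["map_markers"] = len(markers)

    manifest["last_stage"] = "anchor-markers"
    cm = {m.marker_id: m for m in markers}
    # markers keep their physical hit but acquire the map position as query
    anchored = []
    for h in hits_in:
        m = cm.get(h.query_id)
        if m is None:
            continue
        anchored.append(_with_map_query(h, m))
    counts = manifest["counts"]
    counts["anchored_markers"] = len(anchored)
    if not config.chain:
        config.chain = {"max_gap_query": 30.0}  # cM units on the query axis
    if not config.filter:
        config.filter = {"policy": "egm-peg"}  # cross-species marker filter
    _synteny_stages(anchored, config, manifest)


def _with_map_query(h, m):
    from .model import clone
    return clone(h, query_chrom=m.linkage_group,
                 query_start=m.cM, query_end=m.cM + 1e-9)


def _run_qtl_orthology(config: RunConfig, manifest: Dict) -> None:
    manifest["last_stage"] = "parse"
    qtls = io.read_qtl_table(config.inputs["qtl_a"])
    anchors = io.read_marker_anchors(config.inputs["anchors_a"])
    qtls_b = io.read_physical_qtl_bed(config.inputs["qtl_b"])
    traits = orthology.TraitEquivalence.from_yaml(config.inputs["traits"])
    counts = manifest["counts"]
    counts["qtl_a"], counts["qtl_b"] = len(qtls), len(qtls_b)

    manifest["last_stage"] = "project"
    mode = config.projection.get("mode", "local_rate")
    results = projection.project_all(qtls, anchors, mode=mode, species="a")
    projected = [r.physical for r in results if r.physical is not None]
    counts["projected_a"] = len(projected)
    counts["unprojectable_a"] = len(results) - len(projected)
    counts["extrapolated_a"] = sum(1 for r in results if r.extrapolated)

    manifest["last_stage"] = "filter-major"
    pve_min = float(config.orthology.get("pve_min", 10.0))
    major_a = orthology.filter_major(projected, pve_min)
    major_b = orthology.filter_major(qtls_b, pve_min)
    counts["major_a"], counts["major_b"] = len(major_a), len(major_b)

    manifest["last_stage"] = "pairs"
    proximity = int(config.orthology.get("proximity_bp", 1_000_000))
    report = orthology.find_orthologous_pairs(major_a, major_b, traits, proximity)
    counts["orthologous_pairs"] = len(report.pairs)
    counts["skipped_unknown_trait"] = report.n_skipped_unknown_trait

    manifest["last_stage"] = "cluster"
    merge_gap = int(config.orthology.get("merge_gap_bp", 1_000_000))
    clusters = orthology.cluster_qtl(major_a, major_b, merge_gap)
    counts["clusters"] = len(clusters)
    counts["orthologous_clusters"] = sum(1 for c in clusters if c.orthologous)
    counts["single_species_clusters"] = sum(1 for c in clusters if not c.orthologous)

    manifest["last_stage"] = "write"
    bed = os.path.join(config.out_dir, "physical_qtl_a.bed")
    io.write_physical_qtl_bed(projected, bed)
    tab = os.path.join(config.out_dir, "clusters.tsv")
    orthology.clusters_table(clusters).to_csv(tab, sep="\t", index=False)
    manifest["outputs"].update(physical_qtl_a=bed, clusters=tab)


def _run_simulate_validate(config: RunConfig, manifest: Dict) -> None:
    manifest["last_stage"] = "simulate"
    sim_kwargs = dict(config.simulate)
    noise_kwargs = sim_kwargs.pop("noise", None)
    if noise_kwargs is not None:
        sim_kwargs["noise"] = simulate.NoiseConfig(**noise_kwargs)
    sim_kwargs.setdefault("seed", config.seed)
    sim_cfg = simulate.SimConfig(**sim_kwargs)
    sim = simulate.simulate_genome_pair(sim_cfg)
    counts = manifest["counts"]
    counts["simulated_hits"] = len(sim.hits)
    counts["planted_events"] = len(sim.truth.events)
    counts["planted_signatures"] = len(sim.truth.signatures)

    _, _, _, calls = _synteny_stages(sim.hits, config, manifest)

    manifest["last_stage"] = "score"
    score = simulate.score_calls(calls, sim.truth)
    manifest["score"] = score
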
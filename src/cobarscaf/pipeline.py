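"""End-to-end scaffolding pipeline.

Runs the top-to-bottom scheme: data preparation (depths, seeds, binned
barcode index, Jaccard similarities) -> global ordering on the seed scaffold
graph -> consensus orienting -> paired-end local scaffolding -> gap size
assignment -> scaffold records ready for FASTA/AGP output.  Contigs that end
up unscaffolded are emitted as singleton scaffolds so the output partitions
the input assembly exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

from . import gap_estimation, local_scaffolding, ordering, orienting, prep
from .io_formats import (GAP_COBARCODE, GAP_PAIRED_END, ContigSet,
                         ReadAlignment, RunConfig, ScaffoldGap,
                         ScaffoldRecord)

log = logging.getLogger("cobarscaf")


@dataclass
class PipelineResult:
    scaffolds: list[ScaffoldRecord]
    seeds: set[str]
    screened: set[str]
    pruned: set[str]
    pool: set[str]                  # unscaffolded after local scaffolding
    depths: dict[str, float]
    mean_depth: float
    edges: list[prep.JaccardEdge]
    tree_classes: dict[str, int]
    oriented: list[orienting.OrientedScaffold]
    fills: list[local_scaffolding.GapFill]
    model: Optional[gap_estimation.JSDistanceModel]
    tree: Optional[object] = None         # final pruned spanning forest
    tree_classification: Optional[ordering.TreeClassification] = None
    singleton_names: set[str] = field(default_factory=set)

    def multi_contig_scaffolds(self) -> list[ScaffoldRecord]:
        return [s for s in self.scaffolds if len(s.parts) > 1]


def run_pipeline(contigs: ContigSet, alignments: Sequence[ReadAlignment],
                 config: Optional[RunConfig] = None) -> PipelineResult:
    """Run the full scaffolding pipeline on in-memory inputs."""
    cfg = config or RunConfig()

    # --- data preparation -------------------------------------------------
    unique = [a for a in alignments if a.is_unique]
    depths, mean_depth = prep.estimate_depths(
        unique, contigs, cfg.read_length, cfg.seed_min_length)
    for c in contigs:
        c.depth = depths[c.id]
    seeds = prep.select_seeds(contigs, depths, mean_depth,
                              cfg.seed_min_length, cfg.depth_window)
    log.info("prepare: %d contigs, %d seeds, mean depth %.2f",
             len(contigs), len(seeds), mean_depth)

    whitelist = None
    if cfg.minhash_ratio < 1.0:
        universe = {a.barcode for a in unique
                    if a.barcode and a.barcode != cfg.null_barcode}
        whitelist = prep.minhash_sample(universe, cfg.minhash_ratio,
                                        cfg.rng_seed)
        log.info("prepare: MinHash kept %d/%d barcodes",
                 len(whitelist), len(universe))
    index = prep.build_bin_index(unique, contigs, cfg.bin_size,
                                 cfg.keep_middle_bin, whitelist,
                                 cfg.null_barcode)
    edges = prep.all_pairs_js(index, cfg.min_barcode_union)
    log.info("prepare: %d JS edges", len(edges))

    # --- ordering ---------------------------------------------------------
    ordered, screened, pruned, cls, tree = ordering.order_seeds(
        seeds, edges, cfg.js_threshold, cfg.screen_iteration_cap,
        cfg.screen_removal_ratio_cap)
    log.info("order: %d scaffolds, %d screened, %d pruned",
             len(ordered), len(screened), len(pruned))

    # --- orienting --------------------------------------------------------
    splits = orienting.build_splits(unique, contigs, cfg.null_barcode)
    oriented = [orienting.orient_scaffold(o, splits, cfg.orient_window)
                for o in ordered]

    def _sym(state: str) -> str:
        return "+" if state == orienting.UP else "-"

    scaffolds = [
        ScaffoldRecord(
            name=f"scaffold_{i + 1}",
            parts=[(cid, _sym(st)) for cid, st in o.parts],
            gaps=[ScaffoldGap(kind=GAP_COBARCODE)
                  for _ in range(len(o.parts) - 1)])
        for i, o in enumerate(oriented)]

    # --- local scaffolding ------------------------------------------------
    pool = (set(contigs.ids()) - seeds) | screened | pruned
    links = local_scaffolding.build_pe_links(
        alignments, contigs, cfg.pe_min_support, cfg.pe_max_end_distance,
        cfg.read_length)
    scaffolds, pool, fills = local_scaffolding.insert_unscaffolded(
        scaffolds, pool, contigs, index, links, cfg.candidate_js_threshold,
        cfg.min_barcode_union, cfg.max_path_nodes)
    n_filled = sum(1 for f in fills if f.status == "filled")
    log.info("fill: %d PE links, %d/%d gaps filled",
             len(links), n_filled, len(fills))

    # --- gap size estimation ----------------------------------------------
    model = _calibrate_with_backoff(index, contigs, cfg)
    edge_lookup = {tuple(sorted((e.contig_a, e.contig_b))): e for e in edges}
    for s in scaffolds:
        _assign_gap_sizes(s, contigs, index, edge_lookup, model, cfg)

    # --- singletons for everything unscaffolded ---------------------------
    singleton_names: set[str] = set()
    n_named = len(scaffolds)
    for cid in sorted(pool):
        n_named += 1
        name = f"scaffold_{n_named}"
        scaffolds.append(ScaffoldRecord(name=name, parts=[(cid, "+")]))
        singleton_names.add(name)

    return PipelineResult(
        scaffolds=scaffolds, seeds=seeds, screened=screened, pruned=pruned,
        pool=pool, depths=depths, mean_depth=mean_depth, edges=edges,
        tree_classes=cls.class_counts(), oriented=oriented, fills=fills,
        model=model, tree=tree, tree_classification=cls,
        singleton_names=singleton_names)


def _calibrate_with_backoff(index, contigs, cfg: RunConfig):
    """Calibrate the JS-distance model, halving max_distance on failure.

    With no contigs long enough at any scale the model is None and
    co-barcode gaps fall back to ``cfg.default_gap_size``.
    """
    max_distance = cfg.calib_max_distance
    while max_distance >= 4 * cfg.calib_bucket_width:
        try:
            model = gap_estimation.calibrate_js_distance(
                index, contigs, max_distance, cfg.calib_bucket_width,
                cfg.calib_noise_floor)
            log.info("gapsize: calibrated JS-distance model over %d bp "
                     "(slope %.3g)", max_distance, model.slope)
            return model
        except ValueError:
            max_distance //= 2
    log.info("gapsize: no calibration possible; using default gap %d bp",
             cfg.default_gap_size)
    return None


def _assign_gap_sizes(scaffold: ScaffoldRecord, contigs: ContigSet, index,
                      edge_lookup, model, cfg: RunConfig) -> None:
    for i, gap in enumerate(scaffold.gaps):
        if gap.kind == GAP_PAIRED_END:
            gap.size = gap_estimation.assign_pe_gap(cfg.pe_gap_size)
            continue
        left_id, left_orient = scaffold.parts[i]
        right_id, right_orient = scaffold.parts[i + 1]
        key = tuple(sorted((left_id, right_id)))
        edge = edge_lookup.get(key)
        if edge is None:
            edge = prep.contig_js(key[0], key[1], index,
                                  cfg.min_barcode_union)
        if model is None or edge.js <= 0.0:
            gap.size = cfg.default_gap_size
            continue
        offset = (_facing_offset(left_id, left_orient, edge, contigs, index,
                                 facing="right")
                  + _facing_offset(right_id, right_orient, edge, contigs,
                                   index, facing="left"))
        gap.size = gap_estimation.estimate_gap(
            edge.js, model, cfg.gap_min, cfg.gap_max, offset)


def _facing_offset(cid: str, orient: str, edge, contigs: ContigSet, index,
                   facing: str) -> float:
    """Distance from the best bin's centre to the contig end facing the gap.

    The left flank faces the gap with its scaffold-right end, which is the
    sequence 3' end when oriented '+' and the 5' end when '-'; vice versa
    for the right flank.
    """
    bins = index.contig_bins(cid)
    b = bins[min(edge.bin_index_of(cid), len(bins) - 1)]
    length = contigs[cid].length
    at_seq_end = (orient == "+") == (facing == "right")
    return (length - b.center) if at_seq_end else b.center
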
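"""Local scaffolding: inserting unscaffolded contigs into gaps with
paired-end links.

After global ordering and orienting, the unscaffolded pool holds non-seed
contigs plus seeds dropped by tip pruning or screening.  For each gap of an
oriented scaffold, pool contigs with strong co-barcoding similarity to either
flank are clustered as candidates, a small directed graph is built whose
directed edges are contig-end junctions supported by enough read pairs
(forward-reverse library geometry), and a depth-first search enumerates
simple paths from the left flank's exit end to the right flank's entry end.
The path with the fewest inserted contigs wins (ties by total read-pair
support).  Junctions created here are paired-end evidence and later receive
the fixed small gap size.

Each pool contig can be inserted at most once globally; scaffolds are
processed in descending span order and gaps left to right, so runs are
deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

from .io_formats import (GAP_COBARCODE, GAP_PAIRED_END, ContigSet,
                         ReadAlignment, ScaffoldGap, ScaffoldRecord)
from .orienting import OrientedScaffold
from .prep import BinBarcodeIndex, JaccardEdge, contig_js

HEAD = "head"
TAIL = "tail"

End = tuple[str, str]            # (contig_id, HEAD|TAIL)
LinkKey = tuple[End, End]        # canonical: min end first


def _canonical(a: End, b: End) -> LinkKey:
    return (a, b) if a <= b else (b, a)


def build_pe_links(alignments: Sequence[ReadAlignment], contigs: ContigSet,
                   pe_min_support: int = 3, max_end_distance: int = 1000,
                   read_length: int = 100) -> dict[LinkKey, int]:
    """Aggregate read pairs spanning two contigs into contig-end links.

    Assuming a forward-reverse library, a forward read points off its
    contig's tail and a reverse read off its head; a pair whose mates map
    uniquely to two different contigs therefore joins one specific end of
    each.  Reads farther than ``max_end_distance`` from the implied end are
    ignored (their mate would fall inside the same contig).  Links supported
    by fewer than ``pe_min_support`` pairs are dropped.  Unpaired reads are
    ignored (counted in the return of :func:`count_unpaired`).
    """
    by_id = {a.read_id: a for a in alignments if a.is_unique}
    links: dict[LinkKey, int] = {}
    for aln in alignments:
        if not aln.is_unique or not aln.mate_read_id:
            continue
        if aln.read_id >= aln.mate_read_id:   # count each pair once
            continue
        mate = by_id.get(aln.mate_read_id)
        if mate is None or mate.contig_id == aln.contig_id:
            continue
        end_a = _implied_end(aln, contigs, max_end_distance, read_length)
        end_b = _implied_end(mate, contigs, max_end_distance, read_length)
        if end_a is None or end_b is None:
            continue
        key = _canonical((aln.contig_id, end_a), (mate.contig_id, end_b))
        links[key] = links.get(key, 0) + 1
    return {k: n for k, n in links.items() if n >= pe_min_support}


def _implied_end(aln: ReadAlignment, contigs: ContigSet,
                 max_end_distance: int, read_length: int) -> Optional[str]:
    length = contigs[aln.contig_id].length
    if aln.strand == "+":
        dist = length - (aln.position + read_length)
        return TAIL if dist <= max_end_distance else None
    return HEAD if aln.position <= max_end_distance else None


def count_unpaired(alignments: Sequence[ReadAlignment]) -> int:
    by_id = {a.read_id for a in alignments}
    return sum(1 for a in alignments
               if a.mate_read_id and a.mate_read_id not in by_id)


# ---------------------------------------------------------------------------
# Candidate clustering and gap filling
# ---------------------------------------------------------------------------

def candidates_for_gap(left_id: str, right_id: str, pool: set[str],
                       index: BinBarcodeIndex,
                       candidate_js_threshold: float,
                       min_union: int = 10,
                       js_cache: Optional[dict] = None) -> set[str]:
    """Pool contigs with JS >= threshold to either flank of the gap."""
    out = set()
    for cid in pool:
        for flank in (left_id, right_id):
            js = _cached_js(cid, flank, index, min_union, js_cache)
            if js >= candidate_js_threshold:
                out.add(cid)
                break
    return out


def _cached_js(a: str, b: str, index: BinBarcodeIndex, min_union: int,
               cache: Optional[dict]) -> float:
    key = (a, b) if a <= b else (b, a)
    if cache is not None and key in cache:
        return cache[key]
    js = contig_js(key[0], key[1], index, min_union).js
    if cache is not None:
        cache[key] = js
    return js


@dataclass
class GapFill:
    """Result of trying to fill one gap of one scaffold."""

    scaffold: str
    left: str
    right: str
    inserted: list[tuple[str, str]] = field(default_factory=list)  # (id, +/-)
    support: int = 0
    status: str = "unfilled"      # 'filled', 'pe_confirmed' or 'unfilled'


def _exit_end(orient: str) -> str:
    return TAIL if orient == "+" else HEAD


def _entry_end(orient: str) -> str:
    return HEAD if orient == "+" else TAIL


def fill_gap(left: tuple[str, str], right: tuple[str, str],
             candidates: set[str], links: dict[LinkKey, int],
             max_path_nodes: int = 5,
             scaffold_name: str = "") -> GapFill:
    """Depth-first search for the shortest supported path across one gap.

    Nodes of the local directed graph are (contig, orientation) states of
    the candidate contigs; a directed edge exists when a paired-end link
    joins the exit end of one state to the entry end of the next.  Among
    complete left-to-right paths the fewest-node one wins, ties broken by
    greatest total support, then lexicographically.  A direct flank-to-flank
    link yields an empty insertion with status ``pe_confirmed``.
    """
    fill = GapFill(scaffold_name, left[0], right[0])
    target_entry = (right[0], _entry_end(right[1]))
    states = [(c, o) for c in sorted(candidates) for o in "+-"]

    def successors(exit_of: End):
        out = []
        for cid, orient in states:
            sup = links.get(_canonical(exit_of, (cid, _entry_end(orient))))
            if sup:
                out.append(((cid, orient), sup))
        return out

    best: Optional[tuple[int, int, list]] = None  # (n_nodes, -support, path)

    def dfs(state_end: End, path: list, used: set, support: int):
        nonlocal best
        direct = links.get(_canonical(state_end, target_entry))
        if direct:
            cand = (len(path), -(support + direct), list(path))
            if best is None or cand < best:
                best = cand
        if len(path) >= max_path_nodes:
            return
        for (cid, orient), sup in successors(state_end):
            if cid in used:
                continue
            used.add(cid)
            path.append((cid, orient))
            dfs((cid, _exit_end(orient)), path, used, support + sup)
            path.pop()
            used.discard(cid)

    dfs((left[0], _exit_end(left[1])), [], {left[0], right[0]}, 0)
    if best is None:
        return fill
    n_nodes, neg_support, path = best
    fill.inserted = path
    fill.support = -neg_support
    fill.status = "pe_confirmed" if n_nodes == 0 else "filled"
    return fill


def insert_unscaffolded(scaffolds: list[ScaffoldRecord], pool: set[str],
                        contigs: ContigSet, index: BinBarcodeIndex,
                        links: dict[LinkKey, int],
                        candidate_js_threshold: float,
                        min_union: int = 10, max_path_nodes: int = 5,
                        ) -> tuple[list[ScaffoldRecord], set[str],
                                   list[GapFill]]:
    """Fill gaps of all scaffolds, consuming the unscaffolded pool.

    Scaffolds are processed in descending span order (gaps left to right);
    every inserted contig leaves the pool so no contig lands in two places.
    Flank contigs are never reordered or reoriented.  Returns the rewritten
    scaffolds, the remaining pool, and a per-gap fill report.
    """
    pool = set(pool)
    js_cache: dict = {}
    fills: list[GapFill] = []
    out: list[ScaffoldRecord] = []
    order = sorted(range(len(scaffolds)),
                   key=lambda i: (-scaffolds[i].span(contigs),
                                  scaffolds[i].name))
    rewritten: dict[int, ScaffoldRecord] = {}
    for i in order:
        s = scaffolds[i]
        new_parts: list[tuple[str, str]] = [s.parts[0]]
        new_gaps: list[ScaffoldGap] = []
        for gi in range(len(s.gaps)):
            left = s.parts[gi]
            right = s.parts[gi + 1]
            cands = candidates_for_gap(left[0], right[0], pool, index,
                                       candidate_js_threshold, min_union,
                                       js_cache)
            fill = fill_gap(left, right, cands, links, max_path_nodes,
                            scaffold_name=s.name)
            fills.append(fill)
            if fill.status == "filled":
                for cid, orient in fill.inserted:
                    new_gaps.append(ScaffoldGap(kind=GAP_PAIRED_END))
                    new_parts.append((cid, orient))
                    pool.discard(cid)
                new_gaps.append(ScaffoldGap(kind=GAP_PAIRED_END))
            elif fill.status == "pe_confirmed":
                new_gaps.append(ScaffoldGap(kind=GAP_PAIRED_END))
            else:
                new_gaps.append(ScaffoldGap(kind=s.gaps[gi].kind))
            new_parts.append(right)
        rewritten[i] = ScaffoldRecord(name=s.name, parts=new_parts,
                                      gaps=new_gaps)
    out = [rewritten[i] for i in range(len(scaffolds))]
    return out, pool, fills
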
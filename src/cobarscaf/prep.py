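"""Data preparation: depth estimation, seed selection, binned barcode index
and Jaccard-similarity computation.

Co-barcoding correlation between two contigs is quantified as the maximum
Jaccard similarity (JS) over all pairs of fixed-size bins, one bin from each
contig, where a bin's set is the set of barcodes whose uniquely aligned reads
start inside it.  Bins are chopped from both ends of a contig toward the
middle with no gap or overlap; the middle remainder shorter than one bin is
kept as a short bin by default so that the union of bin barcode sets equals
the contig's barcode set.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

from .io_formats import Contig, ContigSet, ReadAlignment


# ---------------------------------------------------------------------------
# Depth and seed selection
# ---------------------------------------------------------------------------

def estimate_depths(alignments: Sequence[ReadAlignment], contigs: ContigSet,
                    read_length: int,
                    seed_min_length: int = 7000) -> tuple[dict[str, float], float]:
    """Per-contig unique-read depth and the assembly-wide mean depth.

    depth(c) = (#unique reads on c * read_length) / length(c).  The mean is
    taken over contigs of length >= ``seed_min_length`` only, so that the
    depth window for seed selection is centred on the depth of contigs long
    enough to be seeds themselves.
    """
    counts: dict[str, int] = {c.id: 0 for c in contigs}
    for aln in alignments:
        if aln.is_unique:
            counts[aln.contig_id] += 1
    depths = {cid: counts[cid] * read_length / contigs[cid].length
              for cid in counts}
    long_ids = [c.id for c in contigs if c.length >= seed_min_length]
    if not long_ids:
        raise ValueError("no contigs reach seed_min_length; cannot estimate "
                         "mean depth (lower the threshold)")
    mean_depth = sum(depths[cid] for cid in long_ids) / len(long_ids)
    return depths, mean_depth


def select_seeds(contigs: ContigSet, depths: dict[str, float],
                 mean_depth: float, seed_min_length: int = 7000,
                 depth_window: tuple[float, float] = (0.5, 1.5)) -> set[str]:
    """Mark and return seed contigs: long and depth-typical.

    A seed must satisfy length >= ``seed_min_length`` and depth within
    ``[lo * mean, hi * mean]``.  The window excludes collapsed repeats
    (inflated depth) and poorly supported contigs (depleted depth).
    """
    lo, hi = depth_window
    seeds: set[str] = set()
    for c in contigs:
        ok = (c.length >= seed_min_length
              and lo * mean_depth <= depths[c.id] <= hi * mean_depth)
        c.is_seed = ok
        if ok:
            seeds.add(c.id)
    if not seeds:
        raise ValueError("no seed contigs selected; lower seed_min_length "
                         "or widen depth_window")
    return seeds


# ---------------------------------------------------------------------------
# Binned barcode index
# ---------------------------------------------------------------------------

@dataclass
class Bin:
    contig_id: str
    index: int           # position in the contig's start-sorted bin list
    start: int           # 0-based half-open span on the contig
    end: int
    barcodes: set[str]

    @property
    def center(self) -> float:
        return (self.start + self.end) / 2.0


class BinBarcodeIndex:
    """Per-bin barcode sets for every contig.

    ``bins[contig_id]`` is the start-sorted list of :class:`Bin` objects.
    """

    def __init__(self, bin_size: int) -> None:
        if bin_size <= 0:
            raise ValueError("bin_size must be positive")
        self.bin_size = bin_size
        self.bins: dict[str, list[Bin]] = {}

    def contig_bins(self, contig_id: str) -> list[Bin]:
        try:
            return self.bins[contig_id]
        except KeyError:
            raise KeyError(f"contig {contig_id} not in bin index") from None

    def contig_barcodes(self, contig_id: str) -> set[str]:
        out: set[str] = set()
        for b in self.contig_bins(contig_id):
            out |= b.barcodes
        return out


def bin_spans(length: int, bin_size: int,
              keep_middle: bool = True) -> list[tuple[int, int]]:
    """Chop a contig of ``length`` into bins from both ends toward the middle.

    Full-size bins alternate none-overlapping from the 5' and 3' ends; any
    middle remainder shorter than ``bin_size`` is kept as one short bin when
    ``keep_middle`` (default) or discarded otherwise.  Returned spans are
    start-sorted, 0-based half-open, and tile the contig without overlap.
    """
    n_full = length // bin_size
    n_left = (n_full + 1) // 2
    n_right = n_full // 2
    spans = [(i * bin_size, (i + 1) * bin_size) for i in range(n_left)]
    mid_start = n_left * bin_size
    mid_end = length - n_right * bin_size
    if keep_middle and mid_end > mid_start:
        spans.append((mid_start, mid_end))
    spans.extend((length - (j + 1) * bin_size, length - j * bin_size)
                 for j in range(n_right - 1, -1, -1))
    return spans


def build_bin_index(alignments: Sequence[ReadAlignment], contigs: ContigSet,
                    bin_size: int, keep_middle: bool = True,
                    barcode_whitelist: Optional[set[str]] = None,
                    null_barcode: str = "0_0_0") -> BinBarcodeIndex:
    """Build the binned barcode index from unique, barcoded alignments.

    Each read is assigned to the bin containing its leftmost position.
    Reads that are non-unique, carry the null barcode sentinel, or fall
    outside the whitelist (MinHash sampling) are excluded.
    """
    index = BinBarcodeIndex(bin_size)
    starts: dict[str, list[int]] = {}
    for c in contigs:
        spans = bin_spans(c.length, bin_size, keep_middle)
        index.bins[c.id] = [Bin(c.id, i, s, e, set())
                            for i, (s, e) in enumerate(spans)]
        starts[c.id] = [s for s, _ in spans]
    for aln in alignments:
        if not aln.is_unique or not aln.barcode:
            continue
        if aln.barcode == null_barcode:
            continue
        if barcode_whitelist is not None and aln.barcode not in barcode_whitelist:
            continue
        bins = index.bins[aln.contig_id]
        if not bins:
            continue
        # bins tile the contig; locate by binary search on starts
        lst = starts[aln.contig_id]
        lo, hi = 0, len(lst) - 1
        while lo < hi:
            mid = (lo + hi + 1) // 2
            if lst[mid] <= aln.position:
                lo = mid
            else:
                hi = mid - 1
        b = bins[lo]
        if b.start <= aln.position < b.end:
            b.barcodes.add(aln.barcode)
    return index


# ---------------------------------------------------------------------------
# Jaccard similarity
# ---------------------------------------------------------------------------

@dataclass
class JaccardEdge:
    """Maximum bin-pair Jaccard similarity between two contigs.

    ``nb`` (number of shared barcodes at contig level) is carried for
    diagnostics only; scaffolding decisions use ``js``.
    """

    contig_a: str
    contig_b: str
    js: float
    best_bin_pair: tuple[int, int] = (0, 0)
    nb: int = 0

    def other(self, cid: str) -> str:
        return self.contig_b if cid == self.contig_a else self.contig_a

    def bin_index_of(self, cid: str) -> int:
        return (self.best_bin_pair[0] if cid == self.contig_a
                else self.best_bin_pair[1])


def jaccard_bins(set_a: set[str], set_b: set[str]) -> float:
    """|a & b| / |a | b|; 0.0 when both sets are empty."""
    if not set_a and not set_b:
        return 0.0
    inter = len(set_a & set_b)
    union = len(set_a) + len(set_b) - inter
    return inter / union


def contig_js(contig_a: str, contig_b: str, index: BinBarcodeIndex,
              min_union: int = 10) -> JaccardEdge:
    """Maximum JS over all bin pairs of two contigs (exhaustive loop).

    Bin pairs whose barcode union is smaller than ``min_union`` contribute
    js = 0: tiny unions make the ratio too noisy to rank.
    """
    if contig_a == contig_b:
        raise ValueError("contig_js requires two distinct contigs")
    best, best_pair = 0.0, (0, 0)
    for ba in index.contig_bins(contig_a):
        for bb in index.contig_bins(contig_b):
            union = len(ba.barcodes | bb.barcodes)
            if union < min_union:
                continue
            js = jaccard_bins(ba.barcodes, bb.barcodes)
            if js > best or (js == best and (ba.index, bb.index) < best_pair
                             and js > 0.0):
                best, best_pair = js, (ba.index, bb.index)
    return JaccardEdge(contig_a, contig_b, best, best_pair)


def all_pairs_js(index: BinBarcodeIndex, min_union: int = 10,
                 restrict_to: Optional[set[str]] = None) -> list[JaccardEdge]:
    """JS for every contig pair sharing at least one barcode.

    Uses an inverted barcode -> bins map so only bin pairs with non-empty
    intersection are visited; equivalent to running :func:`contig_js` on
    every pair (pairs with no shared barcode have js = 0 and are omitted).
    """
    inverted: dict[str, list[Bin]] = {}
    for cid, bins in index.bins.items():
        if restrict_to is not None and cid not in restrict_to:
            continue
        for b in bins:
            for bc in b.barcodes:
                inverted.setdefault(bc, []).append(b)
    inter: dict[tuple[int, int], int] = {}
    bin_key: dict[int, Bin] = {}
    for bins in inverted.values():
        for i in range(len(bins)):
            for j in range(i + 1, len(bins)):
                a, b = bins[i], bins[j]
                if a.contig_id == b.contig_id:
                    continue
                if (a.contig_id, a.index) > (b.contig_id, b.index):
                    a, b = b, a
                key = (id(a), id(b))
                bin_key[id(a)] = a
                bin_key[id(b)] = b
                inter[key] = inter.get(key, 0) + 1

    best: dict[tuple[str, str], JaccardEdge] = {}
    for (ka, kb), n_inter in inter.items():
        a, b = bin_key[ka], bin_key[kb]
        union = len(a.barcodes) + len(b.barcodes) - n_inter
        if union < min_union:
            continue
        js = n_inter / union
        pair_key = (a.contig_id, b.contig_id)
        cur = best.get(pair_key)
        pair = (a.index, b.index)
        if (cur is None or js > cur.js
                or (js == cur.js and pair < cur.best_bin_pair)):
            best[pair_key] = JaccardEdge(a.contig_id, b.contig_id, js, pair)
    contig_sets: dict[str, set[str]] = {}
    for edge in best.values():
        for cid in (edge.contig_a, edge.contig_b):
            if cid not in contig_sets:
                contig_sets[cid] = index.contig_barcodes(cid)
        edge.nb = len(contig_sets[edge.contig_a]
                      & contig_sets[edge.contig_b])
    return [best[k] for k in sorted(best)]


# ---------------------------------------------------------------------------
# MinHash barcode sampling
# ---------------------------------------------------------------------------

def minhash_sample(barcode_universe: Iterable[str], ratio: float,
                   rng_seed: int) -> set[str]:
    """Deterministic hash-rank subsample of the barcode universe.

    Each barcode gets a keyed 64-bit hash; the ``ratio`` fraction with the
    smallest hashes is kept.  The same subset is applied to every bin, so
    the sampled JS remains a consistent estimator of the full JS.
    """
    if not (0.0 < ratio <= 1.0):
        raise ValueError("ratio must be in (0, 1]")
    universe = sorted(set(barcode_universe))
    if ratio == 1.0:
        return set(universe)
    key = rng_seed.to_bytes(8, "little", signed=False)
    ranked = sorted(
        (int.from_bytes(hashlib.blake2b(bc.encode(), digest_size=8,
                                        key=key).digest(), "big"), bc)
        for bc in universe)
    n_keep = max(1, round(ratio * len(universe)))
    return {bc for _, bc in ranked[:n_keep]}
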
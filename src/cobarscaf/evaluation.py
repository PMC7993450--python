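"""Truth-based evaluation of scaffolding output.

Edges (adjacent contig pairs in a scaffold, or spanning-tree edges) are
classified against the simulated truth map by the number of contigs lying
strictly between the pair in the genome: none -> 1-order, one -> 2-order,
two or more -> high-order; pairs involving a misassembled (chimeric) contig
are error edges.  Standard contiguity metrics (NG50 against the known genome
size) and a global-flip-normalised orientation accuracy complete the report.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .synthetic_data import TruthMap


@dataclass
class EdgeClassCounts:
    one_order: int = 0
    two_order: int = 0
    high_order: int = 0
    error: int = 0

    @property
    def total(self) -> int:
        return self.one_order + self.two_order + self.high_order + self.error

    def as_dict(self) -> dict[str, int]:
        return {"1-order": self.one_order, "2-order": self.two_order,
                "high-order": self.high_order, "error": self.error}


def classify_edge(a: str, b: str, truth: TruthMap,
                  _order_cache: dict | None = None) -> str:
    """Class of one contig pair: '1-order', '2-order', 'high-order', 'error'."""
    for cid in (a, b):
        if cid not in truth:
            raise KeyError(f"contig {cid} absent from truth map")
    ra, rb = truth[a], truth[b]
    if ra.is_chimeric or rb.is_chimeric:
        return "error"
    starts, ends = _interval_arrays(truth, _order_cache)
    sa, ea, _ = ra.primary
    sb, eb, _ = rb.primary
    if sa > sb:
        (sa, ea), (sb, eb) = (sb, eb), (sa, ea)
    if ea > sb:   # overlapping intervals (collapsed repeats): treat as 1-order
        return "1-order"
    # contigs strictly inside (ea, sb)
    lo = bisect.bisect_left(starts, ea)
    n_between = 0
    for k in range(lo, len(starts)):
        if starts[k] >= sb:
            break
        if ends[k] <= sb:
            n_between += 1
    if n_between == 0:
        return "1-order"
    if n_between == 1:
        return "2-order"
    return "high-order"


def _interval_arrays(truth: TruthMap, cache):
    if cache is not None and "starts" in cache:
        return cache["starts"], cache["ends"]
    recs = truth.ordered_non_chimeric()
    starts = [r.primary[0] for r in recs]
    ends = [r.primary[1] for r in recs]
    if cache is not None:
        cache["starts"], cache["ends"] = starts, ends
    return starts, ends


def classify_edges(pairs: Iterable[tuple[str, str]],
                   truth: TruthMap) -> EdgeClassCounts:
    """Edge-class census over contig pairs (symmetric in each pair)."""
    counts = EdgeClassCounts()
    cache: dict = {}
    for a, b in pairs:
        cls = classify_edge(a, b, truth, cache)
        if cls == "1-order":
            counts.one_order += 1
        elif cls == "2-order":
            counts.two_order += 1
        elif cls == "high-order":
            counts.high_order += 1
        else:
            counts.error += 1
    return counts


def scaffold_adjacent_pairs(scaffolds) -> list[tuple[str, str]]:
    """Adjacent contig pairs of scaffold part lists (ids or (id, orient))."""
    pairs = []
    for s in scaffolds:
        ids = [p[0] if isinstance(p, tuple) else p for p in
               (s.parts if hasattr(s, "parts") else s)]
        pairs.extend((ids[i], ids[i + 1]) for i in range(len(ids) - 1))
    return pairs


# ---------------------------------------------------------------------------
# Contiguity
# ---------------------------------------------------------------------------

def contiguity_metrics(scaffold_lengths: Sequence[int],
                       genome_length: int) -> dict[str, int]:
    """NG50, total length, largest scaffold and scaffold count.

    NG50 is the length of the scaffold at which the cumulative
    descending-sorted length first reaches half the genome size (0 when the
    assembly never gets there).
    """
    if genome_length <= 0:
        raise ValueError("genome_length must be positive")
    lengths = sorted(scaffold_lengths, reverse=True)
    metrics = {"count": len(lengths),
               "total_length": sum(lengths),
               "largest": lengths[0] if lengths else 0,
               "ng50": 0}
    half = genome_length / 2
    cum = 0
    for L in lengths:
        cum += L
        if cum >= half:
            metrics["ng50"] = L
            break
    return metrics


# ---------------------------------------------------------------------------
# Orientation accuracy
# ---------------------------------------------------------------------------

def orientation_accuracy(oriented_scaffolds, truth: TruthMap) -> float:
    """Fraction of contigs oriented consistently with truth.

    Orientation is defined relative to the scaffold, so each scaffold is
    first normalised by the global flip that maximises agreement with the
    truth strands; chimeric contigs are excluded.  Returns 1.0 for empty
    input (nothing is wrong).
    """
    correct = total = 0
    for s in oriented_scaffolds:
        parts = s.parts if hasattr(s, "parts") else s
        match = n = 0
        for cid, orient in parts:
            rec = truth[cid]
            if rec.is_chimeric:
                continue
            up = orient in ("up", "+")
            if up == (rec.primary[2] == "+"):
                match += 1
            n += 1
        correct += max(match, n - match)
        total += n
    return correct / total if total else 1.0
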
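"""Orienting ordered scaffolds by consensus of neighbour votes.

Co-barcoding linkage is undirected, so a contig's orientation is resolved by
splitting it at its midpoint into a head (5' half) and a tail and comparing
the Jaccard similarity of each half against nearby neighbours in the ordered
scaffold.  A preceding neighbour supports the "up" state (same direction as
the scaffold) when the head is the closer half (JS_Head > JS_Tail); for a
following neighbour the comparison is reversed.  Each contig collects votes
from up to a window of neighbours on both sides and takes the majority;
ties and all-abstain cases resolve to "up" with a low-confidence flag.

Since neighbour orientations are unknown at this stage, the neighbour votes
with its full barcode set (both halves pooled): the decision is carried by
the *target's* head/tail asymmetry, and pooling keeps the vote exactly
antisymmetric under reversing the scaffold — reversing the order flips
every non-tie orientation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from .io_formats import Contig, ContigSet, ReadAlignment
from .ordering import OrderedScaffold
from .prep import jaccard_bins

UP = "up"
DOWN = "down"
ABSTAIN = "abstain"


@dataclass
class HeadTailSplit:
    """Barcode sets of the two halves of a contig.

    head covers [0, length // 2), tail covers [length // 2, length).
    """

    contig_id: str
    head: set[str] = field(default_factory=set)
    tail: set[str] = field(default_factory=set)

    @property
    def all_barcodes(self) -> set[str]:
        return self.head | self.tail


def split_head_tail(contig: Contig,
                    alignments: Sequence[ReadAlignment],
                    null_barcode: str = "0_0_0") -> HeadTailSplit:
    """Partition a contig's unique barcoded reads at the midpoint."""
    split = HeadTailSplit(contig.id)
    mid = contig.length // 2
    for aln in alignments:
        if aln.contig_id != contig.id or not aln.is_unique:
            continue
        if not aln.barcode or aln.barcode == null_barcode:
            continue
        (split.head if aln.position < mid else split.tail).add(aln.barcode)
    return split


def build_splits(alignments: Sequence[ReadAlignment], contigs: ContigSet,
                 null_barcode: str = "0_0_0") -> dict[str, HeadTailSplit]:
    """Head/tail splits for every contig, in one pass over the alignments."""
    splits = {c.id: HeadTailSplit(c.id) for c in contigs}
    mids = {c.id: c.length // 2 for c in contigs}
    for aln in alignments:
        if not aln.is_unique or not aln.barcode:
            continue
        if aln.barcode == null_barcode:
            continue
        s = splits[aln.contig_id]
        (s.head if aln.position < mids[aln.contig_id] else s.tail).add(
            aln.barcode)
    return splits


def neighbor_vote(target: HeadTailSplit, neighbor: HeadTailSplit,
                  side: str) -> str:
    """One neighbour's orientation vote for the target contig.

    ``side`` is 'preceding' or 'following' (the neighbour's position relative
    to the target in the ordered scaffold).  The neighbour contributes its
    pooled barcode set; the target's head/tail asymmetry decides the vote.
    """
    if side not in ("preceding", "following"):
        raise ValueError(f"side must be 'preceding' or 'following', "
                         f"got {side!r}")
    facing = neighbor.all_barcodes
    js_head = jaccard_bins(target.head, facing)
    js_tail = jaccard_bins(target.tail, facing)
    if js_head == js_tail:
        return ABSTAIN
    head_closer = js_head > js_tail
    if side == "preceding":
        return UP if head_closer else DOWN
    return DOWN if head_closer else UP


@dataclass
class OrientedScaffold:
    """Ordered scaffold with per-contig orientation and vote records."""

    parts: list[tuple[str, str]]          # (contig_id, UP or DOWN)
    votes: dict[str, tuple[int, int, int]] = field(default_factory=dict)
    low_confidence: set[str] = field(default_factory=set)
    branch_id: int = -1

    def contig_ids(self) -> list[str]:
        return [cid for cid, _ in self.parts]


def orient_scaffold(ordered: OrderedScaffold,
                    splits: dict[str, HeadTailSplit],
                    window: int = 3) -> OrientedScaffold:
    """Assign up/down states to every contig of an ordered scaffold.

    Votes come from up to ``window`` neighbours on each side; the majority of
    non-abstaining votes wins.  An overall tie (including the no-neighbour
    singleton case) resolves to "up" and flags the contig low-confidence.
    """
    ids = ordered.contig_ids
    out = OrientedScaffold(parts=[], branch_id=ordered.branch_id)
    for i, cid in enumerate(ids):
        target = splits[cid]
        up = down = abstain = 0
        for j in range(max(0, i - window), i):
            v = neighbor_vote(target, splits[ids[j]], "preceding")
            up, down, abstain = _tally(v, up, down, abstain)
        for j in range(i + 1, min(len(ids), i + 1 + window)):
            v = neighbor_vote(target, splits[ids[j]], "following")
            up, down, abstain = _tally(v, up, down, abstain)
        if up > down:
            orientation = UP
        elif down > up:
            orientation = DOWN
        else:
            orientation = UP
            out.low_confidence.add(cid)
        out.parts.append((cid, orientation))
        out.votes[cid] = (up, down, abstain)
    return out


def _tally(vote: str, up: int, down: int, abstain: int):
    if vote == UP:
        return up + 1, down, abstain
    if vote == DOWN:
        return up, down + 1, abstain
    return up, down, abstain + 1
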
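"""Synthetic stLFR-like datasets with ground truth.

The generator emulates the study conditions of a single-tube long fragment
read (stLFR) library over a random genome: long DNA fragments drawn
uniformly at random, (ideally) one fragment per barcode, read pairs sparsely
sampled along each fragment with a non-Gaussian insert-size distribution,
plus a fragmented "draft assembly" of the genome with optional chimeric
(misassembled) contigs and collapsed repeats, and a truth map recording each
contig's genome coordinates.  Reads are emitted directly as an alignment
table via the truth map (aligner-free path), with an optional FASTQ writer
for end-to-end runs through a real aligner.

Default parameter choices mirror a sequenced stLFR library: ~50 kb
fragments, one fragment per barcode, one read pair every 2.5 kb of fragment
(the observed spacing between neighbouring same-fragment reads), and an
insert-size mixture of a narrow ~250 bp mode with a long tail.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .io_formats import Contig, ContigSet, ReadAlignment, reverse_complement

_ALPHABET = np.frombuffer(b"ACGT", dtype=np.uint8)


# ---------------------------------------------------------------------------
# Parameters and truth
# ---------------------------------------------------------------------------

@dataclass
class SimParams:
    """Study conditions of the simulated library and draft assembly."""

    genome_length: int = 2_000_000
    contig_mean_length: int = 10_000
    contig_min_length: int = 2_000
    chimera_rate: float = 0.0
    n_repeat_contigs: int = 0
    flip_prob: float = 0.5            # P(contig stored reverse-complemented)
    fragment_mean_length: int = 50_000
    fragment_shape: float = 3.0       # gamma shape; size-selected HMW DNA
    fragment_min_length: int = 1_000
    fragment_coverage: float = 10.0
    fragments_per_barcode: int = 1
    read_length: int = 100
    read_pairs_per_kb: float = 2.0
    insert_mode: float = 350.0        # narrow component of the insert mix
    insert_mode_sd: float = 35.0
    insert_tail_weight: float = 0.2   # long-tailed component weight
    insert_tail_sigma: float = 0.6    # lognormal sigma of the tail
    insert_max: int = 3000
    rng_seed: int = 1

    def __post_init__(self) -> None:
        if not (0.0 <= self.chimera_rate < 1.0):
            raise ValueError("chimera_rate must be in [0, 1)")
        for name in ("genome_length", "contig_mean_length",
                     "fragment_mean_length", "read_length"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class TruthRecord:
    """Genome provenance of one simulated contig.

    ``intervals`` holds (start, end, strand) pieces in contig order
    (one for ordinary contigs, two for chimeras).  ``donor`` is the second
    genome copy of a collapsed repeat.
    """

    contig_id: str
    intervals: list[tuple[int, int, str]]
    is_chimeric: bool = False
    is_repeat: bool = False
    donor: Optional[tuple[int, int]] = None

    @property
    def primary(self) -> tuple[int, int, str]:
        return self.intervals[0]

    @property
    def length(self) -> int:
        return sum(e - s for s, e, _ in self.intervals)


class TruthMap:
    """Per-contig genome coordinates of a simulated draft assembly."""

    def __init__(self, genome_length: int) -> None:
        self.genome_length = genome_length
        self.records: dict[str, TruthRecord] = {}

    def add(self, rec: TruthRecord) -> None:
        self.records[rec.contig_id] = rec

    def __getitem__(self, cid: str) -> TruthRecord:
        return self.records[cid]

    def __contains__(self, cid: str) -> bool:
        return cid in self.records

    def ordered_non_chimeric(self) -> list[TruthRecord]:
        """Non-chimeric records sorted by primary interval start."""
        recs = [r for r in self.records.values() if not r.is_chimeric]
        return sorted(recs, key=lambda r: r.primary[0])

    def write_tsv(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write("#contig\tintervals\tchimeric\trepeat\tdonor\t"
                     f"genome_length={self.genome_length}\n")
            for cid in sorted(self.records):
                r = self.records[cid]
                ivs = ";".join(f"{s}-{e}:{st}" for s, e, st in r.intervals)
                donor = f"{r.donor[0]}-{r.donor[1]}" if r.donor else ""
                fh.write(f"{cid}\t{ivs}\t{int(r.is_chimeric)}\t"
                         f"{int(r.is_repeat)}\t{donor}\n")

    @classmethod
    def read_tsv(cls, path: str) -> "TruthMap":
        with open(path) as fh:
            header = fh.readline()
            genome_length = int(header.rstrip().rsplit("genome_length=")[1])
            truth = cls(genome_length)
            for line in fh:
                cid, ivs, chim, rep, donor = line.rstrip("\n").split("\t")
                intervals = []
                for piece in ivs.split(";"):
                    span, strand = piece.split(":")
                    s, e = span.split("-")
                    intervals.append((int(s), int(e), strand))
                truth.add(TruthRecord(
                    contig_id=cid, intervals=intervals,
                    is_chimeric=bool(int(chim)), is_repeat=bool(int(rep)),
                    donor=(tuple(int(x) for x in donor.split("-"))
                           if donor else None)))
        return truth


# ---------------------------------------------------------------------------
# Genome and assembly
# ---------------------------------------------------------------------------

def simulate_genome(params: SimParams,
                    rng: Optional[np.random.Generator] = None) -> str:
    """Uniform random nucleotide string of ``genome_length``."""
    rng = rng or np.random.default_rng(params.rng_seed)
    idx = rng.integers(0, 4, size=params.genome_length)
    return _ALPHABET[idx].tobytes().decode("ascii")


def simulate_assembly(genome: str, params: SimParams,
                      rng: Optional[np.random.Generator] = None,
                      ) -> tuple[ContigSet, TruthMap]:
    """Fragment the genome into a draft assembly with known truth.

    The genome is cut into contigs with lengths drawn around
    ``contig_mean_length``; each contig is reverse-complemented with
    probability ``flip_prob`` (strand '-').  With probability
    ``chimera_rate`` a contig is made chimeric by concatenating it with a
    distant interval (consuming that interval's own contig); collapsed
    repeats merge two distant same-length intervals into one contig that
    receives reads from both.  Contigs are shuffled and renamed.
    """
    rng = rng or np.random.default_rng(params.rng_seed)
    glen = len(genome)
    # cut points
    intervals: list[tuple[int, int]] = []
    pos = 0
    sd = 0.3 * params.contig_mean_length
    while pos < glen:
        size = int(rng.normal(params.contig_mean_length, sd))
        size = max(params.contig_min_length, size)
        end = min(pos + size, glen)
        if glen - end < params.contig_min_length:
            end = glen
        intervals.append((pos, end))
        pos = end

    n = len(intervals)
    consumed = np.zeros(n, dtype=bool)
    truth = TruthMap(glen)
    contigs: list[Contig] = []
    records: list[TruthRecord] = []

    # chimeras: pair interval i with a distant interval j; both consumed
    chimera_flags = rng.random(n) < params.chimera_rate
    for i in range(n):
        if consumed[i] or not chimera_flags[i]:
            continue
        distant = [j for j in range(n)
                   if not consumed[j] and j != i
                   and abs(intervals[j][0] - intervals[i][0]) > 5 *
                   params.contig_mean_length]
        if not distant:
            continue
        j = distant[rng.integers(0, len(distant))]
        consumed[i] = consumed[j] = True
        strand_j = "-" if rng.random() < 0.5 else "+"
        records.append(TruthRecord(
            contig_id="", is_chimeric=True,
            intervals=[(intervals[i][0], intervals[i][1], "+"),
                       (intervals[j][0], intervals[j][1], strand_j)]))

    # collapsed repeats: contig R also receives reads from a distant donor
    free = [i for i in range(n) if not consumed[i]]
    n_rep = min(params.n_repeat_contigs, max(0, len(free) // 2 - 1))
    for _ in range(n_rep):
        free = [i for i in range(n) if not consumed[i]]
        if len(free) < 2:
            break
        i = int(free[rng.integers(0, len(free))])
        distant = [j for j in free if j != i
                   and abs(intervals[j][0] - intervals[i][0]) > 5 *
                   params.contig_mean_length]
        if not distant:
            break
        j = int(distant[rng.integers(0, len(distant))])
        consumed[i] = consumed[j] = True
        li = intervals[i][1] - intervals[i][0]
        donor = (intervals[j][0], min(intervals[j][1],
                                      intervals[j][0] + li))
        records.append(TruthRecord(
            contig_id="", is_repeat=True, donor=donor,
            intervals=[(intervals[i][0], intervals[i][1], "+")]))

    for i in range(n):
        if not consumed[i]:
            records.append(TruthRecord(
                contig_id="", intervals=[(intervals[i][0], intervals[i][1],
                                          "+")]))

    # random global flips, shuffle, rename
    order = rng.permutation(len(records))
    for rank, k in enumerate(order):
        rec = records[k]
        cid = f"ctg{rank:05d}"
        rec.contig_id = cid
        if rng.random() < params.flip_prob:
            rec.intervals = [(s, e, "-" if st == "+" else "+")
                             for s, e, st in reversed(rec.intervals)]
        seq = "".join(
            genome[s:e] if st == "+" else reverse_complement(genome[s:e])
            for s, e, st in rec.intervals)
        contigs.append(Contig(id=cid, length=len(seq), sequence=seq))
        truth.add(rec)
    return ContigSet(contigs), truth


# ---------------------------------------------------------------------------
# Fragments and reads
# ---------------------------------------------------------------------------

def _sample_inserts(n: int, params: SimParams,
                    rng: np.random.Generator) -> np.ndarray:
    """Non-Gaussian insert sizes: narrow mode plus lognormal tail."""
    narrow = rng.normal(params.insert_mode, params.insert_mode_sd, size=n)
    tail = params.insert_mode * np.exp(
        rng.normal(0.5, params.insert_tail_sigma, size=n))
    pick_tail = rng.random(n) < params.insert_tail_weight
    inserts = np.where(pick_tail, tail, narrow)
    lo = 2 * params.read_length + 1
    return np.clip(inserts, lo, params.insert_max).astype(np.int64)


def simulate_reads(truth: TruthMap, params: SimParams,
                   rng: Optional[np.random.Generator] = None,
                   ) -> list[ReadAlignment]:
    """Generate barcoded read pairs and project them onto contigs.

    Fragments are placed uniformly on the genome at ``fragment_coverage``
    total coverage with exponentially distributed lengths; each fragment
    receives a Poisson number of read pairs proportional to its length.
    Read genome coordinates are projected through the truth map, so reads on
    chimeric junctions follow the chimeric coordinates and reads inside a
    repeat's donor interval map onto the collapsed repeat contig.  Reads
    falling across a contig boundary (not fully inside any truth interval)
    are dropped, as an aligner would clip or reject them.
    """
    rng = rng or np.random.default_rng(params.rng_seed)
    glen = truth.genome_length
    n_frags = int(round(params.fragment_coverage * glen /
                        params.fragment_mean_length))
    frag_lens = np.maximum(
        rng.gamma(params.fragment_shape,
                  params.fragment_mean_length / params.fragment_shape,
                  size=n_frags),
        params.fragment_min_length).astype(np.int64)
    frag_starts = rng.integers(0, glen, size=n_frags)
    frag_lens = np.minimum(frag_lens, glen - frag_starts)

    # barcode assignment: consecutive fragments share one barcode when
    # fragments_per_barcode > 1
    fpb = max(1, params.fragments_per_barcode)
    barcodes = [f"{1 + i // fpb}_0_0" for i in range(n_frags)]

    # generate pair coordinates on the genome
    gstarts: list[int] = []
    ginserts: list[int] = []
    pair_barcode: list[str] = []
    n_pairs_per_frag = rng.poisson(
        params.read_pairs_per_kb * frag_lens / 1000.0)
    for i in range(n_frags):
        k = int(n_pairs_per_frag[i])
        if k == 0:
            continue
        inserts = _sample_inserts(k, params, rng)
        inserts = np.minimum(inserts, frag_lens[i])
        offs = (rng.random(k) * (frag_lens[i] - inserts + 1)).astype(np.int64)
        for off, ins in zip(offs, inserts):
            gstarts.append(int(frag_starts[i] + off))
            ginserts.append(int(ins))
            pair_barcode.append(barcodes[i])

    # project onto contigs via the truth map
    rl = params.read_length
    # Build projection pieces: (gstart, gend, contig, offset_in_contig, strand)
    pieces: list[tuple[int, int, str, int, str]] = []
    for cid in sorted(truth.records):
        rec = truth.records[cid]
        off = 0
        for s, e, st in rec.intervals:
            pieces.append((s, e, cid, off, st))
            off += e - s
        if rec.donor is not None:
            ds, de = rec.donor
            # donor aligns to the primary interval of the collapsed repeat
            s, e, st = rec.primary
            off0 = 0  # primary is always the first interval
            pieces.append((ds, de, cid, off0, st))
    pieces.sort()
    piece_starts = np.array([p[0] for p in pieces])

    alignments: list[ReadAlignment] = []
    pair_id = 0
    for gstart, insert, barcode in zip(gstarts, ginserts, pair_barcode):
        r1 = (gstart, "+")                      # leftmost mate, forward
        r2 = (gstart + insert - rl, "-")        # rightmost mate, reverse
        name = f"p{pair_id}"
        placed = []
        for mate_no, (gpos, strand) in enumerate((r1, r2), start=1):
            hits = _project(gpos, rl, pieces, piece_starts)
            placed.append((mate_no, gpos, strand, hits))
        ids = {1: f"{name}/1", 2: f"{name}/2"}
        for mate_no, gpos, strand, hits in placed:
            for contig_id, cpos, piece_strand in hits:
                alignments.append(ReadAlignment(
                    read_id=ids[mate_no], barcode=barcode,
                    contig_id=contig_id, position=cpos,
                    strand=_orient_strand(strand, piece_strand),
                    mate_read_id=ids[3 - mate_no], is_unique=True))
        pair_id += 1
    return alignments


def _project(gpos: int, read_length: int, pieces, piece_starts):
    """Map a genome read interval onto all containing truth pieces.

    Returns (contig_id, contig_position, piece_strand) hits; the caller
    combines the piece strand with the read's own genome strand.
    """
    import bisect

    hits = []
    idx = bisect.bisect_right(piece_starts, gpos) - 1
    if idx >= 0:
        s, e, cid, off, st = pieces[idx]
        if s <= gpos and gpos + read_length <= e:
            if st == "+":
                cpos = off + (gpos - s)
            else:
                cpos = off + (e - (gpos + read_length))
            hits.append((cid, cpos, st))
    return hits


def _flip(strand: str) -> str:
    return "-" if strand == "+" else "+"


# reads on '-' truth pieces flip their strand on the contig
def _orient_strand(read_strand: str, piece_strand: str) -> str:
    return read_strand if piece_strand == "+" else _flip(read_strand)


def write_fastq(alignments: list[ReadAlignment], contigs: ContigSet,
                path_r1: str, path_r2: str, read_length: int,
                separator: str = "#") -> None:
    """Emit paired FASTQ with stLFR-style ``name#barcode`` read names.

    Sequences are reconstructed from the contig sequences at the aligned
    positions (error-free).
    """
    by_id = {}
    for a in alignments:
        by_id.setdefault(a.read_id, a)
    with open(path_r1, "w") as f1, open(path_r2, "w") as f2:
        for rid in sorted(by_id):
            a = by_id[rid]
            if not rid.endswith("/1"):
                continue
            mate = by_id.get(a.mate_read_id)
            if mate is None:
                continue
            for fh, aln in ((f1, a), (f2, mate)):
                seq = contigs[aln.contig_id].sequence[
                    aln.position:aln.position + read_length]
                if aln.strand == "-":
                    seq = reverse_complement(seq)
                base = aln.read_id.rsplit("/", 1)[0]
                fh.write(f"@{base}{separator}{aln.barcode}\n{seq}\n+\n"
                         f"{'I' * len(seq)}\n")


def simulate_dataset(params: SimParams,
                     ) -> tuple[str, ContigSet, TruthMap,
                                list[ReadAlignment]]:
    """One-call generation of genome, assembly, truth and alignments.

    Identical ``params`` (including ``rng_seed``) give byte-identical
    outputs.
    """
    rng = np.random.default_rng(params.rng_seed)
    genome = simulate_genome(params, rng)
    contigs, truth = simulate_assembly(genome, params, rng)
    alignments = simulate_reads(truth, params, rng)
    return genome, contigs, truth, alignments
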
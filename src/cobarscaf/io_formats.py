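"""Input/output and run configuration.

Reads draft-assembly contigs (FASTA) and barcode-tagged read alignments
(SAM/BAM or a plain tab-separated table), and writes finished scaffolds as
FASTA plus AGP v2.1.  Internal coordinates are 0-based half-open throughout;
only the AGP writer converts to the 1-based inclusive convention the format
requires.

Barcodes follow the stLFR convention of a suffix on the read name after a
separator character (``read123#45_67_89``); a per-read alignment tag (``BX``)
is supported as a fallback for other linked-read chemistries.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field, fields, replace
from typing import Iterable, Optional, Sequence

import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

log = logging.getLogger("cobarscaf")

_COMPLEMENT = str.maketrans("ACGTacgtNn", "TGCAtgcaNn")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class Contig:
    """A draft-assembly sequence with bookkeeping used for seed selection.

    ``depth`` is mean unique-read coverage (reads x read_length / length),
    dimensionless; ``is_seed`` marks contigs admitted to the global scaffold
    graph.
    """

    id: str
    length: int
    sequence: Optional[str] = None
    depth: float = 0.0
    is_seed: bool = False

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValueError(f"contig {self.id}: length must be >= 1")
        if self.sequence is not None and len(self.sequence) != self.length:
            raise ValueError(f"contig {self.id}: sequence/length mismatch")


class ContigSet:
    """Ordered mapping of contig id -> :class:`Contig`."""

    def __init__(self, contigs: Iterable[Contig] = ()) -> None:
        self._contigs: dict[str, Contig] = {}
        for c in contigs:
            self.add(c)

    def add(self, contig: Contig) -> None:
        if contig.id in self._contigs:
            raise ValueError(f"duplicate contig id: {contig.id}")
        self._contigs[contig.id] = contig

    def __getitem__(self, cid: str) -> Contig:
        return self._contigs[cid]

    def __contains__(self, cid: str) -> bool:
        return cid in self._contigs

    def __iter__(self):
        return iter(self._contigs.values())

    def __len__(self) -> int:
        return len(self._contigs)

    def ids(self) -> list[str]:
        return list(self._contigs)


@dataclass
class ReadAlignment:
    """One read aligned to one contig, carrying its co-barcoding barcode.

    ``position`` is the 0-based leftmost coordinate on the contig. Reads that
    fail the uniqueness filter keep ``is_unique=False`` and are excluded from
    barcode indexing but may still contribute paired-end links.
    """

    read_id: str
    barcode: str
    contig_id: str
    position: int
    strand: str  # '+' or '-'
    mate_read_id: Optional[str] = None
    is_unique: bool = True


@dataclass
class RunConfig:
    """All tunable parameters of the scaffolding pipeline.

    Defaults follow the stLFR working point: 5 kb bins for barcode-set
    Jaccard similarity, a 7 kb seed length threshold, and the fixed 11 bp
    gap for junctions established by paired-end evidence alone.
    """

    bin_size: int = 5000
    js_threshold: float = 0.1
    seed_min_length: int = 7000
    depth_window: tuple[float, float] = (0.5, 1.5)
    screen_iteration_cap: int = 5
    screen_removal_ratio_cap: float = 0.02
    pe_min_support: int = 3
    pe_gap_size: int = 11
    minhash_ratio: float = 1.0
    rng_seed: int = 1
    mapq_min: int = 30
    read_length: int = 100
    barcode_separator: str = "#"
    barcode_tag: str = "BX"
    null_barcode: str = "0_0_0"
    multimap_mode: str = "mapq"  # 'mapq' or 'xa'
    min_barcode_union: int = 10
    keep_middle_bin: bool = True
    orient_window: int = 3
    candidate_js_threshold: Optional[float] = None  # default: js_threshold/2
    max_path_nodes: int = 5
    pe_max_end_distance: int = 1000
    calib_max_distance: int = 50_000
    calib_bucket_width: Optional[int] = None  # default: bin_size
    calib_noise_floor: float = 0.02
    gap_min: int = 1
    gap_max: Optional[int] = None  # default: 2 * calib_max_distance
    default_gap_size: int = 100

    def __post_init__(self) -> None:
        if self.bin_size <= 0 or self.seed_min_length <= 0:
            raise ValueError("bin_size and seed_min_length must be positive")
        if not (0.0 < self.minhash_ratio <= 1.0):
            raise ValueError("minhash_ratio must be in (0, 1]")
        if self.depth_window[0] >= self.depth_window[1]:
            raise ValueError("depth_window must be (lo, hi) with lo < hi")
        if self.candidate_js_threshold is None:
            self.candidate_js_threshold = self.js_threshold / 2.0
        if self.calib_bucket_width is None:
            self.calib_bucket_width = self.bin_size
        if self.gap_max is None:
            self.gap_max = 2 * self.calib_max_distance

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "depth_window" in data:
            data["depth_window"] = tuple(data["depth_window"])
        return cls(**data)

    def to_yaml(self, path: str) -> None:
        data = {f.name: getattr(self, f.name) for f in fields(self)}
        data["depth_window"] = list(self.depth_window)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)

    def updated(self, **kwargs) -> "RunConfig":
        return replace(self, **kwargs)


# ---------------------------------------------------------------------------
# Scaffold records (shared by ordering/orienting/local/gap stages)
# ---------------------------------------------------------------------------

GAP_COBARCODE = "cobarcode"
GAP_PAIRED_END = "paired_end"


@dataclass
class ScaffoldGap:
    size: int = -1  # -1 until gap estimation has run
    kind: str = GAP_COBARCODE


@dataclass
class ScaffoldRecord:
    """An oriented scaffold: contig runs with typed gaps between them.

    ``parts[i]`` is (contig_id, orientation) with orientation '+'
    (same direction as the scaffold) or '-'; ``gaps[i]`` sits between
    ``parts[i]`` and ``parts[i+1]``.
    """

    name: str
    parts: list[tuple[str, str]]
    gaps: list[ScaffoldGap] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.parts:
            raise ValueError("scaffold must contain at least one contig")
        if not self.gaps:
            self.gaps = [ScaffoldGap() for _ in range(len(self.parts) - 1)]
        if len(self.gaps) != len(self.parts) - 1:
            raise ValueError("need exactly len(parts)-1 gaps")

    def contig_ids(self) -> list[str]:
        return [cid for cid, _ in self.parts]

    def span(self, contigs: ContigSet) -> int:
        total = sum(contigs[cid].length for cid, _ in self.parts)
        total += sum(max(g.size, 0) for g in self.gaps)
        return total


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_contigs(fasta_path: str) -> ContigSet:
    """Read a contig FASTA into a :class:`ContigSet`.

    Lengths come from the sequences; depth starts at 0 and ``is_seed`` False.
    Duplicate ids raise.
    """
    contigs = ContigSet()
    for rec in SeqIO.parse(fasta_path, "fasta"):
        seq = str(rec.seq).upper()
        if not seq:
            raise ValueError(f"contig {rec.id}: empty sequence")
        contigs.add(Contig(id=rec.id, length=len(seq), sequence=seq))
    return contigs


def write_contigs(contigs: ContigSet, fasta_path: str) -> None:
    records = []
    for c in contigs:
        if c.sequence is None:
            raise ValueError(f"contig {c.id} has no sequence")
        records.append(SeqRecord(Seq(c.sequence), id=c.id, description=""))
    SeqIO.write(records, fasta_path, "fasta")


# ---------------------------------------------------------------------------
# Alignments
# ---------------------------------------------------------------------------

def _parse_barcode(read_name: str, separator: str) -> tuple[str, Optional[str]]:
    """Split an stLFR-style read name into (bare name, barcode or None)."""
    if separator in read_name:
        name, _, barcode = read_name.rpartition(separator)
        return name, (barcode or None)
    return read_name, None


def read_alignments(
    path: str,
    barcode_separator: str = "#",
    mapq_min: int = 30,
    barcode_tag: str = "BX",
    multimap_mode: str = "mapq",
    contigs: Optional[ContigSet] = None,
) -> list[ReadAlignment]:
    """Read barcode-tagged alignments from SAM/BAM or a TSV table.

    Dispatch is by file extension (``.sam``/``.bam`` -> pysam, anything else
    -> TSV with columns read_id, barcode, contig, position, strand,
    mate_read_id[, mapq]).  Records below ``mapq_min``, secondary or
    supplementary records, or (with ``multimap_mode='xa'``) records carrying
    an XA multi-hit tag are marked ``is_unique=False``.  Records with no
    barcode in the name and no tag are skipped with a counted warning.
    """
    ext = os.path.splitext(path)[1].lower()
    if ext in (".sam", ".bam"):
        alignments = _read_sam(path, barcode_separator, mapq_min, barcode_tag,
                               multimap_mode)
    else:
        alignments = _read_tsv(path, mapq_min)
    if contigs is not None:
        for aln in alignments:
            if aln.contig_id not in contigs:
                raise ValueError(f"alignment references unknown contig "
                                 f"{aln.contig_id!r}")
            if not (0 <= aln.position < contigs[aln.contig_id].length):
                raise ValueError(
                    f"read {aln.read_id}: position {aln.position} outside "
                    f"contig {aln.contig_id}")
    return alignments


def _read_sam(path, separator, mapq_min, barcode_tag, multimap_mode):
    import pysam

    alignments: list[ReadAlignment] = []
    skipped = 0
    mode = "rb" if path.endswith(".bam") else "r"
    with pysam.AlignmentFile(path, mode, check_sq=False) as fh:
        for rec in fh:
            if rec.is_unmapped:
                continue
            name, barcode = _parse_barcode(rec.query_name, separator)
            if barcode is None and rec.has_tag(barcode_tag):
                barcode = str(rec.get_tag(barcode_tag))
            if barcode is None:
                skipped += 1
                continue
            unique = (not rec.is_secondary and not rec.is_supplementary
                      and rec.mapping_quality >= mapq_min)
            if multimap_mode == "xa" and rec.has_tag("XA"):
                unique = False
            mate = None
            if rec.is_paired:
                suffix = "/2" if rec.is_read1 else "/1"
                own = "/1" if rec.is_read1 else "/2"
                mate = name + suffix
                name = name + own
            alignments.append(ReadAlignment(
                read_id=name, barcode=barcode,
                contig_id=rec.reference_name, position=rec.reference_start,
                strand="-" if rec.is_reverse else "+",
                mate_read_id=mate, is_unique=unique))
    if skipped:
        log.warning("read_alignments: %d records without barcode skipped",
                    skipped)
    return alignments


def _read_tsv(path, mapq_min):
    alignments: list[ReadAlignment] = []
    skipped = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 6:
                raise ValueError(f"{path}:{lineno}: expected >= 6 columns")
            read_id, barcode, contig, pos, strand, mate = cols[:6]
            if not barcode:
                skipped += 1
                continue
            mapq = int(cols[6]) if len(cols) > 6 else 60
            if strand not in "+-":
                raise ValueError(f"{path}:{lineno}: bad strand {strand!r}")
            alignments.append(ReadAlignment(
                read_id=read_id, barcode=barcode, contig_id=contig,
                position=int(pos), strand=strand,
                mate_read_id=mate or None, is_unique=mapq >= mapq_min))
    if skipped:
        log.warning("read_alignments: %d records without barcode skipped",
                    skipped)
    return alignments


def write_alignments_tsv(alignments: Sequence[ReadAlignment], path: str,
                         mapq_unique: int = 60) -> None:
    """Write the plain TSV alignment table the pipeline consumes."""
    with open(path, "w") as fh:
        for a in alignments:
            mapq = mapq_unique if a.is_unique else 0
            fh.write("\t".join([
                a.read_id, a.barcode, a.contig_id, str(a.position), a.strand,
                a.mate_read_id or "", str(mapq)]) + "\n")


# ---------------------------------------------------------------------------
# Scaffold output: FASTA + AGP v2.1
# ---------------------------------------------------------------------------

_GAP_EVIDENCE = {GAP_PAIRED_END: "paired-ends",
                 GAP_COBARCODE: "proximity_ligation"}
_EVIDENCE_GAP = {v: k for k, v in _GAP_EVIDENCE.items()}


def render_scaffold_sequence(scaffold: ScaffoldRecord,
                             contigs: ContigSet) -> str:
    """Build the scaffold nucleotide sequence, gaps rendered as N runs."""
    pieces: list[str] = []
    for i, (cid, orient) in enumerate(scaffold.parts):
        contig = contigs[cid]
        if contig.sequence is None:
            raise ValueError(f"contig {cid} has no sequence")
        seq = contig.sequence if orient == "+" else reverse_complement(
            contig.sequence)
        pieces.append(seq)
        if i < len(scaffold.gaps):
            size = scaffold.gaps[i].size
            if size < 0:
                raise ValueError(
                    f"scaffold {scaffold.name}: gap {i} has no size")
            pieces.append("N" * size)
    return "".join(pieces)


def write_scaffolds(scaffolds: Sequence[ScaffoldRecord], contigs: ContigSet,
                    out_fasta: str, out_agp: str) -> None:
    """Write scaffolds as FASTA plus AGP v2.1.

    AGP coordinates are 1-based inclusive; gap lines are typed ``scaffold``
    with linkage evidence ``paired-ends`` for paired-end junctions and
    ``proximity_ligation`` for co-barcode junctions.
    """
    seen: set[str] = set()
    for s in scaffolds:
        for cid, _ in s.parts:
            if cid in seen:
                raise ValueError(f"contig {cid} appears in two scaffolds")
            seen.add(cid)

    records = []
    with open(out_agp, "w") as agp:
        agp.write("##agp-version\t2.1\n")
        for s in scaffolds:
            seq = render_scaffold_sequence(s, contigs)
            records.append(SeqRecord(Seq(seq), id=s.name, description=""))
            pos = 0  # 0-based cursor on the scaffold
            part_no = 1
            for i, (cid, orient) in enumerate(s.parts):
                length = contigs[cid].length
                agp.write("\t".join([
                    s.name, str(pos + 1), str(pos + length), str(part_no),
                    "W", cid, "1", str(length), orient]) + "\n")
                pos += length
                part_no += 1
                if i < len(s.gaps):
                    gap = s.gaps[i]
                    if gap.size > 0:
                        agp.write("\t".join([
                            s.name, str(pos + 1), str(pos + gap.size),
                            str(part_no), "N", str(gap.size), "scaffold",
                            "yes", _GAP_EVIDENCE[gap.kind]]) + "\n")
                        pos += gap.size
                        part_no += 1
    SeqIO.write(records, out_fasta, "fasta")


def read_agp(path: str) -> list[ScaffoldRecord]:
    """Parse an AGP v2.1 file back into :class:`ScaffoldRecord` objects."""
    scaffolds: dict[str, ScaffoldRecord] = {}
    order: list[str] = []
    pending_gap: dict[str, ScaffoldGap] = {}
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            cols = line.rstrip("\n").split("\t")
            name, comp_type = cols[0], cols[4]
            if name not in scaffolds:
                if comp_type in ("N", "U"):
                    raise ValueError(f"scaffold {name} begins with a gap")
                scaffolds[name] = ScaffoldRecord(name=name,
                                                 parts=[(cols[5], cols[8])],
                                                 gaps=[])
                order.append(name)
                continue
            rec = scaffolds[name]
            if comp_type in ("N", "U"):
                if name in pending_gap:
                    raise ValueError(f"scaffold {name}: consecutive gaps")
                pending_gap[name] = ScaffoldGap(
                    size=int(cols[5]),
                    kind=_EVIDENCE_GAP.get(cols[8], GAP_COBARCODE))
            else:
                rec.parts.append((cols[5], cols[8]))
                rec.gaps.append(pending_gap.pop(name, ScaffoldGap(size=0)))
    for name, rec in scaffolds.items():
        if len(rec.gaps) != len(rec.parts) - 1:
            raise ValueError(f"scaffold {name}: trailing gap")
    return [scaffolds[n] for n in order]
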
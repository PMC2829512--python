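"""Read placement, per-base depth/pileups, and the mappable-genome mask.

For synthetic data an internal ungapped mapper places reads with at most
``max_mismatches`` substitutions on either strand, using exact full-window
hashing plus a pigeonhole seed search (three non-overlapping seeds cover
any placement with <= 2 mismatches of a 36-mer).  External data enters via
SAM.  Reads with two or more equally good placements are kept but classed
``multi_zero`` and excluded from depth and pileups -- the analogue of
discarding mapping-quality < 10 alignments.  The mappable mask marks
positions whose read-length window occurs exactly once in the genome
counting both strands; depth, SNP and CNV statistics are defined over it.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pysam

from .synthetic_data import Genome, Read, ReadSet, encode_seq, revcomp

UNIQUE_HIGH = "unique_high"
MULTI_ZERO = "multi_zero"

#: chromosome names treated as non-nuclear (excluded from totals/segmentation)
DEFAULT_NON_NUCLEAR = frozenset({"chrm", "chrmt", "mt", "mito", "mitochondrion"})


def is_nuclear(chrom: str, non_nuclear: frozenset[str] = DEFAULT_NON_NUCLEAR) -> bool:
    return chrom.lower() not in non_nuclear


@dataclass(frozen=True)
class Alignment:
    """An ungapped read placement.

    ``start`` is 1-based; ``seq_fwd`` is the read sequence expressed in
    forward-strand (reference) orientation so pileups can consume it
    directly regardless of strand.
    """

    read_id: str
    chrom: str
    start: int
    strand: str
    mismatches: int
    mapq_class: str
    seq_fwd: str

    @property
    def end(self) -> int:
        return self.start + len(self.seq_fwd) - 1


class GenomeIndex:
    """Exact-location lookup for every read-length window of the genome.

    Holds a full-window hash (forward strand; reverse-strand placements are
    found by looking up the reverse complement of the query) and a
    non-overlapping seed hash used for the mismatch-tolerant search.
    """

    def __init__(self, genome: Genome, read_len: int, seed_len: int | None = None):
        if read_len < 12:
            raise ValueError("read_len must be >= 12")
        shortest = min(len(s) for s in genome.sequences.values())
        if read_len > shortest:
            raise ValueError("read_len longer than the shortest chromosome")
        self.genome = genome
        self.read_len = read_len
        self.seed_len = seed_len if seed_len is not None else max(12, read_len // 3)
        self.codes = {c: encode_seq(s) for c, s in genome.sequences.items()}
        self.windows: dict[str, list[tuple[str, int]]] = {}
        self.seeds: dict[str, list[tuple[str, int]]] = {}
        w, k = read_len, self.seed_len
        for chrom, seq in genome.sequences.items():
            for p in range(len(seq) - w + 1):
                self.windows.setdefault(seq[p : p + w], []).append((chrom, p))
            for p in range(len(seq) - k + 1):
                self.seeds.setdefault(seq[p : p + k], []).append((chrom, p))
        # seed offsets covering the read; with 3+ seeds any placement with
        # <= 2 mismatches has at least one exact seed (pigeonhole)
        n_seeds = max(3, -(-read_len // self.seed_len))
        step = (read_len - self.seed_len) / max(1, n_seeds - 1)
        self.seed_offsets = sorted({int(round(i * step)) for i in range(n_seeds)})

    def occurrences(self, window: str) -> int:
        """Occurrence count of a read-length window, counting both strands."""
        if len(window) != self.read_len:
            raise ValueError("window length must equal read_len")
        n = len(self.windows.get(window, ()))
        rc = revcomp(window)
        if rc != window:
            n += len(self.windows.get(rc, ()))
        return n

    def locate_exact(self, window: str) -> list[tuple[str, int, str]]:
        """All exact placements (chrom, 0-based pos, strand) of a window."""
        hits = [(c, p, "+") for c, p in self.windows.get(window, ())]
        hits += [(c, p, "-") for c, p in self.windows.get(revcomp(window), ())]
        return hits


def build_index(genome: Genome, read_len: int) -> GenomeIndex:
    """Build the exact/seed lookup index for a genome at one read length."""
    return GenomeIndex(genome, read_len)


def _count_mismatches(ref_codes: np.ndarray, read_codes: np.ndarray, limit: int) -> int:
    n = int(np.count_nonzero(ref_codes != read_codes))
    return n


def map_read(read: Read, index: GenomeIndex, max_mismatches: int = 2) -> Alignment | None:
    """Best ungapped placement of a read on either strand.

    Returns a ``unique_high`` Alignment for a unique best placement with
    <= max_mismatches, a ``multi_zero`` Alignment when two or more equally
    good placements exist (such reads are excluded from pileups), and
    ``None`` when no placement qualifies.
    """
    seq = read.sequence
    if len(seq) != index.read_len:
        raise ValueError("read length does not match index read_len")

    exact = index.locate_exact(seq)
    if exact:
        candidates = {(c, p, s): 0 for c, p, s in exact}
    else:
        candidates = {}
        rc = revcomp(seq)
        enc = {"+": encode_seq(seq), "-": encode_seq(rc)}
        for strand, s in (("+", seq), ("-", rc)):
            for off in index.seed_offsets:
                for chrom, p in index.seeds.get(s[off : off + index.seed_len], ()):
                    start = p - off
                    key = (chrom, start, strand)
                    if key in candidates or start < 0:
                        continue
                    ref = index.codes[chrom]
                    if start + index.read_len > ref.size:
                        continue
                    mm = _count_mismatches(
                        ref[start : start + index.read_len], enc[strand], max_mismatches
                    )
                    if mm <= max_mismatches:
                        candidates[key] = mm
    if not candidates:
        return None
    best = min(candidates.values())
    hits = sorted(k for k, v in candidates.items() if v == best)
    chrom, pos, strand = hits[0]
    mapq_class = UNIQUE_HIGH if len(hits) == 1 else MULTI_ZERO
    seq_fwd = seq if strand == "+" else revcomp(seq)
    return Alignment(read.id, chrom, pos + 1, strand, best, mapq_class, seq_fwd)


def map_reads(
    reads: Iterable[Read], index: GenomeIndex, max_mismatches: int = 2
) -> tuple[list[Alignment], list[Read]]:
    """Map a read pool; returns (alignments, unmapped reads)."""
    alignments, unmapped = [], []
    for read in reads:
        aln = map_read(read, index, max_mismatches)
        if aln is None:
            unmapped.append(read)
        else:
            alignments.append(aln)
    return alignments, unmapped


# ---------------------------------------------------------------------------
# SAM ingestion
# ---------------------------------------------------------------------------


def read_sam(path: str | Path, mapq_threshold: int = 10) -> tuple[list[Alignment], list[Read]]:
    """Ingest alignments from SAM: mapped records become Alignments (mapping
    quality below ``mapq_threshold`` demoted to multi_zero), unmapped records
    populate the unmapped pool.  Read lengths must be uniform.
    """
    alignments: list[Alignment] = []
    unmapped: list[Read] = []
    length: int | None = None
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for rec in sam:
            seq = rec.query_sequence
            if seq is None:
                raise ValueError(f"SAM record {rec.query_name} has no sequence")
            if length is None:
                length = len(seq)
            elif len(seq) != length:
                raise ValueError("inconsistent read lengths in SAM")
            qual = (
                "".join(chr(q + 33) for q in rec.query_qualities)
                if rec.query_qualities is not None
                else "I" * len(seq)
            )
            if rec.is_unmapped:
                # pysam reports the stored sequence; unmapped records are
                # stored as sequenced
                unmapped.append(Read(rec.query_name, seq.upper(), qual))
                continue
            strand = "-" if rec.is_reverse else "+"
            mapq_class = UNIQUE_HIGH if rec.mapping_quality >= mapq_threshold else MULTI_ZERO
            try:
                nm = int(rec.get_tag("NM"))
            except KeyError:
                nm = 0
            # query_sequence is already reference(forward)-oriented in SAM
            alignments.append(
                Alignment(
                    rec.query_name,
                    rec.reference_name,
                    rec.reference_start + 1,
                    strand,
                    nm,
                    mapq_class,
                    seq.upper(),
                )
            )
    return alignments, unmapped


def write_sam(
    path: str | Path,
    genome: Genome,
    alignments: Sequence[Alignment],
    unmapped: Sequence[Read] = (),
) -> None:
    """Write alignments + unmapped pool as SAM (text)."""
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": c, "LN": len(s)} for c, s in genome.sequences.items()],
    }
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        refs = {c: i for i, c in enumerate(genome.sequences)}
        for aln in alignments:
            rec = pysam.AlignedSegment(out.header)
            rec.query_name = aln.read_id
            rec.query_sequence = aln.seq_fwd
            rec.reference_id = refs[aln.chrom]
            rec.reference_start = aln.start - 1
            rec.cigarstring = f"{len(aln.seq_fwd)}M"
            rec.flag = 16 if aln.strand == "-" else 0
            rec.mapping_quality = 37 if aln.mapq_class == UNIQUE_HIGH else 0
            rec.query_qualities = pysam.qualitystring_to_array("I" * len(aln.seq_fwd))
            rec.set_tag("NM", aln.mismatches)
            out.write(rec)
        for read in unmapped:
            rec = pysam.AlignedSegment(out.header)
            rec.query_name = read.id
            rec.query_sequence = read.sequence
            rec.flag = 4
            rec.reference_id = -1
            rec.reference_start = -1
            rec.mapping_quality = 0
            rec.query_qualities = pysam.qualitystring_to_array(read.quality)
            out.write(rec)


# ---------------------------------------------------------------------------
# Pileups and depth
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PileupColumn:
    chrom: str
    pos: int  # 1-based
    depth: int
    counts: tuple[int, int, int, int]  # A, C, G, T


class Pileup:
    """Per-position base counts from unique-high alignments."""

    def __init__(self, genome: Genome, counts: dict[str, np.ndarray]):
        self.genome = genome
        self.counts = counts  # chrom -> (4, L) int32

    def depth(self, chrom: str) -> np.ndarray:
        return self.counts[chrom].sum(axis=0)

    def column(self, chrom: str, pos: int) -> PileupColumn:
        col = self.counts[chrom][:, pos - 1]
        return PileupColumn(chrom, pos, int(col.sum()), tuple(int(x) for x in col))


@dataclass
class DepthTrack:
    """Integer per-base depth per chromosome for one strain."""

    depth: dict[str, np.ndarray]
    non_nuclear: frozenset[str] = DEFAULT_NON_NUCLEAR

    @property
    def total_nuclear_bases(self) -> int:
        return int(
            sum(arr.sum() for c, arr in self.depth.items() if is_nuclear(c, self.non_nuclear))
        )


def pileup(
    alignments: Iterable[Alignment],
    genome: Genome,
    non_nuclear: frozenset[str] = DEFAULT_NON_NUCLEAR,
) -> tuple[DepthTrack, Pileup]:
    """Accumulate depth and base counts from unique-high alignments only.

    Reverse-strand reads contribute complemented bases at their covered
    positions (their ``seq_fwd`` is already reference-oriented).
    """
    counts = {
        c: np.zeros((4, len(s)), dtype=np.int32) for c, s in genome.sequences.items()
    }
    pos_buf: dict[str, list[np.ndarray]] = {c: [] for c in genome.sequences}
    code_buf: dict[str, list[np.ndarray]] = {c: [] for c in genome.sequences}
    for aln in alignments:
        if aln.mapq_class != UNIQUE_HIGH:
            continue
        if aln.chrom not in counts:
            raise ValueError(f"alignment references unknown chromosome {aln.chrom!r}")
        L = len(aln.seq_fwd)
        if aln.start < 1 or aln.start - 1 + L > counts[aln.chrom].shape[1]:
            raise ValueError("alignment overruns chromosome end")
        pos_buf[aln.chrom].append(np.arange(aln.start - 1, aln.start - 1 + L))
        code_buf[aln.chrom].append(encode_seq(aln.seq_fwd))
    for chrom in counts:
        if pos_buf[chrom]:
            pos = np.concatenate(pos_buf[chrom])
            codes = np.concatenate(code_buf[chrom])
            np.add.at(counts[chrom], (codes, pos), 1)
    pile = Pileup(genome, counts)
    track = DepthTrack(
        {c: counts[c].sum(axis=0).astype(np.int64) for c in counts}, non_nuclear
    )
    return track, pile


@dataclass
class MappabilityMask:
    """Boolean per-position mappability (read-length-window uniqueness)."""

    mask: dict[str, np.ndarray]
    read_len: int

    def __getitem__(self, chrom: str) -> np.ndarray:
        return self.mask[chrom]

    def is_mappable(self, chrom: str, pos: int) -> bool:
        return bool(self.mask[chrom][pos - 1])

    def n_mappable(self, nuclear_only: bool = True) -> int:
        return int(
            sum(
                arr.sum()
                for c, arr in self.mask.items()
                if not nuclear_only or is_nuclear(c)
            )
        )


def mappability_mask(
    genome: Genome, read_len: int, index: GenomeIndex | None = None
) -> MappabilityMask:
    """Position p is mappable iff the read-length window starting at p occurs
    exactly once in the genome counting both strands; windows overrunning the
    chromosome end are unmappable.
    """
    if index is None or index.read_len != read_len:
        index = GenomeIndex(genome, read_len)
    mask = {}
    for chrom, seq in genome.sequences.items():
        m = np.zeros(len(seq), dtype=bool)
        for p in range(len(seq) - read_len + 1):
            m[p] = index.occurrences(seq[p : p + read_len]) == 1
        mask[chrom] = m
    return MappabilityMask(mask, read_len)
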
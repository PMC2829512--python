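"""Breakpoint sequence recovery from unmapped reads.

Unmapped reads are assembled into contigs with a de Bruijn graph, the
contigs are split-aligned to the reference as maximal ungapped local
alignments on either strand, and contigs explained by two alignments are
classified: opposite-strand parts mark an inversion junction, and the
micro-homology overlap is the number of contig bases claimed by both
parts (lenA + lenB - contig length).  Three filters remove
contigs explained by a single region, contigs whose ends land in
unmappable sequence, and contigs not >=90% covered by their alignments.
Wild-type-junction support, a background-rate probability for junction
contigs, and tandem-inversion structure inference complete the module.

The graph is directed over both strands (every read contributes its own
and its reverse-complement k-mers) rather than canonical-collapsed:
inverted-tandem junction contigs contain a sequence and its reverse
complement a few bases apart, and canonical nodes would put a spurious
branch inside every junction contig.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .cnv import Segment
from .mapping import UNIQUE_HIGH, Alignment, MappabilityMask, is_nuclear
from .synthetic_data import Genome, Read, encode_seq, revcomp

DNA = "ACGT"


@dataclass(frozen=True)
class Contig:
    id: str
    sequence: str
    n_reads: int

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class ContigAlignment:
    """An ungapped local alignment of a contig piece to the reference.

    Intervals are 1-based inclusive; ``contig_start/end`` are always in
    forward-contig coordinates, whichever strand the piece aligns to.
    """

    contig_id: str
    contig_start: int
    contig_end: int
    chrom: str
    ref_start: int
    ref_end: int
    strand: str
    identity: float

    @property
    def contig_span(self) -> int:
        return self.contig_end - self.contig_start + 1


@dataclass(frozen=True)
class BreakpointCall:
    contig_id: str
    part_a: ContigAlignment
    part_b: ContigAlignment
    junction_coords: tuple[int, int]  # reference coords of the inner ends
    chrom: str
    orientation: str  # "inverted" | "direct"
    overlap: int  # micro-homology length (nt)
    in_amplification: bool = False


@dataclass
class AmplificationModel:
    segment: Segment | None
    copy_number: float
    left_call: BreakpointCall | None
    right_call: BreakpointCall | None
    wildtype_left: bool
    wildtype_right: bool
    structure: str
    background_p: float | None = None
    evidence: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# De Bruijn assembly
# ---------------------------------------------------------------------------


def _kmers(seq: str, k: int) -> Iterable[str]:
    for i in range(len(seq) - k + 1):
        yield seq[i : i + k]


def assemble_contigs(
    unmapped_reads: Sequence[Read],
    k: int = 21,
    min_contig_len: int = 40,
    min_kmer_count: int = 2,
) -> list[Contig]:
    """Assemble unmapped reads into unitigs.

    Builds a directed de Bruijn graph over both strands, prunes k-mers seen
    fewer than ``min_kmer_count`` times (error suppression), and emits
    maximal unambiguous paths of length >= ``min_contig_len``, deduplicated
    against their reverse complements and ordered by (length desc, sequence).
    """
    reads = list(unmapped_reads)
    if not reads:
        return []
    read_len = len(reads[0].sequence)
    if not 12 <= k < read_len:
        raise ValueError("k must satisfy 12 <= k < read length")

    counts: dict[str, int] = {}
    for read in reads:
        for seq in (read.sequence, revcomp(read.sequence)):
            for km in _kmers(seq, k):
                counts[km] = counts.get(km, 0) + 1
    kept = {km for km, c in counts.items() if c >= min_kmer_count}

    def successors(km: str) -> list[str]:
        suf = km[1:]
        return [suf + b for b in DNA if suf + b in kept]

    def predecessors(km: str) -> list[str]:
        pre = km[:-1]
        return [b + pre for b in DNA if b + pre in kept]

    visited: set[str] = set()
    unitigs: list[str] = []
    for start in sorted(kept):
        if start in visited:
            continue
        # walk backward to the chain start (unique-predecessor chain)
        node = start
        seen_back = {node}
        while True:
            preds = predecessors(node)
            if len(preds) != 1 or len(successors(preds[0])) != 1:
                break
            prev = preds[0]
            if prev in seen_back:  # cycle guard
                break
            node = prev
            seen_back.add(node)
        # walk forward emitting the unitig
        chain = [node]
        visited.add(node)
        while True:
            succs = successors(chain[-1])
            if len(succs) != 1 or len(predecessors(succs[0])) != 1:
                break
            nxt = succs[0]
            if nxt in visited:
                break
            chain.append(nxt)
            visited.add(nxt)
        seq = chain[0] + "".join(km[-1] for km in chain[1:])
        unitigs.append(seq)

    # reverse-complement dedup: keep the lexicographically smaller twin
    canon: dict[str, str] = {}
    for seq in unitigs:
        key = min(seq, revcomp(seq))
        canon.setdefault(key, seq)
    seqs = [s for s in canon.values() if len(s) >= min_contig_len]
    seqs.sort(key=lambda s: (-len(s), s))

    # supporting read counts via shared k-mers
    contig_kmers: list[set[str]] = [set(_kmers(s, k)) | set(_kmers(revcomp(s), k)) for s in seqs]
    supports = [0] * len(seqs)
    for read in reads:
        rk = set(_kmers(read.sequence, k))
        for i, ck in enumerate(contig_kmers):
            if rk & ck:
                supports[i] += 1
    return [
        Contig(f"contig_{i + 1}", seq, supports[i]) for i, seq in enumerate(seqs)
    ]


# ---------------------------------------------------------------------------
# Split ungapped alignment
# ---------------------------------------------------------------------------


class _SeedIndex:
    """Exact seed lookup (forward strand) reused across contigs."""

    def __init__(self, genome: Genome, seed_len: int = 12):
        self.genome = genome
        self.seed_len = seed_len
        self.codes = {c: encode_seq(s) for c, s in genome.sequences.items()}
        self.seeds: dict[str, list[tuple[str, int]]] = {}
        for chrom, seq in genome.sequences.items():
            for p in range(len(seq) - seed_len + 1):
                self.seeds.setdefault(seq[p : p + seed_len], []).append((chrom, p))


_seed_cache: dict[int, _SeedIndex] = {}


def _get_seed_index(genome: Genome) -> _SeedIndex:
    key = id(genome)
    idx = _seed_cache.get(key)
    if idx is None or idx.genome is not genome:
        _seed_cache.clear()
        idx = _SeedIndex(genome)
        _seed_cache[key] = idx
    return idx


def _extend_on_diagonal(
    q: np.ndarray, ref: np.ndarray, q0: int, r0: int, bridge: int = 12
) -> tuple[int, int, int]:
    """Maximal ungapped run through (q0, r0) on one diagonal.

    Extends exact matches in both directions from the seed; a mismatch is
    absorbed only when followed by at least ``bridge`` exact matches.  The
    default is deliberately strict: at an inverted-repeat junction the
    spacer between the arms reads as a near-palindrome, and a lenient
    bridge would let the alignment read through the junction and inflate
    the measured micro-homology (the spacer interior can only supply
    spacer-2 chance matches, so bridge > spacer keeps junctions tight).
    Returns (q_start, q_end_exclusive, n_matches) in query coordinates.
    """
    diag = r0 - q0
    lo = max(0, -diag)
    hi = min(q.size, ref.size - diag)
    eq = q[lo:hi] == ref[lo + diag : hi + diag]
    anchor = q0 - lo
    n_mismatch = 0
    # rightward
    right = anchor
    while True:
        while right < eq.size and eq[right]:
            right += 1
        if right < eq.size and np.all(eq[right + 1 : right + 1 + bridge]) and right + bridge < eq.size:
            n_mismatch += 1
            right += 1
            continue
        break
    # leftward
    left = anchor
    while True:
        while left > 0 and eq[left - 1]:
            left -= 1
        if left > 0 and left - 1 - bridge >= 0 and np.all(eq[left - 1 - bridge : left - 1]):
            n_mismatch += 1
            left -= 1
            continue
        break
    n_match = (right - left) - n_mismatch
    return lo + left, lo + right, n_match


def align_contig(
    contig: Contig,
    genome: Genome,
    min_identity: float = 0.9,
    min_align_len: int = 18,
    seed_len: int = 12,
) -> list[ContigAlignment]:
    """Maximal ungapped local alignments of a contig on both strands with
    identity >= ``min_identity``.

    Seeds every ``seed_len``-mer of the contig against the genome, extends
    each hit along its diagonal to the maximal-scoring ungapped run, and
    keeps one best alignment per (chrom, strand, diagonal).  Alignments
    shorter than ``min_align_len`` are dropped (random seed hits on a
    genome-sized target would otherwise occasionally pass the identity
    threshold).
    """
    index = _get_seed_index(genome)
    n = len(contig.sequence)
    results: dict[tuple[str, str, int], ContigAlignment] = {}
    best_matches: dict[tuple[str, str, int], int] = {}
    for strand in "+-":
        seq = contig.sequence if strand == "+" else revcomp(contig.sequence)
        q = encode_seq(seq)
        seen_diags: set[tuple[str, int]] = set()
        for off in range(0, n - seed_len + 1):
            for chrom, p in index.seeds.get(seq[off : off + seed_len], ()):
                diag = p - off
                if (chrom, diag) in seen_diags:
                    continue
                seen_diags.add((chrom, diag))
                qs, qe, n_match = _extend_on_diagonal(q, index.codes[chrom], off, p)
                length = qe - qs
                if length < min_align_len:
                    continue
                identity = n_match / length
                if identity < min_identity:
                    continue
                key = (chrom, strand, diag)
                if n_match > best_matches.get(key, -1):
                    if strand == "+":
                        c_start, c_end = qs + 1, qe
                    else:  # coordinates in forward-contig orientation
                        c_start, c_end = n - qe + 1, n - qs
                    results[key] = ContigAlignment(
                        contig_id=contig.id,
                        contig_start=c_start,
                        contig_end=c_end,
                        chrom=chrom,
                        ref_start=diag + qs + 1,
                        ref_end=diag + qe,
                        strand=strand,
                        identity=identity,
                    )
                    best_matches[key] = n_match
    # deduplicate identical reference placements found via both strands of a
    # palindromic piece (rare): keep unique (chrom, strand, intervals)
    out = sorted(
        set(results.values()),
        key=lambda a: (a.contig_start, a.contig_end, a.chrom, a.ref_start, a.strand),
    )
    return out


# ---------------------------------------------------------------------------
# Contig filters and classification
# ---------------------------------------------------------------------------


def filter_contigs(
    contigs: Sequence[Contig],
    alignments_by_contig: dict[str, list[ContigAlignment]],
    mask: MappabilityMask,
    min_coverage: float = 0.9,
    full_span_fraction: float = 0.95,
) -> list[tuple[Contig, list[ContigAlignment]]]:
    """Apply the three contig filters.

    Retains contigs that (a) are not fully explained by a single reference
    region, (b) have their end-anchoring alignments landing in mappable
    positions, and (c) have >= ``min_coverage`` of their bases covered by
    the alignments.
    """
    retained = []
    for contig in contigs:
        alns = alignments_by_contig.get(contig.id, [])
        if not alns:
            continue
        n = len(contig.sequence)
        # (a) single full-length explanation
        if any(a.contig_span >= full_span_fraction * n for a in alns):
            continue
        # (c) alignment coverage of the contig
        covered = np.zeros(n, dtype=bool)
        for a in alns:
            covered[a.contig_start - 1 : a.contig_end] = True
        if covered.sum() < min_coverage * n:
            continue
        # (b) end anchors in mappable sequence
        first = min(alns, key=lambda a: a.contig_start)
        last = max(alns, key=lambda a: a.contig_end)
        left_ref = first.ref_start if first.strand == "+" else first.ref_end
        right_ref = last.ref_end if last.strand == "+" else last.ref_start
        ok = True
        for a, ref_pos in ((first, left_ref), (last, right_ref)):
            pos0 = min(ref_pos - 1, mask[a.chrom].size - 1)
            if not mask[a.chrom][pos0]:
                ok = False
        if not ok:
            continue
        retained.append((contig, alns))
    return retained


def classify_breakpoint(
    contig: Contig,
    alignments: Sequence[ContigAlignment],
    segment: Segment | None = None,
) -> BreakpointCall:
    """Classify a two-part contig: orientation from the strand pair, the
    micro-homology overlap from the contig-interval lengths, and junction
    coordinates from the inner alignment ends."""
    if len(alignments) != 2:
        raise ValueError("classification requires exactly two alignments")
    a, b = sorted(alignments, key=lambda x: (x.contig_start, x.contig_end))
    n = len(contig.sequence)
    overlap = a.contig_span + b.contig_span - n
    if overlap < 0:
        raise ValueError("alignments do not explain the contig (negative overlap)")
    orientation = "inverted" if a.strand != b.strand else "direct"
    # inner ends: the reference coordinate of A's right contig end and of B's
    # left contig end
    inner_a = a.ref_end if a.strand == "+" else a.ref_start
    inner_b = b.ref_start if b.strand == "+" else b.ref_end
    in_amp = False
    if segment is not None and a.chrom == segment.chrom == b.chrom:
        # the inner end on the wild-type side sits at the segment boundary;
        # the other inner end lies spacer+homology beyond it, so membership
        # is judged on the nearer coordinate
        lo = segment.start - segment.uncertainty_bp
        hi = segment.end + segment.uncertainty_bp
        in_amp = (lo <= inner_a <= hi) or (lo <= inner_b <= hi)
    return BreakpointCall(
        contig_id=contig.id,
        part_a=a,
        part_b=b,
        junction_coords=(inner_a, inner_b),
        chrom=a.chrom,
        orientation=orientation,
        overlap=overlap,
        in_amplification=in_amp,
    )


# ---------------------------------------------------------------------------
# Wild-type support, background probability, structure inference
# ---------------------------------------------------------------------------


def wildtype_support(
    alignments: Iterable[Alignment],
    genome: Genome,
    chrom: str,
    coordinate: int,
    min_span: int = 10,
) -> tuple[bool, int]:
    """True iff at least one unique-high read alignment covers
    ``[coordinate - min_span, coordinate + min_span]`` contiguously with the
    reference sequence."""
    seq = genome.sequences.get(chrom)
    if seq is None:
        raise ValueError(f"unknown chromosome {chrom!r}")
    if not 1 <= coordinate <= len(seq):
        raise ValueError("coordinate out of range")
    lo = coordinate - min_span
    hi = coordinate + min_span
    count = 0
    for aln in alignments:
        if aln.mapq_class != UNIQUE_HIGH or aln.chrom != chrom:
            continue
        if aln.start <= lo and aln.end >= hi:
            # window must match the reference exactly (wild-type sequence)
            off = lo - aln.start
            if lo < 1 or hi > len(seq):
                continue
            if aln.seq_fwd[off : off + (hi - lo + 1)] == seq[lo - 1 : hi]:
                count += 1
    return count > 0, count


def background_probability(
    n_background_contigs: int,
    mappable_bases: int,
    window: int = 50,
    n_breakpoints: int = 2,
) -> float:
    """Probability of background junction contigs landing inside the
    predicted windows: per-base rate r = n_background / mappable bases;
    P = (r x window)^n_breakpoints, capped at 1."""
    if mappable_bases <= 0:
        raise ValueError("mappable_bases must be positive")
    if window < 1:
        raise ValueError("window must be >= 1")
    if n_background_contigs < 0 or n_breakpoints < 0:
        raise ValueError("counts must be non-negative")
    rate = n_background_contigs / mappable_bases
    return min(1.0, (rate * window) ** n_breakpoints)


def infer_structure(
    segment: Segment | None,
    copy_number: float,
    left_call: BreakpointCall | None,
    right_call: BreakpointCall | None,
    wildtype_left: bool,
    wildtype_right: bool,
    background_p: float | None = None,
) -> AmplificationModel:
    """Label the amplification ``tandem_inverted`` iff both boundary calls
    are inverted-class, both fall within the segment boundaries (within
    uncertainty), and wild-type support holds at both boundaries; otherwise
    ``unresolved`` with the evidence listed."""
    evidence: list[str] = []
    ok = True
    for name, call in (("left", left_call), ("right", right_call)):
        if call is None:
            evidence.append(f"no {name} breakpoint call")
            ok = False
        else:
            if call.orientation != "inverted":
                evidence.append(f"{name} call is {call.orientation}, not inverted")
                ok = False
            if segment is not None and not call.in_amplification:
                evidence.append(f"{name} call outside segment boundaries")
                ok = False
            evidence.append(
                f"{name} junction overlap {call.overlap} nt ({call.orientation})"
            )
    for name, wt in (("left", wildtype_left), ("right", wildtype_right)):
        evidence.append(
            f"wild-type spanning reads at {name} boundary: {'yes' if wt else 'no'}"
        )
        if not wt:
            ok = False
    if segment is None:
        evidence.append("no amplified segment provided")
        ok = False
    structure = "tandem_inverted" if ok else "unresolved"
    return AmplificationModel(
        segment=segment,
        copy_number=copy_number,
        left_call=left_call,
        right_call=right_call,
        wildtype_left=wildtype_left,
        wildtype_right=wildtype_right,
        structure=structure,
        background_p=background_p,
        evidence=evidence,
    )
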
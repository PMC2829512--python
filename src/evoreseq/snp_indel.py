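"""Dual-threshold heuristic SNP calling and the small-indel screen.

A position is called as a SNP between the strains iff it is mappable, the
evolved pileup has depth >= 6 with a single base at >= 80% of calls, and
the parent pileup has depth >= 5 with a *different* base at >= 70% of
calls (thresholds inclusive and configurable).  The indel screen
split-aligns unmapped reads into two ordered, same-strand ungapped pieces
(bipartite alignment): a reference gap between the pieces marks a
deletion, a read gap an insertion.  Candidate coordinates need multiple
supporting reads in one strain, no wild-type-spanning reads in that
strain, and wild-type-spanning reads in the comparison strain.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .mapping import (
    UNIQUE_HIGH,
    Alignment,
    MappabilityMask,
    Pileup,
)
from .synthetic_data import DNA, Genome, Read, revcomp


@dataclass(frozen=True)
class SnpThresholds:
    """Read-depth / base-call-concordance thresholds for the two strains."""

    evolved_min_depth: int = 6
    evolved_min_fraction: float = 0.80
    parent_min_depth: int = 5
    parent_min_fraction: float = 0.70

    def __post_init__(self) -> None:
        if self.evolved_min_depth < 1 or self.parent_min_depth < 1:
            raise ValueError("depth thresholds must be >= 1")
        for f in (self.evolved_min_fraction, self.parent_min_fraction):
            if not 0.0 < f <= 1.0:
                raise ValueError("fraction thresholds must lie in (0, 1]")


@dataclass(frozen=True)
class SnpCall:
    chrom: str
    pos: int  # 1-based
    parent_base: str
    evolved_base: str
    evolved_depth: int
    evolved_fraction: float
    parent_depth: int
    parent_fraction: float


@dataclass(frozen=True)
class IndelCandidate:
    chrom: str
    pos: int  # 1-based reference base immediately left of the event
    kind: str  # "deletion" | "insertion"
    size: int
    strain: str  # strain carrying the event
    support: int  # split-aligned reads in that strain


def call_snps(
    pileup_evolved: Pileup,
    pileup_parent: Pileup,
    mask: MappabilityMask,
    thresholds: SnpThresholds | None = None,
) -> list[SnpCall]:
    """Apply the dual-threshold heuristic position by position (vectorized).

    Output is sorted by (chrom, pos).
    """
    thr = thresholds or SnpThresholds()
    if pileup_evolved.genome.sequences.keys() != pileup_parent.genome.sequences.keys():
        raise ValueError("pileups computed over different references")
    calls: list[SnpCall] = []
    for chrom in pileup_evolved.counts:
        ce = pileup_evolved.counts[chrom]
        cp = pileup_parent.counts[chrom]
        if ce.shape != cp.shape:
            raise ValueError("pileups computed over different references")
        de = ce.sum(axis=0)
        dp = cp.sum(axis=0)
        maj_e = ce.argmax(axis=0)
        maj_p = cp.argmax(axis=0)
        top_e = np.take_along_axis(ce, maj_e[None, :], axis=0)[0]
        top_p = np.take_along_axis(cp, maj_p[None, :], axis=0)[0]
        with np.errstate(divide="ignore", invalid="ignore"):
            frac_e = np.where(de > 0, top_e / np.maximum(de, 1), 0.0)
            frac_p = np.where(dp > 0, top_p / np.maximum(dp, 1), 0.0)
        eligible = (
            mask[chrom]
            & (de >= thr.evolved_min_depth)
            & (frac_e >= thr.evolved_min_fraction)
            & (dp >= thr.parent_min_depth)
            & (frac_p >= thr.parent_min_fraction)
            & (maj_e != maj_p)
        )
        for pos0 in np.where(eligible)[0]:
            calls.append(
                SnpCall(
                    chrom=chrom,
                    pos=int(pos0) + 1,
                    parent_base=DNA[int(maj_p[pos0])],
                    evolved_base=DNA[int(maj_e[pos0])],
                    evolved_depth=int(de[pos0]),
                    evolved_fraction=float(frac_e[pos0]),
                    parent_depth=int(dp[pos0]),
                    parent_fraction=float(frac_p[pos0]),
                )
            )
    calls.sort(key=lambda c: (c.chrom, c.pos))
    return calls


def callable_fraction(
    pileup_evolved: Pileup,
    pileup_parent: Pileup,
    mask: MappabilityMask,
    thresholds: SnpThresholds | None = None,
) -> float:
    """Fraction of mappable positions meeting both depth thresholds."""
    thr = thresholds or SnpThresholds()
    n_ok = 0
    n_mappable = 0
    for chrom in pileup_evolved.counts:
        de = pileup_evolved.counts[chrom].sum(axis=0)
        dp = pileup_parent.counts[chrom].sum(axis=0)
        m = mask[chrom]
        n_mappable += int(m.sum())
        n_ok += int(
            (m & (de >= thr.evolved_min_depth) & (dp >= thr.parent_min_depth)).sum()
        )
    return n_ok / n_mappable if n_mappable else 0.0


# ---------------------------------------------------------------------------
# Small-indel screen
# ---------------------------------------------------------------------------


def _split_align_read(
    seq: str,
    codes: dict[str, np.ndarray],
    seeds: dict[str, list[tuple[str, int]]],
    seed_len: int,
    max_size: int,
) -> list[tuple[str, int, str, int]]:
    """Bipartite (two ungapped, ordered, same-strand pieces) placements of a
    read.  Returns (chrom, 1-based pos of last base before the event, kind,
    size) tuples, with the leftmost consistent split as canonical."""
    n = len(seq)
    events = []
    for oriented in (seq, revcomp(seq)):
        q = np.frombuffer(oriented.encode(), dtype=np.uint8)
        prefix_hits = []
        for chrom, p in seeds.get(oriented[:seed_len], ()):
            ref = codes[chrom]
            limit = min(n, ref.size - p)
            # maximal exact prefix extension
            refseq = ref[p : p + limit]
            qenc = _encode_bytes(q[:limit])
            neq = np.nonzero(refseq != qenc)[0]
            L1 = int(neq[0]) if neq.size else limit
            if L1 >= seed_len:
                prefix_hits.append((chrom, p, L1))
        suffix_hits = []
        for chrom, p in seeds.get(oriented[n - seed_len :], ()):
            ref = codes[chrom]
            # maximal exact suffix extension (backwards from the seed start)
            end = p + seed_len  # exclusive ref end of the seed
            avail = min(n, end)
            refseq = ref[end - avail : end]
            qenc = _encode_bytes(q[n - avail :])
            neq = np.nonzero(refseq != qenc)[0]
            L2 = avail - (int(neq[-1]) + 1) if neq.size else avail
            if L2 >= seed_len:
                # suffix occupies read[n-L2:], ref[end-L2:end]
                suffix_hits.append((chrom, end - L2, L2))
        for chrom1, p, L1 in prefix_hits:
            for chrom2, g2, L2 in suffix_hits:
                if chrom1 != chrom2:
                    continue
                rs = n - L2  # read index where the suffix piece starts
                d = g2 - rs - p  # reference gap implied by the two pieces
                if d > 0 and L1 >= rs and d <= max_size:
                    # deletion of d bases; left flank ends at 0-based p+rs-1
                    events.append((chrom1, p + rs - 1, "deletion", d))
                elif d < 0 and g2 == p + L1 and rs > L1 and -d <= max_size:
                    events.append((chrom1, p + L1 - 1, "insertion", rs - L1))
    # deduplicate (both orientations find the same event)
    uniq = sorted(set(events))
    return [(c, pos0 + 1, kind, size) for c, pos0, kind, size in uniq]


_ENC_TABLE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(DNA):
    _ENC_TABLE[ord(_b)] = _i


def _encode_bytes(b: np.ndarray) -> np.ndarray:
    return _ENC_TABLE[b]


def _has_wildtype_spanning(
    alignments: Sequence[Alignment], genome: Genome, chrom: str, pos: int, span: int
) -> bool:
    seq = genome.sequences[chrom]
    lo, hi = max(1, pos - span), min(len(seq), pos + span)
    for aln in alignments:
        if aln.mapq_class != UNIQUE_HIGH or aln.chrom != chrom:
            continue
        if aln.start <= lo and aln.end >= hi:
            off = lo - aln.start
            if aln.seq_fwd[off : off + (hi - lo + 1)] == seq[lo - 1 : hi]:
                return True
    return False


def screen_indels(
    unmapped_evolved: Sequence[Read],
    unmapped_parent: Sequence[Read],
    genome: Genome,
    alignments_evolved: Sequence[Alignment],
    alignments_parent: Sequence[Alignment],
    mask: MappabilityMask | None = None,
    min_support: int = 2,
    seed_len: int = 12,
    max_size: int = 50,
    wildtype_span: int = 5,
) -> list[IndelCandidate]:
    """Screen both strains' unmapped pools for strain-specific small indels.

    Coordinates with >= ``min_support`` bipartite-aligned reads in one
    strain, no wild-type-spanning reads in that strain, and wild-type
    spanning reads in the comparison strain are emitted.
    """
    from .breakpoints import _get_seed_index

    idx = _get_seed_index(genome)
    pools = {"evolved": unmapped_evolved, "parent": unmapped_parent}
    alns = {"evolved": alignments_evolved, "parent": alignments_parent}
    counts: dict[tuple[str, int, str, int], dict[str, int]] = {}
    for strain, pool in pools.items():
        for read in pool:
            for event in _split_align_read(
                read.sequence, idx.codes, idx.seeds, seed_len, max_size
            ):
                per = counts.setdefault(event, {"evolved": 0, "parent": 0})
                per[strain] += 1
    candidates: list[IndelCandidate] = []
    for (chrom, pos, kind, size), per in sorted(counts.items()):
        if mask is not None and not mask.is_mappable(chrom, min(pos, mask[chrom].size)):
            continue
        for strain, other in (("evolved", "parent"), ("parent", "evolved")):
            if per[strain] < min_support:
                continue
            if _has_wildtype_spanning(alns[strain], genome, chrom, pos, wildtype_span):
                continue
            if not _has_wildtype_spanning(alns[other], genome, chrom, pos, wildtype_span):
                continue
            candidates.append(
                IndelCandidate(
                    chrom=chrom,
                    pos=pos,
                    kind=kind,
                    size=size,
                    strain=strain,
                    support=per[strain],
                )
            )
    return candidates
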
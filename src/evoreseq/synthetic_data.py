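"""Synthetic genomes, evolved derivatives, and simulated short reads.

This module fabricates the study system end to end: a small haploid
reference genome, an "evolved" derivative carrying a handful of clonal
SNPs plus a tandem-inverted amplification of one segment, and single-end
short reads from both strains.  Every planted event is recorded in a
:class:`TruthSet` so downstream callers can be scored against ground
truth.

The amplification is built the way micro-homology-mediated inverted
duplications look in real genomes: short inverted-repeat arms are planted
in the reference flanks, and each inverted junction of the evolved
chromosome runs forward through the proximal arm and then continues as
the reverse complement from the distal arm.  A sequence crossing such a
junction therefore aligns back to the reference as two ungapped pieces on
opposite strands whose contig-interval claims overlap by exactly the arm
length -- the signature the breakpoint caller recovers.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

DNA = "ACGT"
_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")

# encode/decode tables shared with the read simulator
_ENCODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(DNA):
    _ENCODE[ord(_b)] = _i
_DECODE = np.frombuffer(DNA.encode(), dtype=np.uint8)
_COMP_CODE = np.array([3, 2, 1, 0], dtype=np.uint8)  # A<->T, C<->G


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string."""
    return seq.translate(_COMPLEMENT)[::-1]


def encode_seq(seq: str) -> np.ndarray:
    """DNA string -> uint8 codes (A=0, C=1, G=2, T=3)."""
    codes = _ENCODE[np.frombuffer(seq.encode(), dtype=np.uint8)]
    if codes.max(initial=0) > 3:
        raise ValueError("sequence contains characters outside A/C/G/T")
    return codes


def decode_seq(codes: np.ndarray) -> str:
    return _DECODE[codes].tobytes().decode()


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class Genome:
    """Haploid genome: mapping of chromosome name -> uppercase DNA string."""

    sequences: dict[str, str]

    def __post_init__(self) -> None:
        if not self.sequences:
            raise ValueError("genome has no chromosomes")
        for name, seq in self.sequences.items():
            if not seq:
                raise ValueError(f"chromosome {name!r} is empty")
            if set(seq) - set(DNA):
                raise ValueError(f"chromosome {name!r} has non-ACGT characters")

    def lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.sequences.items()}

    def total_length(self) -> int:
        return sum(len(s) for s in self.sequences.values())

    def __eq__(self, other: object) -> bool:
        return isinstance(other, Genome) and self.sequences == other.sequences

    # --- FASTA I/O ---------------------------------------------------------

    @classmethod
    def from_fasta(cls, path: str | Path) -> "Genome":
        records = list(SeqIO.parse(str(path), "fasta"))
        if not records:
            raise ValueError(f"no FASTA records in {path}")
        return cls({rec.id: str(rec.seq).upper() for rec in records})

    def to_fasta(self, path: str | Path) -> None:
        records = [
            SeqRecord(Seq(seq), id=name, description="")
            for name, seq in self.sequences.items()
        ]
        SeqIO.write(records, str(path), "fasta")


@dataclass(frozen=True)
class Read:
    """A single-end read: identifier, sequence, quality string."""

    id: str
    sequence: str
    quality: str


@dataclass
class ReadSet:
    """Fixed-length single-end reads for one strain."""

    reads: list[Read]
    read_length: int

    def __post_init__(self) -> None:
        for r in self.reads:
            if len(r.sequence) != self.read_length:
                raise ValueError("reads must all have the same length")
            if len(r.quality) != len(r.sequence):
                raise ValueError("quality length differs from sequence length")

    def __len__(self) -> int:
        return len(self.reads)

    def __iter__(self):
        return iter(self.reads)

    @classmethod
    def from_fastq(cls, path: str | Path) -> "ReadSet":
        reads = []
        for rec in SeqIO.parse(str(path), "fastq"):
            qual = "".join(
                chr(q + 33) for q in rec.letter_annotations["phred_quality"]
            )
            reads.append(Read(rec.id, str(rec.seq).upper(), qual))
        if not reads:
            raise ValueError(f"no FASTQ records in {path}")
        return cls(reads, read_length=len(reads[0].sequence))

    def to_fastq(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for r in self.reads:
                fh.write(f"@{r.id}\n{r.sequence}\n+\n{r.quality}\n")


@dataclass(frozen=True)
class Amplification:
    """A planted tandem-inverted amplification.

    ``left``/``right`` are 1-based inclusive reference coordinates of the
    amplified segment; ``h_left``/``h_right`` are the micro-homology arm
    lengths at each boundary junction and ``spacer_left``/``spacer_right``
    the distances between the inverted-repeat arms.
    """

    chrom: str
    left: int
    right: int
    copy_number: int
    h_left: int = 7
    h_right: int = 13
    spacer_left: int = 6
    spacer_right: int = 10

    def __post_init__(self) -> None:
        if self.copy_number < 1:
            raise ValueError("copy_number must be >= 1")
        if self.left >= self.right:
            raise ValueError("amplification requires left < right")
        if self.h_left < 0 or self.h_right < 0:
            raise ValueError("micro-homology lengths must be >= 0")
        if self.spacer_left < 0 or self.spacer_right < 0:
            raise ValueError("spacer lengths must be >= 0")
        if (self.h_left > 0 and self.spacer_left < 1) or (
            self.h_right > 0 and self.spacer_right < 1
        ):
            # with no spacer the arms abut and the true homology exceeds h
            raise ValueError("a non-zero micro-homology arm requires spacer >= 1")

    @property
    def length(self) -> int:
        return self.right - self.left + 1


@dataclass
class EvolutionSpec:
    """Events to plant in the evolved genome."""

    snps: list[tuple[str, int, str]] = field(default_factory=list)
    amplification: Amplification | None = None


@dataclass
class TruthSet:
    """Machine-readable record of everything planted in the evolved genome."""

    snps: list[dict] = field(default_factory=list)
    amplification: dict | None = None
    junctions: list[dict] = field(default_factory=list)
    read_origins: dict[str, list[tuple[str, int, str]]] = field(default_factory=dict)

    # --- serialization -----------------------------------------------------

    def snps_to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("# planted SNPs, 1-based inclusive coordinates\n")
            fh.write("chrom\tpos\tref\talt\n")
            for s in self.snps:
                fh.write(f"{s['chrom']}\t{s['pos']}\t{s['ref']}\t{s['alt']}\n")

    def amplification_to_bed(self, path: str | Path) -> None:
        """BED (0-based half-open, per the format standard)."""
        with open(path, "w") as fh:
            if self.amplification is not None:
                a = self.amplification
                fh.write(
                    f"{a['chrom']}\t{a['left'] - 1}\t{a['right']}\t"
                    f"{a['structure']}\t{a['copy_number']}\t+\n"
                )

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "snps": self.snps,
                    "amplification": self.amplification,
                    "junctions": self.junctions,
                },
                fh,
                indent=2,
            )
            fh.write("\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "TruthSet":
        with open(path) as fh:
            data = json.load(fh)
        return cls(
            snps=data.get("snps", []),
            amplification=data.get("amplification"),
            junctions=data.get("junctions", []),
        )


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------


def generate_reference(
    n_chroms: int,
    lengths: Sequence[int],
    gc: float = 0.38,
    seed: int = 0,
    names: Sequence[str] | None = None,
) -> Genome:
    """Generate a random haploid reference with i.i.d. bases at a given GC.

    Deterministic for a fixed seed.  Chromosome names default to chrI,
    chrII, ... in order.
    """
    if n_chroms < 1:
        raise ValueError("need at least one chromosome")
    if len(lengths) != n_chroms:
        raise ValueError("lengths must have one entry per chromosome")
    if any(l <= 0 for l in lengths):
        raise ValueError("chromosome lengths must be positive")
    if not 0.0 < gc < 1.0:
        raise ValueError("gc must lie strictly between 0 and 1")
    if names is None:
        roman = [
            "I", "II", "III", "IV", "V", "VI", "VII", "VIII", "IX", "X",
            "XI", "XII", "XIII", "XIV", "XV", "XVI",
        ]
        names = [f"chr{roman[i]}" if i < len(roman) else f"chr{i + 1}" for i in range(n_chroms)]
    rng = np.random.default_rng(seed)
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    seqs = {}
    for name, length in zip(names, lengths):
        codes = rng.choice(4, size=length, p=probs).astype(np.uint8)
        seqs[name] = decode_seq(codes)
    return Genome(seqs)


def _replace(seq: str, start0: int, replacement: str) -> str:
    return seq[:start0] + replacement + seq[start0 + len(replacement):]


def plant_inverted_repeats(
    genome: Genome, chrom: str, boundary: int, arm_len: int, spacer: int
) -> Genome:
    """Plant an inverted repeat: the ``arm_len`` bases ending at ``boundary``
    (1-based) are mirrored as a reverse-complement arm ``spacer`` bases
    downstream.  The downstream copy is (over)written; all other bases are
    untouched.  ``arm_len == 0`` returns the genome unchanged.
    """
    if arm_len == 0:
        return Genome(dict(genome.sequences))
    if arm_len < 0:
        raise ValueError("arm_len must be >= 0")
    if spacer < 0:
        raise ValueError("arms would overlap each other (spacer < 0)")
    seq = genome.sequences[chrom]
    prox_start0 = boundary - arm_len  # 0-based
    dist_start0 = boundary + spacer  # 0-based
    if prox_start0 < 0 or dist_start0 + arm_len > len(seq):
        raise ValueError("inverted-repeat arms do not fit on the chromosome")
    arm = seq[prox_start0:boundary]
    new = dict(genome.sequences)
    new[chrom] = _replace(seq, dist_start0, revcomp(arm))
    return Genome(new)


def plant_amplification_arms(genome: Genome, amp: Amplification) -> Genome:
    """Plant the micro-homology inverted-repeat arms for an amplification
    into the reference flanks.

    The arms are features of the *ancestor* genome (the rearrangement forms
    through them), so this must be applied to the reference before deriving
    the evolved genome from it:

    - left:  ref[left-s-h .. left-s-1]   <- revcomp(ref[left .. left+h-1])
    - right: ref[right+s+1 .. right+s+h] <- revcomp(ref[right-h+1 .. right])

    Micro-homology length is defined as the *maximal* shared sequence at a
    junction, so the bases that delimit each arm are forced to mismatch the
    continuation they would otherwise extend; without these terminators a
    chance match (p = 1/4 per boundary) would make the true planted homology
    longer than requested.
    """
    seq = genome.sequences[amp.chrom]
    left0, right0 = amp.left - 1, amp.right - 1
    if left0 - amp.spacer_left - amp.h_left - 1 < 0:
        raise ValueError("left arm does not fit on the chromosome")
    if right0 + amp.spacer_right + amp.h_right + 1 >= len(seq):
        raise ValueError("right arm does not fit on the chromosome")
    if amp.h_left > 0:
        arm = seq[left0 : left0 + amp.h_left]
        seq = _replace(seq, left0 - amp.spacer_left - amp.h_left, revcomp(arm))
    if amp.h_right > 0:
        arm = seq[right0 - amp.h_right + 1 : right0 + 1]
        seq = _replace(seq, right0 + 1 + amp.spacer_right, revcomp(arm))

    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}

    def force_mismatch(pos0: int, forbidden: str) -> None:
        nonlocal seq
        if seq[pos0] == forbidden:
            options = [b for b in DNA if b != forbidden]
            # deterministic choice: next base in alphabet order
            seq = _replace(seq, pos0, options[(DNA.index(forbidden) + 1) % 3])

    s_l, s_r = amp.spacer_left, amp.spacer_right
    h_l, h_r = amp.h_left, amp.h_right
    if h_r > 0:
        # plus part must stop at `right`: continuation base comp(seq[right0+s_r])
        # must not equal seq[right0+1] (auto-satisfied when s_r == 1)
        if s_r > 1:
            force_mismatch(right0 + s_r, comp[seq[right0 + 1]])
        # minus part must stop after the arm: base beyond the distal arm must
        # not complement the base beyond the proximal arm
        force_mismatch(right0 + s_r + h_r + 1, comp[seq[right0 - h_r]])
    if h_l > 0:
        # minus part must stop at `left`: first forward-continuation base
        # seq[left0-s_l] must not equal comp(seq[left0-1])
        if s_l > 1:
            force_mismatch(left0 - s_l, comp[seq[left0 - 1]])
        # plus part must stop after the arm
        force_mismatch(left0 - s_l - h_l - 1, comp[seq[left0 + h_l]])
    new = dict(genome.sequences)
    new[amp.chrom] = seq
    return Genome(new)


def has_amplification_arms(genome: Genome, amp: Amplification) -> bool:
    """Whether the inverted-repeat arm relation already holds in a genome."""
    seq = genome.sequences[amp.chrom]
    left0, right0 = amp.left - 1, amp.right - 1
    ok = True
    if amp.h_left > 0:
        ok &= seq[left0 - amp.spacer_left - amp.h_left : left0 - amp.spacer_left] == revcomp(
            seq[left0 : left0 + amp.h_left]
        )
    if amp.h_right > 0:
        ok &= seq[right0 + 1 + amp.spacer_right : right0 + 1 + amp.spacer_right + amp.h_right] == revcomp(
            seq[right0 - amp.h_right + 1 : right0 + 1]
        )
    return ok


def apply_evolution(
    genome: Genome, spec: EvolutionSpec, seed: int = 0, junction_flank: int = 35
) -> tuple[Genome, TruthSet]:
    """Derive the evolved genome: SNP substitutions plus a tandem-inverted
    amplification built through planted micro-homology arms.

    The segment ``S=[left,right]`` is replaced by an alternating-orientation
    array ``S(+), S(-), S(+), ...`` of ``copy_number`` copies.  Inverted
    junctions run forward through the proximal inverted-repeat arm and
    continue leftward (reverse complement) from beyond the distal arm, so a
    junction-crossing sequence aligns back to the reference as two ungapped
    opposite-strand pieces whose contig intervals overlap by exactly the arm
    length.  Odd copy numbers leave wild-type sequence at both outer flanks.

    The inverted-repeat arms must already be present in the input genome
    (see :func:`plant_amplification_arms`): they belong to the ancestor, and
    planting them here would make the evolved flanks differ from the
    reference the parent strain is sequenced from.
    """
    del seed  # construction is fully determined by the spec
    truth = TruthSet()
    seqs = dict(genome.sequences)
    amp = spec.amplification

    # SNPs first (they are forbidden inside/near the amplified footprint)
    for chrom, pos, alt in spec.snps:
        if chrom not in seqs:
            raise ValueError(f"SNP chromosome {chrom!r} not in genome")
        seq = seqs[chrom]
        if not 1 <= pos <= len(seq):
            raise ValueError(f"SNP position {pos} outside chromosome {chrom!r}")
        ref_base = seq[pos - 1]
        if alt not in DNA:
            raise ValueError(f"SNP alt base {alt!r} is not A/C/G/T")
        if alt == ref_base:
            raise ValueError(f"SNP at {chrom}:{pos} does not change the base")
        if amp is not None and chrom == amp.chrom:
            lo = amp.left - amp.spacer_left - amp.h_left
            hi = amp.right + amp.spacer_right + amp.h_right
            if lo <= pos <= hi:
                raise ValueError(
                    f"SNP at {chrom}:{pos} lies inside the amplified footprint"
                )
        seqs[chrom] = _replace(seq, pos - 1, alt)
        truth.snps.append({"chrom": chrom, "pos": pos, "ref": ref_base, "alt": alt})

    if amp is None or amp.copy_number == 1:
        evolved = Genome(seqs)
        if amp is not None:
            truth.amplification = {
                **dataclasses.asdict(amp),
                "structure": "single_copy",
            }
        return evolved, truth

    chrom = amp.chrom
    if chrom not in seqs:
        raise ValueError(f"amplification chromosome {chrom!r} not in genome")
    seq = seqs[chrom]
    left0, right0 = amp.left - 1, amp.right - 1  # 0-based inclusive
    if left0 - amp.spacer_left - amp.h_left < 0 or right0 + amp.spacer_right + amp.h_right >= len(seq):
        raise ValueError("amplification footprint does not fit on the chromosome")
    if not has_amplification_arms(Genome({chrom: seq}), amp):
        raise ValueError(
            "inverted-repeat arms are not present at the amplification "
            "boundaries; apply plant_amplification_arms to the reference first"
        )

    pre = seq[:left0]
    post = seq[right0 + 1 :]
    c_first = seq[left0 : right0 + 1]  # S(+)
    # descending copy: reverse complement from right+spacer_right down to left
    desc = revcomp(seq[left0 : right0 + 1 + amp.spacer_right])  # S(-)
    # ascending copy: forward again from left-spacer_left through right
    asc = seq[left0 - amp.spacer_left : right0 + 1]  # S(+)

    k = amp.copy_number
    pairs, extra_desc = divmod(k - 1, 2)
    body = c_first + (desc + asc) * pairs + (desc if extra_desc else "")
    evolved_chrom = pre + body + post
    seqs_evolved = dict(seqs)
    seqs_evolved[chrom] = evolved_chrom
    evolved = Genome(seqs_evolved)

    structure = "tandem_inverted"
    truth.amplification = {**dataclasses.asdict(amp), "structure": structure}

    # junction positions in evolved coordinates (0-based index of the last
    # base before the junction); record flanking sequence for each distinct
    # junction type
    junctions = []
    offset = left0 + len(c_first)
    if pairs or extra_desc:
        junctions.append(("right_tail_to_tail", offset, amp.h_right))
    if pairs:
        junctions.append(("left_head_to_head", offset + len(desc), amp.h_left))
    w = junction_flank
    for label, j, h in junctions:
        truth.junctions.append(
            {
                "label": label,
                "chrom": chrom,
                "evolved_pos": j,  # junction lies between j and j+1 (1-based)
                "micro_homology": h,
                "sequence": evolved_chrom[max(0, j - w) : j + w],
            }
        )
    return evolved, truth


def simulate_reads(
    genome: Genome,
    mean_depth: float,
    read_len: int = 36,
    err_rate: float = 0.005,
    seed: int = 0,
    both_strands: bool = True,
    quality_char: str = "I",
    id_prefix: str = "read",
) -> tuple[ReadSet, list[tuple[str, int, str]]]:
    """Simulate uniform single-end reads with i.i.d. substitution errors.

    Read start positions are uniform over valid starts; each read is drawn
    from the forward or reverse strand with probability 1/2 (matching real
    single-end libraries).  Returns the reads and their true origins as
    ``(chrom, 1-based start, strand)`` tuples, in read order.  The origin is
    also embedded in each read id.  Deterministic for a fixed seed.
    """
    if mean_depth <= 0:
        raise ValueError("mean_depth must be positive")
    if err_rate < 0 or err_rate >= 1:
        raise ValueError("err_rate must lie in [0, 1)")
    shortest = min(len(s) for s in genome.sequences.values())
    if read_len > shortest:
        raise ValueError("read_len exceeds the shortest chromosome")

    rng = np.random.default_rng(seed)
    chroms = list(genome.sequences)
    codes = {c: encode_seq(genome.sequences[c]) for c in chroms}
    valid = np.array([len(genome.sequences[c]) - read_len + 1 for c in chroms])
    total_valid = int(valid.sum())
    n_reads = int(round(mean_depth * genome.total_length() / read_len))

    # sample a global start offset, then split per chromosome
    flat = rng.integers(0, total_valid, size=n_reads)
    strands = rng.random(n_reads) < 0.5 if both_strands else np.zeros(n_reads, bool)
    bounds = np.concatenate([[0], np.cumsum(valid)])
    chrom_idx = np.searchsorted(bounds, flat, side="right") - 1
    starts0 = flat - bounds[chrom_idx]

    n_err = rng.binomial(read_len, err_rate, size=n_reads)

    reads: list[Read] = []
    origins: list[tuple[str, int, str]] = []
    qual = quality_char * read_len
    offsets = np.arange(read_len)
    for ci in range(len(chroms)):
        sel = np.where(chrom_idx == ci)[0]
        if sel.size == 0:
            continue
        mat = codes[chroms[ci]][starts0[sel][:, None] + offsets]
        rev = strands[sel]
        mat[rev] = _COMP_CODE[mat[rev][:, ::-1]]
        # substitution errors: shift by 1..3 guarantees a different base
        err_rows = np.where(n_err[sel] > 0)[0]
        for r in err_rows:
            k = int(n_err[sel][r])
            pos = rng.choice(read_len, size=k, replace=False)
            mat[r, pos] = (mat[r, pos] + rng.integers(1, 4, size=k)) % 4
        seq_bytes = _DECODE[mat].view(f"S{read_len}").ravel()
        for row, i in enumerate(sel):
            chrom = chroms[ci]
            start1 = int(starts0[i]) + 1
            strand = "-" if strands[i] else "+"
            rid = f"{id_prefix}_{i}:{chrom}:{start1}:{strand}"
            reads.append(Read(rid, seq_bytes[row].decode(), qual))
            origins.append((chrom, start1, strand))
    # restore read-index order (per-chromosome batches shuffled it)
    order = np.argsort([int(r.id.split(":")[0].rsplit("_", 1)[1]) for r in reads])
    reads = [reads[i] for i in order]
    origins = [origins[i] for i in order]
    return ReadSet(reads, read_length=read_len), origins


def write_fixtures(
    genome: Genome,
    evolved_genome: Genome,
    readsets: dict[str, ReadSet],
    truth: TruthSet,
    out_dir: str | Path,
) -> dict[str, Path]:
    """Write reference/evolved FASTA, per-strain FASTQ, and truth TSV/BED/JSON.

    Everything round-trips through this module's own readers.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "reference": out / "reference.fasta",
        "evolved": out / "evolved.fasta",
        "truth_snps": out / "truth_snps.tsv",
        "truth_amplification": out / "truth_amplification.bed",
        "truth": out / "truth.json",
    }
    genome.to_fasta(paths["reference"])
    evolved_genome.to_fasta(paths["evolved"])
    truth.snps_to_tsv(paths["truth_snps"])
    truth.amplification_to_bed(paths["truth_amplification"])
    truth.to_json(paths["truth"])
    for strain, rs in readsets.items():
        p = out / f"{strain}.fastq"
        rs.to_fastq(p)
        paths[f"reads_{strain}"] = p
    return paths
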
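"""Pipeline orchestration: simulate -> map -> SNP/indel -> CNV -> breakpoints.

A :class:`PipelineConfig` carries every stage parameter with the study's
defaults (36 bp single-end reads, 35x/28x depths, 6x/80% and 5x/70% SNP
thresholds, 25 bp bins, CBS at alpha 0.01 with 1000 permutations, 3-SD
smoothing, >=1000 bp segments, >=90% ungapped contig identity and
coverage).  :func:`run_pipeline` produces standard-format outputs (VCF,
BED, TSV, FASTA, JSON) plus a structure report; :func:`make_demo`
generates the canonical synthetic scenario -- four clonal SNPs and a
five-copy tandem-inverted amplification of an ~11 kb segment with 7 nt
and 13 nt micro-homology junctions -- together with its truth files.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import breakpoints as bp
from . import cnv, mapping, snp_indel
from . import synthetic_data as synth

logger = logging.getLogger("evoreseq")


@dataclass
class PipelineConfig:
    """All pipeline parameters plus input/output paths."""

    # inputs (either FASTQ reads or pre-computed SAM alignments per strain)
    reference_fasta: str | None = None
    evolved_reads: str | None = None
    parent_reads: str | None = None
    evolved_sam: str | None = None
    parent_sam: str | None = None
    out_dir: str = "evoreseq_out"

    # read geometry / mapping
    read_length: int = 36
    max_mismatches: int = 2
    mapq_threshold: int = 10

    # SNP calling
    evolved_min_depth: int = 6
    evolved_min_fraction: float = 0.80
    parent_min_depth: int = 5
    parent_min_fraction: float = 0.70

    # indel screen
    indel_min_support: int = 2

    # CNV
    bin_width: int = 25
    cbs_alpha: float = 0.01
    cbs_permutations: int = 1000
    smooth_sd_multiplier: float = 3.0
    min_segment_span: int = 1000

    # breakpoints
    assembly_k: int = 21
    min_contig_len: int = 40
    min_identity: float = 0.90
    min_contig_coverage: float = 0.90
    wildtype_min_span: int = 10
    background_window: int = 50

    # simulation (used by the `simulate` stage / demo)
    genome_length: int = 200_000
    gc_content: float = 0.38
    evolved_depth: float = 35.0
    parent_depth: float = 28.0
    error_rate: float = 0.005
    amp_left: int = 121_317
    amp_length: int = 11_038
    amp_copy_number: int = 5
    amp_h_left: int = 7
    amp_h_right: int = 13
    amp_spacer_left: int = 6
    amp_spacer_right: int = 10
    n_snps: int = 4

    seed: int = 0

    # stage gating
    stages: tuple[str, ...] = ("snps", "indels", "cnv", "breakpoints")

    def validate(self) -> None:
        checks = [
            (self.read_length >= 12, "read_length must be >= 12"),
            (self.max_mismatches >= 0, "max_mismatches must be >= 0"),
            (0 < self.evolved_min_fraction <= 1, "evolved_min_fraction must be in (0,1]"),
            (0 < self.parent_min_fraction <= 1, "parent_min_fraction must be in (0,1]"),
            (self.bin_width >= 1, "bin_width must be >= 1"),
            (0 < self.cbs_alpha < 1, "cbs_alpha must be in (0,1)"),
            (self.cbs_permutations >= 100, "cbs_permutations must be >= 100"),
            (self.min_segment_span >= self.bin_width, "min_segment_span must be >= bin_width"),
            (12 <= self.assembly_k < self.read_length, "assembly_k must be in [12, read_length)"),
            (0 < self.min_identity <= 1, "min_identity must be in (0,1]"),
            (self.amp_copy_number >= 1, "amp_copy_number must be >= 1"),
            (0 < self.gc_content < 1, "gc_content must be in (0,1)"),
        ]
        for ok, msg in checks:
            if not ok:
                raise ValueError(f"invalid config: {msg}")

    def cbs_params(self) -> cnv.CbsParams:
        return cnv.CbsParams(
            alpha=self.cbs_alpha,
            n_permutations=self.cbs_permutations,
            smooth_sd_multiplier=self.smooth_sd_multiplier,
            min_segment_span=self.min_segment_span,
            seed=self.seed,
        )

    def snp_thresholds(self) -> snp_indel.SnpThresholds:
        return snp_indel.SnpThresholds(
            evolved_min_depth=self.evolved_min_depth,
            evolved_min_fraction=self.evolved_min_fraction,
            parent_min_depth=self.parent_min_depth,
            parent_min_fraction=self.parent_min_fraction,
        )

    def to_yaml(self, path: str | Path) -> None:
        data = dataclasses.asdict(self)
        data["stages"] = list(self.stages)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        if "stages" in data:
            data["stages"] = tuple(data["stages"])
        return cls(**data)


# ---------------------------------------------------------------------------
# Demo scenario
# ---------------------------------------------------------------------------


def demo_scenario(
    config: PipelineConfig | None = None, seed: int | None = None
) -> tuple[synth.Genome, synth.Genome, synth.TruthSet, synth.ReadSet, synth.ReadSet]:
    """Build the canonical synthetic scenario in memory.

    Returns (reference, evolved genome, truth, evolved reads, parent reads).
    """
    cfg = config or PipelineConfig()
    if seed is not None:
        cfg = dataclasses.replace(cfg, seed=seed)
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    reference = synth.generate_reference(
        1, [cfg.genome_length], gc=cfg.gc_content, seed=int(rng.integers(2**31))
    )
    chrom = next(iter(reference.sequences))
    amp = synth.Amplification(
        chrom=chrom,
        left=cfg.amp_left,
        right=cfg.amp_left + cfg.amp_length - 1,
        copy_number=cfg.amp_copy_number,
        h_left=cfg.amp_h_left,
        h_right=cfg.amp_h_right,
        spacer_left=cfg.amp_spacer_left,
        spacer_right=cfg.amp_spacer_right,
    )
    # the micro-homology arms are features of the ancestor reference
    reference = synth.plant_amplification_arms(reference, amp)
    # scatter SNPs outside the amplified footprint, away from chromosome ends
    footprint = (amp.left - 2_000, amp.right + 2_000)
    snps: list[tuple[str, int, str]] = []
    while len(snps) < cfg.n_snps:
        pos = int(rng.integers(1_000, cfg.genome_length - 1_000))
        if footprint[0] <= pos <= footprint[1]:
            continue
        if any(abs(pos - p) < 100 for _, p, _ in snps):
            continue
        ref_base = reference.sequences[chrom][pos - 1]
        alt = "ACGT".replace(ref_base, "")[int(rng.integers(3))]
        snps.append((chrom, pos, alt))
    snps.sort(key=lambda s: s[1])
    spec = synth.EvolutionSpec(snps=snps, amplification=amp)
    evolved, truth = synth.apply_evolution(reference, spec)
    reads_evo, _ = synth.simulate_reads(
        evolved,
        cfg.evolved_depth,
        read_len=cfg.read_length,
        err_rate=cfg.error_rate,
        seed=int(rng.integers(2**31)),
        id_prefix="evo",
    )
    reads_par, _ = synth.simulate_reads(
        reference,
        cfg.parent_depth,
        read_len=cfg.read_length,
        err_rate=cfg.error_rate,
        seed=int(rng.integers(2**31)),
        id_prefix="par",
    )
    return reference, evolved, truth, reads_evo, reads_par


def make_demo(out_dir: str | Path, seed: int = 0) -> dict[str, Path]:
    """One-command generation of the synthetic scenario fixture bundle."""
    cfg = dataclasses.replace(PipelineConfig(), seed=seed, out_dir=str(out_dir))
    reference, evolved, truth, reads_evo, reads_par = demo_scenario(cfg)
    paths = synth.write_fixtures(
        reference,
        evolved,
        {"evolved": reads_evo, "parent": reads_par},
        truth,
        out_dir,
    )
    cfg_path = Path(out_dir) / "config.yaml"
    cfg.to_yaml(cfg_path)
    paths["config"] = cfg_path
    return paths


# ---------------------------------------------------------------------------
# Report writers
# ---------------------------------------------------------------------------


def write_vcf(
    path: str | Path, genome: synth.Genome, calls: list[snp_indel.SnpCall]
) -> None:
    """Minimal haploid VCF 4.2 (single ALT, no genotype likelihoods)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=evoreseq\n")
        for chrom, seq in genome.sequences.items():
            fh.write(f"##contig=<ID={chrom},length={len(seq)}>\n")
        fh.write('##INFO=<ID=EDP,Number=1,Type=Integer,Description="Evolved depth">\n')
        fh.write('##INFO=<ID=EAF,Number=1,Type=Float,Description="Evolved supporting fraction">\n')
        fh.write('##INFO=<ID=PDP,Number=1,Type=Integer,Description="Parent depth">\n')
        fh.write('##INFO=<ID=PAF,Number=1,Type=Float,Description="Parent supporting fraction">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for c in calls:
            info = (
                f"EDP={c.evolved_depth};EAF={c.evolved_fraction:.3f};"
                f"PDP={c.parent_depth};PAF={c.parent_fraction:.3f}"
            )
            fh.write(
                f"{c.chrom}\t{c.pos}\t.\t{c.parent_base}\t{c.evolved_base}\t.\tPASS\t{info}\n"
            )


def write_segments(
    bed_path: str | Path, tsv_path: str | Path, segments: dict[str, list[cnv.Segment]]
) -> None:
    rows = []
    with open(bed_path, "w") as fh:
        for chrom, segs in segments.items():
            for i, seg in enumerate(segs):
                fh.write(
                    f"{chrom}\t{seg.start - 1}\t{seg.end}\tsegment_{chrom}_{i + 1}\t"
                    f"{min(1000, int(round(seg.copy_ratio * 100)))}\t+\n"
                )
                rows.append(
                    {
                        "chrom": chrom,
                        "start": seg.start,
                        "end": seg.end,
                        "n_bins": seg.n_bins,
                        "mean_log2_ratio": round(seg.mean_log2, 4),
                        "copy_ratio": round(seg.copy_ratio, 3),
                        "uncertainty_bp": seg.uncertainty_bp,
                    }
                )
    pd.DataFrame(rows).to_csv(tsv_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------


def _load_inputs(cfg: PipelineConfig):
    if cfg.reference_fasta is None:
        raise ValueError("missing input: reference_fasta")
    try:
        genome = synth.Genome.from_fasta(cfg.reference_fasta)
    except Exception as exc:  # surface the offending field
        raise ValueError(f"reference_fasta: cannot parse ({exc})") from exc
    strains = {}
    for strain in ("evolved", "parent"):
        sam = getattr(cfg, f"{strain}_sam")
        fastq = getattr(cfg, f"{strain}_reads")
        if sam is not None:
            alns, unmapped = mapping.read_sam(sam, cfg.mapq_threshold)
            strains[strain] = (alns, unmapped)
        elif fastq is not None:
            strains[strain] = fastq  # mapped later (index shared)
        else:
            raise ValueError(f"missing input: {strain}_reads or {strain}_sam")
    return genome, strains


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the configured stages end to end and write the report bundle.

    Returns the structure report as a dict (also written as JSON).
    """
    cfg = config
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=logging.INFO, format="%(levelname)s %(message)s")
    fh = logging.FileHandler(out / "run.log", mode="w")
    fh.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    logger.addHandler(fh)
    try:
        return _run_pipeline_inner(cfg, out)
    finally:
        logger.removeHandler(fh)
        fh.close()


def _run_pipeline_inner(cfg: PipelineConfig, out: Path) -> dict:
    genome, strains = _load_inputs(cfg)
    cfg.to_yaml(out / "config.yaml")
    logger.info("reference: %s chromosomes, %d bp", len(genome.sequences), genome.total_length())

    index = mapping.build_index(genome, cfg.read_length)
    mask = mapping.mappability_mask(genome, cfg.read_length, index=index)
    logger.info("mappable positions: %d", mask.n_mappable())

    data = {}
    for strain, inp in strains.items():
        if isinstance(inp, str):
            reads = synth.ReadSet.from_fastq(inp)
            if reads.read_length != cfg.read_length:
                raise ValueError(f"{strain}_reads: read length != config read_length")
            alns, unmapped = mapping.map_reads(reads, index, cfg.max_mismatches)
        else:
            alns, unmapped = inp
        track, pile = mapping.pileup(alns, genome)
        data[strain] = {"alignments": alns, "unmapped": unmapped, "track": track, "pileup": pile}
        logger.info(
            "%s: %d unique-high/mapped alignments, %d unmapped, %d nuclear bases",
            strain,
            len(alns),
            len(unmapped),
            track.total_nuclear_bases,
        )

    report: dict = {"stages": list(cfg.stages)}

    if "snps" in cfg.stages:
        thr = cfg.snp_thresholds()
        calls = snp_indel.call_snps(data["evolved"]["pileup"], data["parent"]["pileup"], mask, thr)
        frac = snp_indel.callable_fraction(
            data["evolved"]["pileup"], data["parent"]["pileup"], mask, thr
        )
        write_vcf(out / "snps.vcf", genome, calls)
        report["snps"] = {
            "n_calls": len(calls),
            "callable_fraction": round(frac, 4),
            "calls": [dataclasses.asdict(c) for c in calls],
        }
        logger.info("SNPs called: %d (callable fraction %.4f)", len(calls), frac)

    if "indels" in cfg.stages:
        candidates = snp_indel.screen_indels(
            data["evolved"]["unmapped"],
            data["parent"]["unmapped"],
            genome,
            data["evolved"]["alignments"],
            data["parent"]["alignments"],
            mask=mask,
            min_support=cfg.indel_min_support,
        )
        pd.DataFrame([dataclasses.asdict(c) for c in candidates]).to_csv(
            out / "indels.tsv", sep="\t", index=False
        )
        report["indels"] = {"n_candidates": len(candidates)}
        logger.info("indel candidates: %d", len(candidates))

    segments: dict[str, list[cnv.Segment]] = {}
    amp_segment: cnv.Segment | None = None
    if "cnv" in cfg.stages:
        bins = cnv.bin_depth(
            data["evolved"]["track"], data["parent"]["track"], mask, cfg.bin_width
        )
        segments = cnv.segment_genome(bins, cfg.cbs_params())
        write_segments(out / "segments.bed", out / "segments.tsv", segments)
        all_segs = [s for segs in segments.values() for s in segs]
        if all_segs:
            amp_segment = max(all_segs, key=lambda s: abs(s.mean_log2))
            if abs(amp_segment.mean_log2) < 0.5:  # no CNV: all segments at baseline
                amp_segment = None
        report["cnv"] = {
            "n_segments": sum(len(s) for s in segments.values()),
            "segments": [dataclasses.asdict(s) for segs in segments.values() for s in segs],
        }
        if amp_segment is not None:
            ratio, nearest, dist = cnv.copy_ratio(amp_segment)
            report["cnv"]["amplified_segment"] = {
                "chrom": amp_segment.chrom,
                "start": amp_segment.start,
                "end": amp_segment.end,
                "copy_ratio": round(ratio, 3),
                "nearest_integer": nearest,
                "uncertainty_bp": amp_segment.uncertainty_bp,
            }
            logger.info(
                "amplified segment %s:%d-%d, copy ratio %.2f",
                amp_segment.chrom,
                amp_segment.start,
                amp_segment.end,
                ratio,
            )

    if "breakpoints" in cfg.stages:
        report["breakpoints"] = _breakpoint_stage(cfg, out, genome, mask, data, amp_segment)

    with open(out / "report.json", "w") as fhj:
        json.dump(report, fhj, indent=2)
        fhj.write("\n")
    return report


def _breakpoint_stage(cfg, out, genome, mask, data, amp_segment) -> dict:
    contigs = bp.assemble_contigs(
        data["evolved"]["unmapped"], k=cfg.assembly_k, min_contig_len=cfg.min_contig_len
    )
    alns_by_contig = {
        c.id: bp.align_contig(c, genome, cfg.min_identity) for c in contigs
    }
    retained = bp.filter_contigs(contigs, alns_by_contig, mask, cfg.min_contig_coverage)
    calls = []
    for contig, alns in retained:
        if len(alns) != 2:
            continue
        calls.append((contig, bp.classify_breakpoint(contig, alns, amp_segment)))

    # ancestor-background contigs for the probability estimate
    bg_contigs = bp.assemble_contigs(
        data["parent"]["unmapped"], k=cfg.assembly_k, min_contig_len=cfg.min_contig_len
    )
    bg_aln = {c.id: bp.align_contig(c, genome, cfg.min_identity) for c in bg_contigs}
    bg_retained = [
        (c, a)
        for c, a in bp.filter_contigs(bg_contigs, bg_aln, mask, cfg.min_contig_coverage)
        if all(mapping.is_nuclear(x.chrom) for x in a)
    ]
    n_mappable = mask.n_mappable(nuclear_only=True)
    p_bg = bp.background_probability(
        len(bg_retained), n_mappable, cfg.background_window, n_breakpoints=2
    )

    left_call = right_call = None
    wt_left = wt_right = False
    if amp_segment is not None:
        in_amp = [(c, call) for c, call in calls if call.in_amplification]
        mid = (amp_segment.start + amp_segment.end) / 2

        def boundary_coord(call: bp.BreakpointCall) -> float:
            return min(call.junction_coords, key=lambda x: abs(x - mid))

        lefts = [x for x in in_amp if boundary_coord(x[1]) < mid]
        rights = [x for x in in_amp if boundary_coord(x[1]) >= mid]
        if lefts:
            left_call = max(lefts, key=lambda x: len(x[0].sequence))[1]
        if rights:
            right_call = max(rights, key=lambda x: len(x[0].sequence))[1]
        evo_alns = data["evolved"]["alignments"]
        if left_call is not None:
            wt_left, _ = bp.wildtype_support(
                evo_alns, genome, left_call.chrom, boundary_coord(left_call), cfg.wildtype_min_span
            )
        if right_call is not None:
            wt_right, _ = bp.wildtype_support(
                evo_alns, genome, right_call.chrom, boundary_coord(right_call), cfg.wildtype_min_span
            )
    copy_number = cnv.copy_ratio(amp_segment)[0] if amp_segment is not None else float("nan")
    model = bp.infer_structure(
        amp_segment, copy_number, left_call, right_call, wt_left, wt_right, p_bg
    )

    # outputs
    with open(out / "junction_contigs.fasta", "w") as fhf:
        for contig, call in calls:
            fhf.write(f">{contig.id} overlap={call.overlap} {call.orientation}\n")
            fhf.write(contig.sequence + "\n")
    rows = [
        {
            "contig_id": c.id,
            "length": len(c.sequence),
            "n_reads": c.n_reads,
            "chrom": call.chrom,
            "orientation": call.orientation,
            "overlap_nt": call.overlap,
            "junction_coords": f"{call.junction_coords[0]},{call.junction_coords[1]}",
            "in_amplification": call.in_amplification,
            "sequence": c.sequence,
        }
        for c, call in calls
    ]
    pd.DataFrame(rows).to_csv(out / "breakpoints.tsv", sep="\t", index=False)

    result = {
        "n_contigs": len(contigs),
        "n_retained": len(retained),
        "n_classified": len(calls),
        "n_background_contigs": len(bg_retained),
        "background_probability": p_bg,
        "structure": model.structure,
        "copy_number": None if np.isnan(model.copy_number) else round(model.copy_number, 3),
        "evidence": model.evidence,
    }
    if left_call is not None:
        result["left_overlap_nt"] = left_call.overlap
    if right_call is not None:
        result["right_overlap_nt"] = right_call.overlap
    logger.info("structure: %s (P_background = %.3g)", model.structure, p_bg)
    return result


def simulate_and_run(config: PipelineConfig | None = None, seed: int = 0) -> dict:
    """Convenience wrapper: generate the demo scenario in memory and run all
    stages on it (no intermediate FASTQ round-trip).  Returns the report
    augmented with the truth record."""
    cfg = config or PipelineConfig()
    cfg = dataclasses.replace(cfg, seed=seed)
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    reference, evolved, truth, reads_evo, reads_par = demo_scenario(cfg)

    index = mapping.build_index(reference, cfg.read_length)
    mask = mapping.mappability_mask(reference, cfg.read_length, index=index)
    data = {}
    for strain, reads in (("evolved", reads_evo), ("parent", reads_par)):
        alns, unmapped = mapping.map_reads(reads, index, cfg.max_mismatches)
        track, pile = mapping.pileup(alns, reference)
        data[strain] = {"alignments": alns, "unmapped": unmapped, "track": track, "pileup": pile}

    report: dict = {"stages": list(cfg.stages), "truth": {
        "snps": truth.snps,
        "amplification": truth.amplification,
    }}
    thr = cfg.snp_thresholds()
    calls = snp_indel.call_snps(data["evolved"]["pileup"], data["parent"]["pileup"], mask, thr)
    report["snps"] = {
        "n_calls": len(calls),
        "callable_fraction": round(
            snp_indel.callable_fraction(
                data["evolved"]["pileup"], data["parent"]["pileup"], mask, thr
            ),
            4,
        ),
        "calls": [dataclasses.asdict(c) for c in calls],
    }
    bins = cnv.bin_depth(data["evolved"]["track"], data["parent"]["track"], mask, cfg.bin_width)
    segments = cnv.segment_genome(bins, cfg.cbs_params())
    all_segs = [s for segs in segments.values() for s in segs]
    amp_segment = max(all_segs, key=lambda s: abs(s.mean_log2)) if all_segs else None
    if amp_segment is not None and abs(amp_segment.mean_log2) < 0.5:
        amp_segment = None
    report["cnv"] = {
        "segments": [dataclasses.asdict(s) for s in all_segs],
    }
    if amp_segment is not None:
        ratio, nearest, dist = cnv.copy_ratio(amp_segment)
        report["cnv"]["amplified_segment"] = {
            "chrom": amp_segment.chrom,
            "start": amp_segment.start,
            "end": amp_segment.end,
            "copy_ratio": round(ratio, 4),
            "nearest_integer": nearest,
        }
    report["breakpoints"] = _breakpoint_stage(cfg, out, reference, mask, data, amp_segment)
    with open(out / "report.json", "w") as fhj:
        json.dump(report, fhj, indent=2)
        fhj.write("\n")
    return report
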
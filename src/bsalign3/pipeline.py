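"""End-to-end orchestration: index -> prep -> align -> recount -> call -> QC.

The unit of work is a read chunk; chunks are processed independently (in
one process, or a worker pool when ``threads > 1``) and their SAM bodies
are concatenated in chunk order, so output is invariant to the chunk count
and worker count — per-read determinism is guaranteed by the read-id-seeded
recount RNG.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
import tomllib
from concurrent.futures import ProcessPoolExecutor
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

from .align import AlignerParams, align_read
from .genome import Genome, revcomp
from .index import ThreeLetterIndex, build_genome_index
from .methylation import call_methylation, write_cgmap
from .postprocess import recount_mismatches, sam_header, to_sam_record
from .qc import (
    conversion_efficiency,
    genome_windows,
    metaplot,
    mismatch_by_position,
    plot_metaplot,
    plot_mismatch_profile,
    read_features,
)
from .read_prep import (
    DEFAULT_ADAPTER,
    DEFAULT_MIN_OVERLAP,
    DEFAULT_MIN_READ_LEN,
    BisRead,
    chunk_fastq,
    read_fastq,
    trim_adapter,
)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All pipeline parameters; serializable to/from a flat TOML file."""

    fasta: str = ""
    reads: str = ""
    outdir: str = "bsalign3_out"
    seed_len: int = 20
    stride: int = 0  # 0 -> seed_len
    max_edit: int = -1  # -1 -> auto: max(4, ceil(0.06 * read_len))
    uniqueness_gap: int = 2
    max_seed_hits: int = 1000
    max_candidates: int = 50
    adapter: str = DEFAULT_ADAPTER
    trim: bool = True
    min_overlap: int = DEFAULT_MIN_OVERLAP
    min_read_len: int = DEFAULT_MIN_READ_LEN
    chunks: int = 1
    threads: int = 1
    non_directional: bool = False
    spike_chrom: str = ""
    min_cov: int = 1
    window_bp: int = 10000
    features: str = ""  # BED6/GFF3 path for metaplots
    body_bins: int = 60
    flank_bp: int = 2000
    flank_bins: int = 20

    def aligner_params(self) -> AlignerParams:
        return AlignerParams(
            stride=self.stride or None,
            max_edit_distance=None if self.max_edit < 0 else self.max_edit,
            uniqueness_gap=self.uniqueness_gap,
            max_seed_hits=self.max_seed_hits,
            max_candidates=self.max_candidates,
            non_directional=self.non_directional,
        )

    def to_toml(self, path) -> None:
        with open(path, "wt") as fh:
            for f in dataclasses.fields(self):
                v = getattr(self, f.name)
                if isinstance(v, bool):
                    fh.write(f"{f.name} = {'true' if v else 'false'}\n")
                elif isinstance(v, (int, float)):
                    fh.write(f"{f.name} = {v}\n")
                else:
                    fh.write(f'{f.name} = "{v}"\n')

    @classmethod
    def from_toml(cls, path) -> "PipelineConfig":
        with open(path, "rb") as fh:
            data = tomllib.load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        extra = set(data) - known
        if extra:
            raise ValueError(f"unknown config keys: {sorted(extra)}")
        return cls(**data)


@dataclass
class ChunkCounts:
    n_reads: int = 0
    n_discarded: int = 0
    n_unique: int = 0
    n_multiple: int = 0
    n_unmapped: int = 0

    def add(self, other: "ChunkCounts") -> None:
        for f in dataclasses.fields(self):
            setattr(self, f.name, getattr(self, f.name) + getattr(other, f.name))


# worker globals (populated by fork or initializer; chunks share one index)
_WORK: Dict[str, object] = {}


def _init_worker(index: ThreeLetterIndex, config: PipelineConfig) -> None:
    _WORK["index"] = index
    _WORK["config"] = config


def process_chunk(
    chunk_path,
    index: ThreeLetterIndex,
    config: PipelineConfig,
    sam_path,
) -> ChunkCounts:
    """Trim, align, recount and write one chunk's SAM records."""
    params = config.aligner_params()
    genome = index.genome
    counts = ChunkCounts()
    header = sam_header(genome)
    import pysam

    with pysam.AlignmentFile(str(sam_path), "wh", header=header) as out:
        for rid, seq, qual in read_fastq(chunk_path):
            counts.n_reads += 1
            read = BisRead(rid, seq, qual,
                           "non_directional" if config.non_directional else "directional")
            if config.trim:
                read = trim_adapter(read, config.adapter, config.min_overlap, config.min_read_len)
            if read.discarded:
                counts.n_discarded += 1
                continue
            aln = align_read(read, index, params)
            effective_seq = None
            if aln.orientation == "rc":
                read = BisRead(rid, revcomp(read.original_seq), read.quals[::-1],
                               read.library_mode)
            report = None
            if aln.status == "unique":
                max_mm = params.resolve_max_d(len(read))
                report = recount_mismatches(aln, read.original_seq, genome, max_mm, rid)
                if not report.accepted:
                    aln = dataclasses.replace(
                        aln, status="unmapped", locus=None, script=None, reason="recount"
                    )
                    report = None
            if aln.status == "unique":
                counts.n_unique += 1
            elif aln.status == "multiple":
                counts.n_multiple += 1
            else:
                counts.n_unmapped += 1
            out.write(to_sam_record(read, aln, report, header, effective_seq))
    return counts


def _process_chunk_worker(args) -> ChunkCounts:
    chunk_path, sam_path = args
    return process_chunk(chunk_path, _WORK["index"], _WORK["config"], sam_path)


def merge_sams(chunk_sams: List[Path], out_path, header_from: Path) -> None:
    """Concatenate chunk SAM bodies under a single header, in chunk order."""
    with open(out_path, "wt") as out:
        with open(header_from) as fh:
            for line in fh:
                if line.startswith("@"):
                    out.write(line)
                else:
                    break
        for p in chunk_sams:
            with open(p) as fh:
                for line in fh:
                    if not line.startswith("@"):
                        out.write(line)


def run_pipeline(config: PipelineConfig, index: Optional[ThreeLetterIndex] = None) -> Dict:
    """Run the full pipeline; returns the run report (also written as JSON).

    Stages: build (or reuse) the index, chunk the FASTQ, align/recount each
    chunk, merge SAM, call methylation to CGmap, then QC tables (per-cycle
    mismatch profile, genome windows, optional spike-in conversion
    efficiency and metaplot).
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    t0 = time.time()

    def stage(name):
        logger.info("stage %s (t=%.1fs)", name, time.time() - t0)

    stage("index")
    if index is None:
        genome = Genome.from_fasta(config.fasta)
        index = build_genome_index(genome, config.seed_len, config.max_seed_hits)
    genome = index.genome

    stage("chunk")
    chunk_dir = outdir / "chunks"
    chunk_paths = chunk_fastq(config.reads, config.chunks, chunk_dir)

    stage("align")
    sam_paths = [chunk_dir / f"{p.name}.sam" for p in chunk_paths]
    totals = ChunkCounts()
    if config.threads > 1 and len(chunk_paths) > 1:
        with ProcessPoolExecutor(
            max_workers=config.threads, initializer=_init_worker, initargs=(index, config)
        ) as pool:
            for counts in pool.map(_process_chunk_worker, zip(chunk_paths, sam_paths)):
                totals.add(counts)
    else:
        for cp, sp in zip(chunk_paths, sam_paths):
            totals.add(process_chunk(cp, index, config, sp))

    sam_path = outdir / "alignments.sam"
    merge_sams(sam_paths, sam_path, sam_paths[0] if sam_paths else None)

    stage("call")
    table = call_methylation(sam_path, genome, config.min_cov)
    cgmap_path = outdir / "sample.CGmap"
    write_cgmap(table, cgmap_path)

    stage("qc")
    profile = mismatch_by_position(sam_path, genome)
    profile.to_frame().to_csv(outdir / "qc_mismatch_by_position.tsv", sep="\t", index=False)
    plot_mismatch_profile(profile, outdir / "qc_mismatch_by_position.png")

    windows = genome_windows(table, config.window_bp)
    with open(outdir / "methylation_windows.tsv", "wt") as fh:
        fh.write("chrom\tstart\tCG\tCHG\tCHH\n")
        for chrom, frame in windows.items():
            for start, row in frame.iterrows():
                fh.write(f"{chrom}\t{start}\t{row.CG:.4f}\t{row.CHG:.4f}\t{row.CHH:.4f}\n")

    report: Dict = {
        "n_reads": totals.n_reads,
        "n_discarded": totals.n_discarded,
        "n_unique": totals.n_unique,
        "n_multiple": totals.n_multiple,
        "n_unmapped": totals.n_unmapped,
        "n_meth_sites": len(table),
        "elapsed_sec": round(time.time() - t0, 2),
    }
    assert (
        totals.n_discarded + totals.n_unique + totals.n_multiple + totals.n_unmapped
        == totals.n_reads
    ), "read conservation violated"

    if config.spike_chrom:
        stats = conversion_efficiency(table, config.spike_chrom)
        report["conversion_efficiency"] = stats.efficiency
        report["spike_chrom"] = config.spike_chrom

    if config.features:
        feats = read_features(config.features)
        prof = metaplot(table, feats, config.body_bins, config.flank_bp, config.flank_bins)
        prof.to_frame().to_csv(outdir / "metaplot.tsv", sep="\t", index=False)
        plot_metaplot(prof, outdir / "metaplot.png")

    with open(outdir / "report.json", "wt") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)
        fh.write("\n")
    stage("done")
    return report
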
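"""Readers, writers, configuration and the end-to-end pipeline driver.

All interchange formats are plain text: FASTA for genomes, SAM 1.6 for
alignments, TSV for metadata / gene-cluster / abundance tables, BED for
interval calls, Newick for dendrograms. Coordinates are 0-based half-open
internally and in BED; human-readable reports use 1-based inclusive
coordinates. A single global seed fans out to per-stage seeds by fixed
offsets so reruns are byte-identical.
"""

from __future__ import annotations

import dataclasses
import logging
from collections.abc import Iterable, Iterator, Sequence
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import pysam
import yaml
from Bio import SeqIO

from . import __version__
from .recruit import AlignmentRecord, RecruitmentConfig
from .synthetic import Genome

logger = logging.getLogger(__name__)

_ALLOWED = set("ACGTN")

METADATA_REQUIRED = ("sample_id", "latitude", "longitude", "depth",
                     "temperature", "oxygen", "salinity", "chlorophyll",
                     "nutrients")

#: fixed per-stage offsets from the global seed (kept < 2**31 total)
STAGE_SEED_OFFSETS = {"simulate": 0, "recruit": 1000, "snv": 2000,
                      "ecology": 3000}


def read_fasta(path) -> list[Genome]:
    """Parse a FASTA file into Genomes (upper-cased, U mapped to T).

    Records containing characters outside A/C/G/T/N are rejected, as are
    duplicate ids and empty files.
    """
    genomes: list[Genome] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper().replace("U", "T")
        bad = sorted(set(seq) - _ALLOWED)
        if bad:
            raise ValueError(
                f"record {rec.id!r} contains non-ACGTN characters: {bad}"
            )
        if rec.id in seen:
            raise ValueError(f"duplicate FASTA id {rec.id!r}")
        seen.add(rec.id)
        genomes.append(Genome(id=rec.id, sequence=seq))
    if not genomes:
        raise ValueError(f"no FASTA records in {path}")
    return genomes


def write_fasta(genomes: Iterable[Genome], path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for g in genomes:
            fh.write(f">{g.id}\n")
            for i in range(0, len(g.sequence), width):
                fh.write(g.sequence[i:i + width] + "\n")


def read_sam(path) -> Iterator[AlignmentRecord]:
    """Stream mapped primary alignments from a SAM file.

    Secondary (0x100), supplementary (0x800) and unmapped records are
    skipped. ``aligned_length`` is the reference-consuming span from the
    CIGAR; ``read_length`` comes from the CIGAR (or SEQ when the CIGAR is
    clipped-only). Records without an NM tag are skipped with a summary
    error raised after the stream is exhausted.
    """
    n_missing_nm = 0
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for aln in sam.fetch(until_eof=True):
            if aln.is_unmapped or aln.is_secondary or aln.is_supplementary:
                continue
            if not aln.has_tag("NM"):
                n_missing_nm += 1
                logger.error("record %s lacks NM tag; skipped",
                             aln.query_name)
                continue
            aligned = aln.reference_length or 0
            read_len = aln.infer_read_length()
            if read_len is None:
                read_len = len(aln.query_sequence or "")
            yield AlignmentRecord(
                read_id=aln.query_name,
                genome_id=aln.reference_name,
                ref_start=aln.reference_start,
                aligned_length=aligned,
                read_length=read_len,
                n_mismatches=int(aln.get_tag("NM")),
                mapq=aln.mapping_quality)
    if n_missing_nm:
        raise ValueError(
            f"{n_missing_nm} SAM records lacked the required NM tag"
        )


def read_metadata(path) -> pd.DataFrame:
    """Sample metadata TSV; validates required columns and latitude range."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in METADATA_REQUIRED if c not in df.columns]
    if missing:
        raise ValueError(f"metadata is missing required columns: {missing}")
    if (df["latitude"].abs() > 90).any():
        raise ValueError("metadata contains |latitude| > 90")
    return df


def write_metadata(designs, path) -> None:
    """Write CommunityDesign environments as a sample metadata TSV."""
    rows = []
    for d in designs:
        row = {"sample_id": d.sample_id}
        row.update({k: d.environment[k] for k in METADATA_REQUIRED[1:]})
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False,
                              float_format="%.6g")


def read_gene_clusters(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    needed = {"genome_id", "gene_id", "cluster_id"}
    missing = needed - set(df.columns)
    if missing:
        raise ValueError(f"gene-cluster table missing columns: {sorted(missing)}")
    return df


def write_truth(truths, path) -> None:
    pd.DataFrame([dataclasses.asdict(t) for t in truths]).to_csv(
        path, sep="\t", index=False)


def write_bed(intervals, path, name_prefix: str = "HVR",
              chrom: str = "genome") -> None:
    """Write interval calls (objects with start/end) as 0-based BED."""
    with open(path, "w") as fh:
        for i, iv in enumerate(intervals, 1):
            fh.write(f"{chrom}\t{iv.start}\t{iv.end}\t{name_prefix}{i}\n")


def hvr_report(calls, genome_id: str) -> str:
    """Human-readable HVR report with 1-based inclusive coordinates."""
    if not calls:
        return f"{genome_id}: no hypervariable region detected\n"
    lines = []
    for c in calls:
        lines.append(
            f"{genome_id}: putative HVR between {c.start + 1:,} and "
            f"{c.end:,} bp ({c.length:,} bp; mean depth inside "
            f"{c.mean_depth_inside:.1f}x vs genome median "
            f"{c.median_depth_genome:.1f}x)")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# pipeline driver
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """Paths and parameters for a full pipeline run."""

    genomes_fasta: str
    sam_files: list[str]
    metadata_tsv: str
    output_dir: str
    gene_clusters_tsv: str | None = None
    snv_genome: str | None = None       # defaults to the first genome
    recruitment: RecruitmentConfig = field(default_factory=RecruitmentConfig)
    hvr_threshold_fraction: float = 0.2
    hvr_min_length: int = 500
    hvr_min_median: float = 10.0
    snv_min_position_coverage: int = 10
    snv_min_departure: float = 0.10
    snv_sample_breadth: float = 0.70
    snv_cluster_k: int = 2
    ecology_min_prevalence: int = 5
    n_boot: int = 5000
    seed: int = 0
    total_reads_per_sample: int | None = None

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        rc = raw.pop("recruitment", None)
        cfg = cls(**raw)
        if rc:
            cfg.recruitment = RecruitmentConfig(**rc)
        return cfg

    def validate(self) -> None:
        for p in [self.genomes_fasta, self.metadata_tsv, *self.sam_files]:
            if not Path(p).exists():
                raise FileNotFoundError(p)
        if self.gene_clusters_tsv and not Path(self.gene_clusters_tsv).exists():
            raise FileNotFoundError(self.gene_clusters_tsv)


def stage_seed(seed: int, stage: str) -> int:
    return (seed * 10_000 + STAGE_SEED_OFFSETS[stage]) % (2 ** 31)


def run_pipeline(config: PipelineConfig) -> Path:
    """Run recruit -> coverage/HVR -> comparative -> SNV -> ecology.

    Writes plain-text outputs under ``config.output_dir`` plus a MANIFEST of
    completed stages and a run log echoing every parameter. Idempotent for a
    fixed config and seed. On a stage failure, partial outputs and the
    MANIFEST (listing the stages that did finish) are preserved.
    """
    from . import comparative, coverage_hvr, ecology, popgen, recruit

    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "coverage").mkdir(exist_ok=True)
    (out / "ecology").mkdir(exist_ok=True)
    completed: list[str] = []
    manifest = out / "MANIFEST"

    def checkpoint(stage: str) -> None:
        completed.append(stage)
        manifest.write_text("".join(f"{s}\n" for s in completed))

    genomes = {g.id: g for g in read_fasta(config.genomes_fasta)}
    metadata = read_metadata(config.metadata_tsv)

    with open(out / "run.log", "w") as log:
        log.write(f"pelagiscope {__version__}\n")
        log.write(f"seed: {config.seed}\n")
        for key, value in dataclasses.asdict(config).items():
            log.write(f"{key}: {value}\n")

    try:
        # --- recruitment + per-sample coverage ---------------------------
        results = []
        profiles_by_sample: dict[str, dict[str, coverage_hvr.CoverageProfile]] = {}
        for sam in config.sam_files:
            sample_id = Path(sam).stem
            res = recruit.recruit_sample(
                sam, genomes, config.recruitment, sample_id=sample_id,
                total_reads=config.total_reads_per_sample)
            results.append(res)
            records = recruit.filter_alignments(list(read_sam(sam)),
                                                config.recruitment)
            assignment = recruit.competitive_assign(records)
            per_genome: dict[str, coverage_hvr.CoverageProfile] = {}
            for gid, genome in genomes.items():
                recs = [r for r in records
                        if r.genome_id == gid
                        and assignment.get(r.read_id) == gid]
                per_genome[gid] = coverage_hvr.coverage_from_alignments(
                    recs, len(genome), genome_id=gid, sample_id=sample_id)
            profiles_by_sample[sample_id] = per_genome
            depth_frame = pd.DataFrame(
                {gid: prof.depth for gid, prof in sorted(per_genome.items())})
            depth_frame.insert(0, "position", np.arange(len(depth_frame)))
            depth_frame.to_csv(out / "coverage" / f"{sample_id}.tsv",
                               sep="\t", index=False)
        abundance = recruit.abundance_frame(results)
        abundance.to_csv(out / "abundance.tsv", sep="\t", index=False,
                         float_format="%.6g")
        checkpoint("recruit")
        checkpoint("coverage")

        # --- HVR + DTR on pooled coverage --------------------------------
        focal = config.snv_genome or sorted(genomes)[0]
        with open(out / "hvr_report.txt", "w") as rep, \
                open(out / "hvr.bed", "w") as bed:
            for gid, genome in sorted(genomes.items()):
                pooled = sum(profiles_by_sample[s][gid].depth
                             for s in profiles_by_sample)
                profile = coverage_hvr.CoverageProfile(
                    genome_id=gid, sample_id="pooled", depth=pooled)
                calls = coverage_hvr.call_hvrs(
                    profile, config.hvr_threshold_fraction,
                    config.hvr_min_length, config.hvr_min_median)
                rep.write(hvr_report(calls, gid))
                for i, c in enumerate(calls, 1):
                    bed.write(f"{gid}\t{c.start}\t{c.end}\tHVR{i}\n")
                dtr = coverage_hvr.detect_dtr(genome.sequence)
                if dtr:
                    rep.write(f"{gid}: direct terminal repeat of "
                              f"{dtr.length} bp\n")
        checkpoint("hvr")

        # --- comparative --------------------------------------------------
        genome_list = [genomes[g] for g in sorted(genomes)]
        summary = pd.DataFrame(
            [(g.id, *comparative.genome_summary(g)) for g in genome_list],
            columns=["genome_id", "length_bp", "gc_percent"])
        summary.to_csv(out / "genome_summary.tsv", sep="\t", index=False)
        if len(genome_list) >= 2:
            ani = comparative.ani_matrix(genome_list)
            ani.to_csv(out / "ani.tsv", sep="\t", float_format="%.4f")
            taxa = comparative.assign_taxa(ani)
            taxa.frame().to_csv(out / "taxa.tsv", sep="\t", index=False)
        if config.gene_clusters_tsv:
            table = read_gene_clusters(config.gene_clusters_tsv)
            pmat = comparative.shared_gene_pvalue_matrix(table)
            with np.errstate(divide="ignore"):
                neglog = -np.log10(pmat)
            neglog.to_csv(out / "gene_pvalues.tsv", sep="\t",
                          float_format="%.4f")
            core = comparative.core_genes(table,
                                          set(table["genome_id"]))
            (out / "core_genes.txt").write_text(
                "".join(f"{c}\n" for c in sorted(map(str, core))))
        checkpoint("comparative")

        # --- SNV population structure ------------------------------------
        ref = genomes[focal]
        snvs = {}
        focal_profiles = {}
        for sam in config.sam_files:
            sample_id = Path(sam).stem
            pileup = popgen.pileup_from_sam(
                sam, ref,
                min_identity=config.recruitment.min_identity,
                min_aligned_read_fraction=config.recruitment.min_aligned_read_fraction)
            snvs[sample_id] = popgen.call_snvs(
                pileup, ref, sample_id=sample_id,
                min_position_coverage=config.snv_min_position_coverage,
                min_departure=config.snv_min_departure)
            focal_profiles[sample_id] = profiles_by_sample[sample_id][focal]
        matrix = popgen.build_snv_matrix(
            snvs, focal_profiles,
            sample_breadth_cutoff=config.snv_sample_breadth,
            min_position_coverage=config.snv_min_position_coverage)
        matrix.frame().to_csv(out / "snv_matrix.tsv", sep="\t",
                              float_format="%.4f")
        if len(matrix.samples) >= 2 and matrix.positions:
            Z, labels = popgen.cluster_snv_profiles(
                matrix, k=min(config.snv_cluster_k, len(matrix.samples)))
            (out / "snv_dendrogram.nwk").write_text(
                popgen.dendrogram_to_newick(Z, list(matrix.samples)))
            pd.DataFrame(sorted(labels.items()),
                         columns=["sample_id", "cluster"]).to_csv(
                out / "snv_clusters.tsv", sep="\t", index=False)
        checkpoint("snv")

        # --- ecology ------------------------------------------------------
        rpkm = recruit.rpkm_matrix(abundance)
        kept = sorted(ecology.prevalence_filter(
            rpkm, config.ecology_min_prevalence))
        (out / "ecology" / "prevalent_genomes.txt").write_text(
            "".join(f"{g}\n" for g in kept))
        grid = ecology.regression_grid(rpkm, metadata)
        grid.to_csv(out / "ecology" / "regression_grid.tsv", sep="\t",
                    index=False, float_format="%.6g")
        bands = ecology.summarise_by_band(rpkm, metadata)
        bands.to_csv(out / "ecology" / "band_summary.tsv", sep="\t",
                     index=False, float_format="%.6g")
        if len(rpkm.columns) >= 2:
            rows = []
            gids = list(rpkm.columns)
            eco_seed = stage_seed(config.seed, "ecology")
            for i, ga in enumerate(gids):
                for gb in gids[i + 1:]:
                    es = ecology.bootstrap_median_difference(
                        rpkm[ga].to_numpy(), rpkm[gb].to_numpy(),
                        n_boot=config.n_boot, seed=eco_seed)
                    rows.append((ga, gb, es.statistic, es.ci_low,
                                 es.ci_high, es.n_boot))
            pd.DataFrame(rows, columns=["genome_a", "genome_b",
                                        "median_difference", "ci_low",
                                        "ci_high", "n_boot"]).to_csv(
                out / "ecology" / "effect_sizes.tsv", sep="\t",
                index=False, float_format="%.6g")
        checkpoint("ecology")
    except Exception:
        logger.exception("pipeline failed after stages: %s", completed)
        raise
    return out
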
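"""Competitive read recruitment with identity, fraction and breadth filters.

Implements the conservative recruitment standard used for quantifying phage
isolate genomes in ocean viromes: an alignment is kept only if it covers at
least 90% of the read at >=95% nucleotide identity, each read is assigned
competitively to its single best-matching genome, and a genome is reported as
detected in a sample only if recruited reads cover at least 40% of its length
(the breadth filter that suppresses false positives from shared genes and
conserved regions). Abundance is expressed as RPKM: reads per genome kilobase
per million sample reads.
"""

from __future__ import annotations

import logging
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class AlignmentRecord:
    """One read-to-reference alignment, reduced to recruitment essentials.

    ``aligned_length`` counts reference-consuming columns (CIGAR M/=/X/D);
    ``n_mismatches`` is the NM edit distance over the aligned span.
    """

    read_id: str
    genome_id: str
    ref_start: int
    aligned_length: int
    read_length: int
    n_mismatches: int
    mapq: int = 60

    @property
    def identity(self) -> float:
        """Percent-identity proxy: (aligned_length - NM) / aligned_length."""
        if self.aligned_length == 0:
            return 0.0
        return (self.aligned_length - self.n_mismatches) / self.aligned_length

    @property
    def aligned_read_fraction(self) -> float:
        return self.aligned_length / self.read_length if self.read_length else 0.0

    @property
    def ref_end(self) -> int:
        return self.ref_start + self.aligned_length


@dataclass(frozen=True)
class RecruitmentConfig:
    """Recruitment thresholds; defaults follow conservative virome practice."""

    min_identity: float = 0.95
    min_aligned_read_fraction: float = 0.90
    min_covered_fraction: float = 0.40
    rpkm_denominator: str = "sample_reads"  # or "filtered_mapped_reads"

    def __post_init__(self) -> None:
        for name in ("min_identity", "min_aligned_read_fraction",
                     "min_covered_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.rpkm_denominator not in ("sample_reads", "filtered_mapped_reads"):
            raise ValueError(
                f"unknown rpkm_denominator {self.rpkm_denominator!r}"
            )


@dataclass(frozen=True)
class GenomeAbundance:
    """Per-genome quantification within one sample."""

    reads_assigned: int
    covered_fraction: float
    rpkm_raw: float          # RPKM before the breadth filter
    rpkm: float              # 0 when the breadth filter fails
    passed_breadth_filter: bool


@dataclass
class RecruitmentResult:
    sample_id: str
    per_genome: dict[str, GenomeAbundance] = field(default_factory=dict)
    total_reads: int = 0
    filtered_reads: int = 0


def filter_alignments(records: Iterable[AlignmentRecord],
                      config: RecruitmentConfig | None = None,
                      ) -> list[AlignmentRecord]:
    """Keep records meeting the identity and aligned-read-fraction floors.

    Order is preserved. Zero-length alignments are dropped with a warning
    rather than raising, so one degenerate mapper record cannot abort a
    sample.
    """
    config = config or RecruitmentConfig()
    kept = []
    n_degenerate = 0
    for rec in records:
        if rec.aligned_length == 0:
            n_degenerate += 1
            continue
        if (rec.identity >= config.min_identity
                and rec.aligned_read_fraction >= config.min_aligned_read_fraction):
            kept.append(rec)
    if n_degenerate:
        logger.warning("dropped %d records with zero aligned length",
                       n_degenerate)
    return kept


def competitive_assign(records: Sequence[AlignmentRecord],
                       ) -> dict[str, str]:
    """Assign each read to its single best genome.

    Best = highest identity, ties broken by longer alignment, then by
    lexicographically smallest genome id (deterministic regardless of input
    order).
    """
    best: dict[str, AlignmentRecord] = {}
    for rec in records:
        cur = best.get(rec.read_id)
        if cur is None:
            best[rec.read_id] = rec
            continue
        key_new = (rec.identity, rec.aligned_length)
        key_cur = (cur.identity, cur.aligned_length)
        if key_new > key_cur or (key_new == key_cur
                                 and rec.genome_id < cur.genome_id):
            best[rec.read_id] = rec
    return {rid: rec.genome_id for rid, rec in best.items()}


def compute_rpkm(assigned_reads: int, genome_length: int,
                 denominator_reads: int) -> float:
    """Reads per genome kilobase per million (denominator) reads."""
    if genome_length < 1:
        raise ValueError(f"genome_length must be >= 1, got {genome_length}")
    if denominator_reads < 1:
        raise ValueError(
            f"denominator_reads must be >= 1, got {denominator_reads}"
        )
    return assigned_reads / (genome_length / 1e3) / (denominator_reads / 1e6)


def recruit_sample(sam_path, genomes: Mapping[str, "object"],
                   config: RecruitmentConfig | None = None,
                   sample_id: str | None = None,
                   total_reads: int | None = None) -> RecruitmentResult:
    """Quantify every genome in one sample: filter, assign, breadth, RPKM.

    ``genomes`` maps genome id to a Genome (anything with ``len()``).
    ``total_reads`` is the sample's sequencing depth for the RPKM
    denominator under the default ``sample_reads`` convention (viromes are
    typically subsampled to fixed depth); it defaults to the number of
    distinct read ids present in the SAM. Genomes whose covered fraction
    falls below the breadth threshold are reported with ``rpkm`` zeroed and
    the raw value retained in ``rpkm_raw``.
    """
    from .coverage_hvr import coverage_from_alignments
    from .io import read_sam

    config = config or RecruitmentConfig()
    records = list(read_sam(sam_path))
    unknown = sorted({r.genome_id for r in records} - set(genomes))
    if unknown:
        raise ValueError(
            f"SAM references genomes absent from the reference set: {unknown}"
        )
    all_read_ids = {r.read_id for r in records}
    if total_reads is None:
        total_reads = len(all_read_ids)

    filtered = filter_alignments(records, config)
    assignment = competitive_assign(filtered)
    n_filtered_reads = len(assignment)
    by_genome: dict[str, list[AlignmentRecord]] = {g: [] for g in genomes}
    for rec in filtered:
        if assignment.get(rec.read_id) == rec.genome_id:
            by_genome[rec.genome_id].append(rec)

    if config.rpkm_denominator == "sample_reads":
        denom = max(total_reads, 1)
    else:
        denom = max(n_filtered_reads, 1)

    result = RecruitmentResult(
        sample_id=sample_id or str(sam_path),
        total_reads=total_reads, filtered_reads=n_filtered_reads)
    for gid in sorted(genomes):
        recs = by_genome[gid]
        L = len(genomes[gid])
        # competitive assignment keeps one record per read, so depth>0
        # breadth equals breadth of assigned-read spans
        profile = coverage_from_alignments(recs, L, genome_id=gid,
                                           sample_id=result.sample_id)
        covered = float(np.count_nonzero(profile.depth)) / L
        raw = compute_rpkm(len(recs), L, denom)
        passed = covered >= config.min_covered_fraction
        result.per_genome[gid] = GenomeAbundance(
            reads_assigned=len(recs), covered_fraction=covered,
            rpkm_raw=raw, rpkm=raw if passed else 0.0,
            passed_breadth_filter=passed)
    return result


ABUNDANCE_COLUMNS = ["sample_id", "genome_id", "reads_assigned",
                     "covered_fraction", "rpkm_raw", "rpkm",
                     "passed_breadth_filter"]


def abundance_frame(results: Iterable[RecruitmentResult]) -> pd.DataFrame:
    """Long-format abundance table (one row per sample x genome)."""
    rows = []
    for res in results:
        for gid in sorted(res.per_genome):
            ab = res.per_genome[gid]
            rows.append((res.sample_id, gid, ab.reads_assigned,
                         ab.covered_fraction, ab.rpkm_raw, ab.rpkm,
                         ab.passed_breadth_filter))
    return pd.DataFrame(rows, columns=ABUNDANCE_COLUMNS)


def rpkm_matrix(abundance: pd.DataFrame) -> pd.DataFrame:
    """Pivot the long abundance table to a sample x genome RPKM matrix."""
    return (abundance.pivot(index="sample_id", columns="genome_id",
                            values="rpkm").sort_index())
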
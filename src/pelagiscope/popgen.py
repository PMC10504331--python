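"""SNV population profiling and substitution-accumulation estimation.

Within-species population structure is read from single-nucleotide-variant
profiles: per-position base pileups per sample, a departure-from-consensus
statistic (1 - consensus count / coverage), positional filters (minimum
coverage, minimum departure), a sample breadth filter (the genome must be
>=70% covered for a sample's profile to be trusted), and hierarchical
clustering of the resulting sample x position departure matrix. The
substitution-accumulation estimator turns literature per-infection mutation
rates into expected genome-wide substitutions over time.
"""

from __future__ import annotations

import logging
from collections.abc import Mapping, Sequence
from dataclasses import dataclass

import numpy as np
import pandas as pd
import pysam
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .coverage_hvr import CoverageProfile
from .synthetic import encode_sequence

logger = logging.getLogger(__name__)

BASES = "ACGT"


@dataclass(frozen=True)
class SNVRecord:
    """One variant position in one sample."""

    sample_id: str
    position: int            # 0-based
    coverage: int
    base_counts: tuple[int, int, int, int]  # A, C, G, T
    departure: float         # 1 - consensus_count / coverage, in [0, 0.75]


@dataclass(frozen=True)
class SNVMatrix:
    """Samples x positions departure matrix after all filters.

    ``values[i, j]`` is sample i's departure at retained position j; NaN
    marks positions under-covered in that sample (coverage below the
    per-position floor).
    """

    samples: tuple[str, ...]
    positions: tuple[int, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        if self.values.shape != (len(self.samples), len(self.positions)):
            raise ValueError("matrix shape does not match labels")

    @property
    def n_entries(self) -> int:
        return len(self.samples) * len(self.positions)

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.samples),
                            columns=[p + 1 for p in self.positions])


def pileup_from_sam(sam_path, reference, min_identity: float | None = 0.95,
                    min_aligned_read_fraction: float | None = 0.90,
                    ) -> np.ndarray:
    """Per-position base counts (L x 4, A/C/G/T) for one reference genome.

    Reads failing the recruitment identity/fraction filters are excluded so
    the pileup reflects the recruited population, not spurious hits. Only
    aligned (M/=/X) columns contribute.
    """
    L = len(reference)
    counts = np.zeros((L, 4), dtype=np.int64)
    base_code = {b: i for i, b in enumerate(BASES)}
    with pysam.AlignmentFile(str(sam_path), "r", check_sq=False) as sam:
        for aln in sam.fetch(until_eof=True):
            if (aln.is_unmapped or aln.is_secondary or aln.is_supplementary
                    or aln.reference_name != reference.id):
                continue
            ref_len = aln.reference_length or 0
            if ref_len == 0 or aln.query_sequence is None:
                continue
            if min_identity is not None:
                nm = aln.get_tag("NM")
                if (ref_len - nm) / ref_len < min_identity:
                    continue
            if min_aligned_read_fraction is not None:
                qlen = aln.infer_read_length() or len(aln.query_sequence)
                if ref_len / qlen < min_aligned_read_fraction:
                    continue
            for qpos, rpos in aln.get_aligned_pairs(matches_only=True):
                code = base_code.get(aln.query_sequence[qpos])
                if code is not None:
                    counts[rpos, code] += 1
    return counts


def call_snvs(pileup: np.ndarray, reference, sample_id: str = "",
              min_position_coverage: int = 10,
              min_departure: float = 0.10) -> list[SNVRecord]:
    """Positions with sufficient coverage and departure from consensus.

    The consensus is the most frequent base; ties resolve to the reference
    base when it is among the tied maxima (deterministic). Departure is
    1 - consensus_count/coverage, bounded by 0.75 over four bases.
    """
    pileup = np.asarray(pileup)
    if (pileup < 0).any():
        raise ValueError("pileup counts must be non-negative")
    coverage = pileup.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        departure = np.where(coverage > 0,
                             1.0 - pileup.max(axis=1) / np.maximum(coverage, 1),
                             0.0)
    keep = (coverage >= min_position_coverage) & (departure >= min_departure)
    ref_codes = encode_sequence(reference.sequence)
    records = []
    for pos in np.flatnonzero(keep):
        counts = pileup[pos]
        top = int(counts.max())
        # consensus only matters through its count here, but resolve ties
        # to the reference base for a deterministic consensus call
        tied = np.flatnonzero(counts == top)
        _consensus = int(ref_codes[pos]) if ref_codes[pos] in tied else int(tied[0])
        records.append(SNVRecord(
            sample_id=sample_id, position=int(pos),
            coverage=int(coverage[pos]),
            base_counts=tuple(int(c) for c in counts),
            departure=float(1.0 - top / coverage[pos])))
    return records


def build_snv_matrix(snvs: Mapping[str, Sequence[SNVRecord]],
                     profiles: Mapping[str, CoverageProfile],
                     sample_breadth_cutoff: float = 0.70,
                     min_position_coverage: int = 10) -> SNVMatrix:
    """Assemble the sample x position departure matrix.

    Samples whose genome covered fraction falls below
    ``sample_breadth_cutoff`` are dropped; the retained positions are the
    union of SNV positions across retained samples. An entry is the sample's
    departure at that position, 0.0 where the position is covered but
    invariant, and NaN where per-position coverage is below
    ``min_position_coverage``.
    """
    retained = [s for s in sorted(profiles)
                if profiles[s].covered_fraction >= sample_breadth_cutoff]
    dropped = sorted(set(profiles) - set(retained))
    if dropped:
        logger.info("dropped %d samples below breadth %.2f: %s",
                    len(dropped), sample_breadth_cutoff, dropped)
    if not retained:
        logger.warning("no sample passes the %.0f%% breadth cutoff",
                       100 * sample_breadth_cutoff)
        return SNVMatrix(samples=(), positions=(),
                         values=np.zeros((0, 0)))
    positions = sorted({rec.position for s in retained
                        for rec in snvs.get(s, ())})
    pos_index = {p: j for j, p in enumerate(positions)}
    values = np.zeros((len(retained), len(positions)))
    for i, s in enumerate(retained):
        depth = profiles[s].depth
        for j, p in enumerate(positions):
            if depth[p] < min_position_coverage:
                values[i, j] = np.nan
        for rec in snvs.get(s, ()):
            values[i, pos_index[rec.position]] = rec.departure
    return SNVMatrix(samples=tuple(retained), positions=tuple(positions),
                     values=values)


def impute_missing(matrix: SNVMatrix) -> np.ndarray:
    """Mean-impute NaN entries per position (0 when a column is all-NaN)."""
    vals = matrix.values.copy()
    if vals.size == 0:
        return vals
    col_mean = np.nanmean(np.where(np.isnan(vals), np.nan, vals), axis=0)
    col_mean = np.nan_to_num(col_mean, nan=0.0)
    nan_i, nan_j = np.nonzero(np.isnan(vals))
    vals[nan_i, nan_j] = col_mean[nan_j]
    return vals


def cluster_snv_profiles(matrix: SNVMatrix, linkage: str = "average",
                         metric: str = "euclidean", k: int | None = None,
                         distance_threshold: float | None = None,
                         ) -> tuple[np.ndarray, dict[str, int]]:
    """Hierarchically cluster sample SNV profiles.

    Returns the scipy linkage matrix and, when ``k`` or
    ``distance_threshold`` is given, flat cluster labels per sample
    (otherwise every sample gets label 1 at distance 0 cut... i.e. labels
    from a ``k=1`` cut are trivial; pass ``k`` for the grouping you want).
    """
    if len(matrix.samples) < 2:
        raise ValueError("need at least 2 retained samples to cluster")
    vals = impute_missing(matrix)
    Z = hierarchy.linkage(pdist(vals, metric=metric), method=linkage)
    if k is not None:
        flat = hierarchy.fcluster(Z, t=k, criterion="maxclust")
    elif distance_threshold is not None:
        flat = hierarchy.fcluster(Z, t=distance_threshold, criterion="distance")
    else:
        flat = np.ones(len(matrix.samples), dtype=int)
    return Z, {s: int(c) for s, c in zip(matrix.samples, flat)}


def isolate_pseudo_profile(genome, reference,
                           positions: Sequence[int]) -> np.ndarray:
    """Encode an isolate genome as a 0/1 departure vector vs the reference.

    Lets isolate genomes be clustered jointly with metagenome SNV profiles:
    departure 1.0 where the isolate differs from the reference, else 0.0.
    Genomes must be positionally homologous with the reference.
    """
    ref = encode_sequence(reference.sequence)
    iso = encode_sequence(genome.sequence)
    if len(ref) != len(iso):
        raise ValueError("isolate and reference must be equal length")
    pos = np.asarray(positions, dtype=int)
    return (iso[pos] != ref[pos]).astype(float)


def dendrogram_to_newick(Z: np.ndarray, labels: Sequence[str]) -> str:
    """Serialise a scipy linkage matrix as a Newick tree with branch lengths."""
    tree = hierarchy.to_tree(Z)

    def recurse(node, parent_dist) -> str:
        length = parent_dist - node.dist
        if node.is_leaf():
            return f"{labels[node.id]}:{length:.6g}"
        left = recurse(node.left, node.dist)
        right = recurse(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    return recurse(tree, tree.dist) + ";"


@dataclass(frozen=True)
class SubstitutionEstimate:
    """Expected genome-wide substitutions from per-site per-infection rates."""

    mu_low: float
    mu_high: float
    genome_length: int
    generations_per_year: float
    years: float
    subs_low: float
    subs_high: float


def substitution_accumulation(mu_low: float, mu_high: float,
                              genome_length: int,
                              generations_per_year: float = 1.0,
                              years: float = 1.0) -> SubstitutionEstimate:
    """subs = mu x genome_length x generations_per_year x years, per bound.

    With dsDNA-phage literature rates of 1e-6 to 1e-4 substitutions per site
    per infection and roughly one generation-equivalent per year, a 35 kb
    genome accumulates on the order of 0.04-3.5 substitutions per year.
    """
    if min(mu_low, mu_high, genome_length, generations_per_year, years) < 0:
        raise ValueError("all arguments must be non-negative")
    if mu_low > mu_high:
        raise ValueError("mu_low must not exceed mu_high")
    factor = genome_length * generations_per_year * years
    return SubstitutionEstimate(
        mu_low=mu_low, mu_high=mu_high, genome_length=genome_length,
        generations_per_year=generations_per_year, years=years,
        subs_low=mu_low * factor, subs_high=mu_high * factor)
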
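"""Comparative genomics: ANI, ICTV-style taxon clustering, shared genes.

Average nucleotide identity is computed ANIb-style: the query is cut into
non-overlapping fragments, each fragment is aligned to its best local match
in the subject (edit-distance infix alignment), fragments above a minimum
identity are averaged, and the two directions are averaged to a symmetric
value. ICTV viral demarcation thresholds (~95% ANI for species, here 60% for
genus following the phage-isolate convention) are applied by single-linkage
clustering. Gene-content relatedness between genome pairs is scored by the
upper-tail hypergeometric probability of their shared protein clusters, and
core genes are the clusters present in every member of a group.
"""

from __future__ import annotations

import itertools
import logging
import math
from collections.abc import Iterable, Sequence
from dataclasses import dataclass

import edlib
import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from scipy.stats import hypergeom

logger = logging.getLogger(__name__)

#: fragment identities below this are method noise, not homology signal
RELIABLE_ANI_FLOOR = 75.0


@dataclass(frozen=True)
class ANIResult:
    genome_a: str
    genome_b: str
    ani: float                # percent, bidirectional mean; NaN if no alignment
    aligned_fraction: float   # fraction of fragments that aligned

    @property
    def reliable(self) -> bool:
        """Fragment-ANI below ~75% is method-dependent; flag, don't trust."""
        return not math.isnan(self.ani) and self.ani >= RELIABLE_ANI_FLOOR


def _directional_ani(query: str, subject: str, fragment: int,
                     min_fragment_identity: float) -> tuple[float, float]:
    """(mean identity of accepted fragments, fraction of fragments accepted)."""
    frags = [query[i:i + fragment] for i in range(0, len(query), fragment)]
    # a trailing sliver carries no stable signal
    frags = [f for f in frags if len(f) >= max(100, fragment // 2)]
    if not frags:
        raise ValueError("query shorter than one usable fragment")
    identities = []
    for frag in frags:
        aln = edlib.align(frag, subject, mode="HW", task="distance")
        ident = 1.0 - aln["editDistance"] / len(frag)
        if ident >= min_fragment_identity:
            identities.append(ident)
    if not identities:
        return float("nan"), 0.0
    return float(np.mean(identities)), len(identities) / len(frags)


def compute_ani(a, b, fragment: int = 1000,
                min_fragment_identity: float = 0.3) -> ANIResult:
    """Bidirectional fragment-based ANI between two genomes (percent).

    ``a`` and ``b`` are Genome objects (or anything with ``id`` and
    ``sequence``). Fragments failing ``min_fragment_identity`` in their best
    placement are treated as unaligned and excluded from the mean, mirroring
    BLAST-based ANI which simply finds no hit for them.
    """
    if len(a.sequence) < fragment or len(b.sequence) < fragment:
        raise ValueError("both sequences must be at least one fragment long")
    ani_ab, frac_ab = _directional_ani(a.sequence, b.sequence, fragment,
                                       min_fragment_identity)
    ani_ba, frac_ba = _directional_ani(b.sequence, a.sequence, fragment,
                                       min_fragment_identity)
    vals = [v for v in (ani_ab, ani_ba) if not math.isnan(v)]
    ani = 100.0 * float(np.mean(vals)) if vals else float("nan")
    if not vals:
        logger.warning("no fragment of %s/%s aligned above identity %.2f",
                       a.id, b.id, min_fragment_identity)
    return ANIResult(genome_a=a.id, genome_b=b.id, ani=ani,
                     aligned_fraction=(frac_ab + frac_ba) / 2)


def ani_matrix(genomes: Sequence, fragment: int = 1000,
               min_fragment_identity: float = 0.3) -> pd.DataFrame:
    """Symmetric all-vs-all ANI matrix (percent; diagonal 100)."""
    ids = [g.id for g in genomes]
    mat = pd.DataFrame(np.full((len(ids), len(ids)), np.nan),
                       index=ids, columns=ids)
    for g in genomes:
        mat.loc[g.id, g.id] = 100.0
    for ga, gb in itertools.combinations(genomes, 2):
        res = compute_ani(ga, gb, fragment, min_fragment_identity)
        mat.loc[ga.id, gb.id] = res.ani
        mat.loc[gb.id, ga.id] = res.ani
    return mat


@dataclass(frozen=True)
class TaxonAssignment:
    """Species and genus cluster labels per genome (species nest in genera)."""

    species: dict[str, int]
    genus: dict[str, int]

    def frame(self) -> pd.DataFrame:
        ids = sorted(self.species)
        return pd.DataFrame({
            "genome_id": ids,
            "species_cluster": [self.species[g] for g in ids],
            "genus_cluster": [self.genus[g] for g in ids],
        })


def _threshold_clusters(mat: pd.DataFrame, threshold: float) -> dict[str, int]:
    """Single-linkage clusters: connected components of the >=threshold graph."""
    vals = np.nan_to_num(mat.to_numpy(dtype=float), nan=-np.inf)
    adj = csr_matrix(vals >= threshold)
    _, labels = connected_components(adj, directed=False)
    # relabel components in order of first appearance for determinism
    order: dict[int, int] = {}
    out = {}
    for gid, lab in zip(mat.index, labels):
        out[gid] = order.setdefault(int(lab), len(order) + 1)
    return out


def assign_taxa(ani: pd.DataFrame, species_threshold: float = 95.0,
                genus_threshold: float = 60.0) -> TaxonAssignment:
    """Cluster genomes into species and genera by ANI thresholds.

    Single linkage: any chain of pairwise links above the threshold joins a
    cluster, matching how dereplication thresholds are applied in practice.
    Because the species edge set is a subset of the genus edge set, species
    clusters always nest inside genus clusters.
    """
    if list(ani.index) != list(ani.columns):
        raise ValueError("ANI matrix must have identical row/column labels")
    arr = ani.to_numpy(dtype=float)
    asym = np.nanmax(np.abs(arr - arr.T)) if arr.size else 0.0
    if asym > 1e-6:
        raise ValueError(f"ANI matrix is asymmetric (max |a-aT| = {asym:g})")
    if not np.allclose(np.diag(arr), 100.0):
        raise ValueError("ANI matrix diagonal must be 100")
    return TaxonAssignment(
        species=_threshold_clusters(ani, species_threshold),
        genus=_threshold_clusters(ani, genus_threshold))


def shared_gene_pvalue(k_shared: int, n_a: int, n_b: int,
                       n_universe: int) -> float:
    """P(X >= k_shared) for X ~ Hypergeometric(N=n_universe, K=n_b, n=n_a).

    The probability that two genomes drawing ``n_a`` and ``n_b`` protein
    clusters from a universe of ``n_universe`` would share at least
    ``k_shared`` of them by chance. Small values mean more shared gene
    content than chance allows.
    """
    if not (0 <= k_shared <= min(n_a, n_b)):
        raise ValueError(
            f"k_shared={k_shared} impossible for n_a={n_a}, n_b={n_b}"
        )
    if max(n_a, n_b) > n_universe:
        raise ValueError("genome cluster counts exceed the universe")
    if k_shared == 0:
        return 1.0
    # survival function is computed with log-gamma arithmetic internally
    return float(hypergeom.sf(k_shared - 1, n_universe, n_b, n_a))


GENE_TABLE_COLUMNS = ["genome_id", "gene_id", "cluster_id"]


def _check_gene_table(table: pd.DataFrame) -> None:
    missing = set(GENE_TABLE_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"gene-cluster table missing columns: {sorted(missing)}")
    if table["gene_id"].duplicated().any():
        dups = table.loc[table["gene_id"].duplicated(), "gene_id"].tolist()
        raise ValueError(f"genes assigned to multiple clusters: {dups[:5]}")


def clusters_per_genome(table: pd.DataFrame) -> dict[str, set]:
    _check_gene_table(table)
    return {gid: set(sub["cluster_id"])
            for gid, sub in table.groupby("genome_id")}


def shared_gene_pvalue_matrix(table: pd.DataFrame,
                              universe: str = "group") -> pd.DataFrame:
    """Pairwise upper-tail shared-cluster probabilities for all genomes.

    ``universe`` is the hypergeometric population size: ``"group"`` counts
    the distinct clusters across the compared genome set (default),
    ``"table"`` counts every cluster in the table (these differ only when
    the table carries genomes beyond the compared set).
    """
    by_genome = clusters_per_genome(table)
    ids = sorted(by_genome)
    if universe == "table":
        n_u = table["cluster_id"].nunique()
    elif universe == "group":
        n_u = len(set().union(*by_genome.values())) if ids else 0
    else:
        raise ValueError(f"unknown universe {universe!r}")
    mat = pd.DataFrame(np.ones((len(ids), len(ids))), index=ids, columns=ids)
    for a, b in itertools.combinations(ids, 2):
        ca, cb = by_genome[a], by_genome[b]
        p = shared_gene_pvalue(len(ca & cb), len(ca), len(cb), n_u)
        mat.loc[a, b] = p
        mat.loc[b, a] = p
    return mat


def core_genes(table: pd.DataFrame, group: Iterable[str]) -> set:
    """Clusters with at least one gene in every genome of ``group``."""
    group = set(group)
    if not group:
        raise ValueError("group must be non-empty")
    by_genome = clusters_per_genome(table)
    missing = group - set(by_genome)
    if missing:
        raise ValueError(f"genomes absent from table: {sorted(missing)}")
    core = set.intersection(*(by_genome[g] for g in sorted(group)))
    return core


def genome_summary(genome) -> tuple[int, float]:
    """(length in bp, G+C percent to one decimal). N bases are ignored in G+C."""
    seq = genome.sequence
    if not seq:
        raise ValueError("empty sequence")
    gc = seq.count("G") + seq.count("C")
    acgt = len(seq) - seq.count("N")
    if acgt == 0:
        raise ValueError("sequence has no unambiguous bases")
    return len(seq), round(100.0 * gc / acgt, 1)
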
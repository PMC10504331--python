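"""Synthetic virome generator with known ground truth.

Emulates the data a pelagiphage recruitment study consumes: small phage
genomes (optionally carrying a direct terminal repeat), strain populations
that diverge sharply inside a planted hypervariable interval, shotgun reads
drawn from an environment-driven community, and the SAM alignments a mapper
would report against each species' reference genome.

The mutation and sequencing-error model is substitution-only (no indels), so
every alignment identity is analytically checkable from mismatch counts.
Reads are reported against the *species reference*, not the strain they were
drawn from: mismatches accumulated inside a divergent interval push those
reads below recruitment identity thresholds, which is exactly the mechanism
that produces coverage troughs over hypervariable regions in real viromes.
"""

from __future__ import annotations

import dataclasses
import logging
from collections.abc import Callable, Mapping, Sequence
from dataclasses import dataclass, field

import numpy as np

from .recruit import AlignmentRecord

logger = logging.getLogger(__name__)

_BASES = "ACGT"
_BASE_TO_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(_BASES):
    _BASE_TO_CODE[ord(_b)] = _i
_CODE_TO_BASE = np.frombuffer(_BASES.encode(), dtype=np.uint8)


def encode_sequence(sequence: str) -> np.ndarray:
    """Encode an ACGT string as a uint8 code array (A=0, C=1, G=2, T=3)."""
    arr = _BASE_TO_CODE[np.frombuffer(sequence.encode(), dtype=np.uint8)]
    if (arr == 255).any():
        bad = sorted({c for c in sequence if c not in _BASES})
        raise ValueError(f"sequence contains non-ACGT characters: {bad}")
    return arr


def decode_sequence(codes: np.ndarray) -> str:
    return _CODE_TO_BASE[codes].tobytes().decode()


@dataclass(frozen=True)
class GenomeTruth:
    """Planted features of a synthetic genome (zero/None when absent)."""

    dtr_length: int = 0
    hvr_interval: tuple[int, int] | None = None


@dataclass(frozen=True)
class Genome:
    """A named nucleotide sequence with optional planted-feature truth.

    ``sequence`` is restricted to upper-case A/C/G/T (ambiguity codes are the
    concern of the FASTA reader, which maps what it can and rejects the rest);
    a non-zero ``truth.dtr_length`` promises that the first and last
    ``dtr_length`` bases are identical.
    """

    id: str
    sequence: str
    truth: GenomeTruth = field(default_factory=GenomeTruth)

    def __post_init__(self) -> None:
        if len(self.sequence) == 0:
            raise ValueError(f"genome {self.id!r}: empty sequence")
        if self.truth.dtr_length > 0:
            L = self.truth.dtr_length
            if self.sequence[:L] != self.sequence[-L:]:
                raise ValueError(
                    f"genome {self.id!r}: declared {L} bp terminal repeat "
                    "does not match the sequence ends"
                )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class CommunityDesign:
    """One virome sample: its environment and genome abundance weights."""

    sample_id: str
    environment: Mapping[str, float]
    genome_weights: Mapping[str, float]

    def __post_init__(self) -> None:
        w = np.array(list(self.genome_weights.values()), dtype=float)
        if w.size == 0:
            raise ValueError(f"sample {self.sample_id!r}: empty community")
        if (w < 0).any():
            raise ValueError(f"sample {self.sample_id!r}: negative weight")
        if abs(w.sum() - 1.0) > 1e-9:
            raise ValueError(
                f"sample {self.sample_id!r}: weights sum to {w.sum()!r}, not 1"
            )


@dataclass(frozen=True)
class ReadTruth:
    """Provenance of one simulated read."""

    read_id: str
    source_genome: str
    source_strain: str
    true_start: int
    n_errors: int


# ---------------------------------------------------------------------------
# genome and strain simulation
# ---------------------------------------------------------------------------

def simulate_genome(length: int, gc_fraction: float, seed: int,
                    genome_id: str = "synthetic") -> Genome:
    """Draw an i.i.d. random genome with expected G+C ``gc_fraction``.

    Each base is G or C with total probability ``gc_fraction`` (split evenly
    between the two), else A or T.
    """
    if length < 1:
        raise ValueError(f"length must be >= 1, got {length}")
    if not 0.0 <= gc_fraction <= 1.0:
        raise ValueError(f"gc_fraction must be in [0, 1], got {gc_fraction}")
    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc_fraction) / 2, gc_fraction / 2,
                  gc_fraction / 2, (1 - gc_fraction) / 2])
    codes = rng.choice(4, size=length, p=p).astype(np.uint8)
    return Genome(id=genome_id, sequence=decode_sequence(codes))


def plant_dtr(genome: Genome, dtr_length: int) -> Genome:
    """Copy the genome's first ``dtr_length`` bases over its last ones.

    Models the direct terminal repeat left by pac-type headful packaging on a
    linearised genome. The repeat must be shorter than half the genome so the
    two copies cannot overlap.
    """
    L = len(genome)
    if not 0 < dtr_length < L / 2:
        raise ValueError(
            f"dtr_length must be in (0, {L / 2}), got {dtr_length}"
        )
    seq = genome.sequence[:-dtr_length] + genome.sequence[:dtr_length]
    truth = dataclasses.replace(genome.truth, dtr_length=dtr_length)
    return Genome(id=genome.id, sequence=seq, truth=truth)


def simulate_strains(reference: Genome, n_strains: int,
                     background_divergence: float,
                     hvr_interval: tuple[int, int] | None,
                     hvr_divergence: float, seed: int) -> list[Genome]:
    """Derive strain genomes by per-site substitution from a reference.

    Sites mutate independently at rate ``background_divergence`` outside the
    hypervariable interval and ``hvr_divergence`` inside it; a mutated site is
    replaced by one of the three other bases uniformly. No indels.
    """
    if not 0 <= background_divergence <= hvr_divergence <= 1:
        raise ValueError(
            "need 0 <= background_divergence <= hvr_divergence <= 1, got "
            f"{background_divergence}, {hvr_divergence}"
        )
    L = len(reference)
    if hvr_interval is not None:
        s, e = hvr_interval
        if not 0 <= s < e <= L:
            raise ValueError(
                f"hvr_interval {hvr_interval} out of bounds for {L} bp genome"
            )
    rng = np.random.default_rng(seed)
    ref_codes = encode_sequence(reference.sequence)
    rate = np.full(L, background_divergence)
    if hvr_interval is not None:
        rate[hvr_interval[0]:hvr_interval[1]] = hvr_divergence
    strains = []
    for i in range(n_strains):
        mutate = rng.random(L) < rate
        codes = ref_codes.copy()
        # shift by 1..3 mod 4: uniform over the three non-reference bases
        shifts = rng.integers(1, 4, size=int(mutate.sum()), dtype=np.uint8)
        codes[mutate] = (codes[mutate] + shifts) % 4
        # substitutions break an exact terminal repeat, so strains never
        # inherit the reference's DTR truth
        truth = GenomeTruth(dtr_length=0, hvr_interval=hvr_interval)
        strains.append(Genome(id=f"{reference.id}|strain{i + 1}",
                              sequence=decode_sequence(codes), truth=truth))
    return strains


# ---------------------------------------------------------------------------
# read simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SimulatedRead:
    """One read with its sequence and its mismatch count vs the reference."""

    read_id: str
    genome_id: str
    strain_id: str
    start: int
    sequence: str
    n_mismatches: int  # vs species reference (strain divergence + errors)
    n_errors: int      # sequencing errors only


def _resolve_strains(genomes: Mapping[str, Genome],
                     strains_per_genome: Mapping[str, Sequence[Genome]] | None,
                     gid: str) -> list[Genome]:
    if strains_per_genome and gid in strains_per_genome and strains_per_genome[gid]:
        return list(strains_per_genome[gid])
    return [genomes[gid]]


def simulate_reads(community: CommunityDesign,
                   genomes: Mapping[str, Genome],
                   strains_per_genome: Mapping[str, Sequence[Genome]] | None,
                   n_reads: int, read_length: int, error_rate: float,
                   seed: int,
                   dtr_duplication: bool = False,
                   ) -> tuple[list[SimulatedRead], list[ReadTruth]]:
    """Draw reads from a community; the in-memory core of :func:`simulate_sample`.

    Genomes are chosen by their community weights, strains uniformly within a
    genome, start positions uniformly over the linear genome (reads never
    overhang the end). With ``dtr_duplication`` the planted terminal-repeat
    interval is eligible to be sampled twice, emulating the doubled terminal
    coverage that headful packaging produces in real libraries.
    """
    if n_reads < 0:
        raise ValueError("n_reads must be >= 0")
    for gid in community.genome_weights:
        if gid not in genomes:
            raise ValueError(f"community references unknown genome {gid!r}")
        if read_length > len(genomes[gid]):
            raise ValueError(
                f"read_length {read_length} exceeds genome {gid!r} length"
            )
    rng = np.random.default_rng(seed)
    gids = sorted(community.genome_weights)
    weights = np.array([community.genome_weights[g] for g in gids])
    counts = rng.multinomial(n_reads, weights)

    reads: list[SimulatedRead] = []
    truths: list[ReadTruth] = []
    read_no = 0
    for gid, count in zip(gids, counts):
        if count == 0:
            continue
        ref = genomes[gid]
        ref_codes = encode_sequence(ref.sequence)
        strains = _resolve_strains(genomes, strains_per_genome, gid)
        strain_idx = rng.integers(0, len(strains), size=count)
        L = len(ref)
        n_pos = L - read_length + 1
        if dtr_duplication and ref.truth.dtr_length > 0:
            # both physical copies of the terminal repeat shed reads, so
            # starts inside either copy carry double weight
            w = np.ones(n_pos)
            w[:ref.truth.dtr_length] = 2.0
            w[max(0, L - ref.truth.dtr_length):] = 2.0
            starts = rng.choice(n_pos, size=count, p=w / w.sum())
        else:
            starts = rng.integers(0, n_pos, size=count)
        for si in range(len(strains)):
            mask = strain_idx == si
            n = int(mask.sum())
            if n == 0:
                continue
            strain = strains[si]
            strain_codes = encode_sequence(strain.sequence)
            st = starts[mask]
            idx = st[:, None] + np.arange(read_length)[None, :]
            read_codes = strain_codes[idx]
            err = rng.random((n, read_length)) < error_rate
            n_err_per_read = err.sum(axis=1)
            shifts = rng.integers(1, 4, size=int(err.sum()), dtype=np.uint8)
            read_codes[err] = (read_codes[err] + shifts) % 4
            nm = (read_codes != ref_codes[idx]).sum(axis=1)
            for j in range(n):
                rid = f"{community.sample_id}.r{read_no + j:07d}"
                reads.append(SimulatedRead(
                    read_id=rid, genome_id=gid, strain_id=strain.id,
                    start=int(st[j]), sequence=decode_sequence(read_codes[j]),
                    n_mismatches=int(nm[j]), n_errors=int(n_err_per_read[j])))
                truths.append(ReadTruth(
                    read_id=rid, source_genome=gid, source_strain=strain.id,
                    true_start=int(st[j]), n_errors=int(n_err_per_read[j])))
            read_no += n
    return reads, truths


def reads_to_alignments(reads: Sequence[SimulatedRead]) -> list[AlignmentRecord]:
    """View simulated reads as full-length alignments to their reference."""
    return [AlignmentRecord(read_id=r.read_id, genome_id=r.genome_id,
                            ref_start=r.start,
                            aligned_length=len(r.sequence),
                            read_length=len(r.sequence),
                            n_mismatches=r.n_mismatches)
            for r in reads]


def competitive_alignments(reads: Sequence[SimulatedRead],
                           genomes: Mapping[str, Genome],
                           ) -> list[AlignmentRecord]:
    """Align each read against *every* genome at its source coordinates.

    Only meaningful for genome sets derived from a common ancestor by
    substitution (all the same length, positionally homologous), where it
    emulates the multi-reference hits a competitive mapper would report.
    """
    codes = {gid: encode_sequence(g.sequence) for gid, g in genomes.items()}
    out: list[AlignmentRecord] = []
    for r in reads:
        rc = encode_sequence(r.sequence)
        for gid in sorted(genomes):
            ref = codes[gid]
            if r.start + len(rc) > len(ref):
                continue
            nm = int((rc != ref[r.start:r.start + len(rc)]).sum())
            out.append(AlignmentRecord(
                read_id=r.read_id, genome_id=gid, ref_start=r.start,
                aligned_length=len(rc), read_length=len(rc),
                n_mismatches=nm))
    return out


def write_sam(reads: Sequence[SimulatedRead],
              genomes: Mapping[str, Genome], path) -> None:
    """Write simulated reads as SAM 1.6 text against the reference genomes."""
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unsorted\n")
        for gid in sorted(genomes):
            fh.write(f"@SQ\tSN:{gid}\tLN:{len(genomes[gid])}\n")
        for r in reads:
            fh.write("\t".join([
                r.read_id, "0", r.genome_id, str(r.start + 1), "60",
                f"{len(r.sequence)}M", "*", "0", "0", r.sequence, "*",
                f"NM:i:{r.n_mismatches}",
            ]) + "\n")


def simulate_sample(community: CommunityDesign,
                    genomes: Mapping[str, Genome],
                    strains_per_genome: Mapping[str, Sequence[Genome]] | None,
                    n_reads: int, read_length: int, error_rate: float,
                    seed: int, sam_path,
                    dtr_duplication: bool = False,
                    ) -> tuple[str, list[ReadTruth]]:
    """Simulate one virome sample and write its SAM file.

    Returns the SAM path and the per-read ground truth. SAM records carry a
    ``<read_length>M`` CIGAR and an ``NM:i`` tag equal to the read's actual
    mismatch count against the species reference (strain divergence plus
    sequencing error), so recruitment identity is exactly reconstructible.
    """
    reads, truths = simulate_reads(
        community, genomes, strains_per_genome, n_reads, read_length,
        error_rate, seed, dtr_duplication=dtr_duplication)
    write_sam(reads, genomes, sam_path)
    return str(sam_path), truths


# ---------------------------------------------------------------------------
# environmental gradient
# ---------------------------------------------------------------------------

#: temperature model: 30 °C at the equator, falling ~0.33 °C per degree of
#: absolute latitude, with 1 °C Gaussian station-to-station noise
TEMPERATURE_INTERCEPT = 30.0
TEMPERATURE_LAT_SLOPE = -0.33
TEMPERATURE_NOISE_SD = 1.0


def simulate_env_gradient(n_samples: int,
                          abundance_model: Mapping[str, Callable[[Mapping[str, float]], float]],
                          seed: int) -> list[CommunityDesign]:
    """Design communities along a latitude/temperature gradient.

    Latitudes are uniform on 0–90° absolute; temperature decreases linearly
    in latitude plus noise; oxygen, chlorophyll and nutrients rise in colder
    water while salinity is roughly flat, mimicking the covariate structure
    of global surface viromes. Each genome's weight is its
    ``abundance_model`` evaluated on the sample environment, renormalised.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    if not abundance_model:
        raise ValueError("abundance_model must name at least one genome")
    rng = np.random.default_rng(seed)
    designs = []
    for i in range(n_samples):
        lat = float(rng.uniform(0.0, 90.0))
        temp = (TEMPERATURE_INTERCEPT + TEMPERATURE_LAT_SLOPE * lat
                + rng.normal(0.0, TEMPERATURE_NOISE_SD))
        cold = max(0.0, TEMPERATURE_INTERCEPT - temp)
        env = {
            "latitude": lat,
            "longitude": float(rng.uniform(-180.0, 180.0)),
            "depth": 5.0,
            "temperature": temp,
            "oxygen": 200.0 + 5.0 * cold + float(rng.normal(0.0, 10.0)),
            "salinity": 35.0 + float(rng.normal(0.0, 0.5)),
            "chlorophyll": max(0.05, 0.1 + 0.03 * cold
                               + float(rng.normal(0.0, 0.05))),
            "nutrients": max(0.05, 0.5 + 0.05 * cold
                             + float(rng.normal(0.0, 0.1))),
        }
        weights = {}
        for gid in sorted(abundance_model):
            w = float(abundance_model[gid](env))
            if w < 0:
                raise ValueError(
                    f"abundance model for {gid!r} returned negative weight {w}"
                )
            weights[gid] = w
        total = sum(weights.values())
        if total <= 0:
            raise ValueError(
                f"sample {i}: all abundance weights are zero; community "
                "would be empty"
            )
        weights = {g: w / total for g, w in weights.items()}
        designs.append(CommunityDesign(sample_id=f"S{i + 1:03d}",
                                       environment=env,
                                       genome_weights=weights))
    return designs
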
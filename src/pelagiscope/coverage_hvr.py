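"""Per-base coverage profiles, hypervariable-region calls, terminal repeats.

A hypervariable region (HVR) is an interval where reads from a diverse viral
population fail to recruit to a specific strain's genome, visible as a run of
per-base depth far below the genome-wide median. The caller applies the
standard relative rule: depth below 20% of the median over at least 500
contiguous bases. Direct terminal repeats (DTRs) — the signature of pac-type
headful packaging on a linearised genome — are detected both from the
sequence (exact prefix == suffix match) and from the coverage profile
(~2x depth at the genome ends).
"""

from __future__ import annotations

import logging
from collections.abc import Sequence
from dataclasses import dataclass

import numpy as np

from .recruit import AlignmentRecord

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CoverageProfile:
    """Per-base read depth for one genome in one sample."""

    genome_id: str
    sample_id: str
    depth: np.ndarray  # int array, one entry per base

    def __post_init__(self) -> None:
        object.__setattr__(self, "depth", np.asarray(self.depth))
        if (self.depth < 0).any():
            raise ValueError("coverage depth must be non-negative")

    def __len__(self) -> int:
        return len(self.depth)

    @property
    def covered_fraction(self) -> float:
        return float(np.count_nonzero(self.depth)) / len(self.depth)

    @property
    def mean_depth(self) -> float:
        return float(self.depth.mean())


@dataclass(frozen=True)
class HVRCall:
    """One hypervariable interval, 0-based half-open coordinates."""

    start: int
    end: int
    mean_depth_inside: float
    median_depth_genome: float

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class DTRCall:
    length: int
    method: str = "prefix_suffix_repeat"


def coverage_from_alignments(records: Sequence[AlignmentRecord],
                             genome_length: int, genome_id: str = "",
                             sample_id: str = "") -> CoverageProfile:
    """Depth vector from alignment spans (difference-array accumulation).

    Deletions consume reference in ``aligned_length`` and therefore count as
    covered, matching how depth-from-span tools report them.
    """
    diff = np.zeros(genome_length + 1, dtype=np.int64)
    for rec in records:
        if rec.ref_start < 0 or rec.ref_end > genome_length:
            raise ValueError(
                f"record {rec.read_id!r} spans [{rec.ref_start}, "
                f"{rec.ref_end}) outside the {genome_length} bp genome"
            )
        diff[rec.ref_start] += 1
        diff[rec.ref_end] -= 1
    depth = np.cumsum(diff[:-1])
    return CoverageProfile(genome_id=genome_id, sample_id=sample_id,
                           depth=depth)


def lower_median(values: np.ndarray) -> float:
    """Median with even-length ties resolved to the lower element.

    Keeps the HVR threshold an integer multiple of an observed depth value,
    so calls are deterministic on integer profiles.
    """
    v = np.sort(np.asarray(values))
    if v.size == 0:
        raise ValueError("empty depth vector")
    return float(v[(v.size - 1) // 2])


def call_hvrs(profile: CoverageProfile, threshold_fraction: float = 0.2,
              min_length: int = 500, min_median: float = 10.0,
              ) -> list[HVRCall]:
    """Maximal sub-threshold runs: depth < threshold_fraction x median.

    Returns sorted, non-overlapping intervals of length >= ``min_length``.
    When the genome-wide (lower) median depth is below ``min_median`` the
    profile carries too little signal to judge and no calls are made.
    """
    depth = profile.depth
    med = lower_median(depth)
    if med < min_median:
        return []
    below = depth < threshold_fraction * med
    calls: list[HVRCall] = []
    # run-length encode the boolean mask
    edges = np.flatnonzero(np.diff(below.astype(np.int8)))
    starts = np.concatenate(([0], edges + 1))
    ends = np.concatenate((edges + 1, [len(depth)]))
    for s, e in zip(starts, ends):
        if below[s] and e - s >= min_length:
            calls.append(HVRCall(start=int(s), end=int(e),
                                 mean_depth_inside=float(depth[s:e].mean()),
                                 median_depth_genome=med))
    return calls


def detect_dtr(sequence: str, min_dtr: int = 20, max_dtr: int = 1000,
               ) -> DTRCall | None:
    """Largest exact prefix == suffix repeat with length in [min_dtr, max_dtr].

    Exact-match only; a repeat longer than half the genome is not a terminal
    repeat, so the search cap is clamped below that.
    """
    L = len(sequence)
    cap = min(max_dtr, (L - 1) // 2)
    for k in range(cap, min_dtr - 1, -1):
        if sequence[:k] == sequence[-k:]:
            return DTRCall(length=k)
    return None


def terminal_coverage_ratio(profile: CoverageProfile, window: int) -> float:
    """Mean depth over both terminal windows divided by interior mean depth.

    Approaches 2 for a pac-type DTR (both physical copies of the repeat
    recruit to one collapsed assembly copy) and 1 for a plain linear genome.
    NaN when the interior is uncovered.
    """
    L = len(profile)
    if not 0 < window < L / 2:
        raise ValueError(f"window must be in (0, {L / 2}), got {window}")
    depth = profile.depth
    terminal = np.concatenate((depth[:window], depth[-window:]))
    interior = depth[window:L - window]
    if interior.mean() == 0:
        logger.warning("interior coverage is zero; terminal ratio undefined")
        return float("nan")
    return float(terminal.mean() / interior.mean())
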
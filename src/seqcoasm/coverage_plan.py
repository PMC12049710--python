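"""Depth-planning arithmetic for uneven communities.

With relative abundances ``a`` and a per-genome minimum read count ``m``,
the rarest organism pins the required sequencing depth at
``ceil(m / min(a))``; everything sequenced beyond ``n_taxa * m`` is
redundant. This module equates read share with organismal abundance (the
worked-example convention); pass ``genome_lengths`` to plan against the
length-weighted read share that shotgun sequencing actually produces.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = ["DepthPlan", "required_depth", "expected_reads", "excess", "plan"]


def _as_abundances(abundances, genome_lengths=None) -> np.ndarray:
    a = np.asarray(abundances, dtype=float)
    if a.ndim != 1 or a.size == 0:
        raise ValueError("abundances must be a non-empty 1-D sequence")
    if np.any(a < 0):
        raise ValueError("abundances must be non-negative")
    if not math.isclose(float(a.sum()), 1.0, rel_tol=0, abs_tol=1e-6):
        raise ValueError(f"abundances must sum to 1, got {a.sum()}")
    if genome_lengths is not None:
        lens = np.asarray(genome_lengths, dtype=float)
        if lens.shape != a.shape or np.any(lens <= 0):
            raise ValueError("genome_lengths must be positive and match abundances")
        a = a * lens
        a = a / a.sum()
    return a


@dataclass(frozen=True)
class DepthPlan:
    """Depth plan: the minimum depth, its per-organism split, and the excess."""

    required_depth: int
    per_organism: list[tuple[int, int]]  # (taxon index, expected reads)
    excess_reads: int
    redundant_fraction: float


def required_depth(abundances, min_reads_per_genome: int, genome_lengths=None) -> int:
    """Minimum total reads so every organism receives ``min_reads_per_genome``.

    ``ceil(min_reads_per_genome / min(abundances))``; a zero abundance is an
    error (that organism can never reach the minimum).
    """
    if min_reads_per_genome < 1:
        raise ValueError("min_reads_per_genome must be >= 1")
    a = _as_abundances(abundances, genome_lengths)
    if np.any(a == 0):
        raise ValueError("zero abundance: that organism can never reach the minimum")
    return math.ceil(min_reads_per_genome / float(a.min()))


def expected_reads(abundances, depth: int, genome_lengths=None) -> list[int]:
    """Expected per-organism read counts at ``depth``, summing exactly to depth.

    Largest-remainder apportionment: floor the exact shares, then hand the
    leftover reads to the largest fractional remainders (ties resolved in
    favour of the later taxon).
    """
    if depth < 0:
        raise ValueError("depth must be >= 0")
    a = _as_abundances(abundances, genome_lengths)
    exact = a * depth
    counts = np.floor(exact).astype(np.int64)
    rem = exact - counts
    leftover = int(depth - counts.sum())
    if leftover:
        # (remainder desc, index desc); lexsort's last key is primary
        order = np.lexsort((-np.arange(len(a)), -rem))
        counts[order[:leftover]] += 1
    return [int(c) for c in counts]


def excess(abundances, min_reads_per_genome: int, genome_lengths=None) -> tuple[int, float]:
    """Redundant reads implied by the minimum depth: ``(excess, fraction)``.

    ``excess = required_depth - n_taxa * min_reads_per_genome``; the fraction
    is excess over required depth (0 exactly for a uniform community).
    """
    depth = required_depth(abundances, min_reads_per_genome, genome_lengths)
    n = len(np.asarray(abundances))
    excess_reads = depth - n * min_reads_per_genome
    return excess_reads, excess_reads / depth


def plan(abundances, min_reads_per_genome: int, genome_lengths=None) -> DepthPlan:
    """Full depth plan for one community."""
    depth = required_depth(abundances, min_reads_per_genome, genome_lengths)
    per_org = expected_reads(abundances, depth, genome_lengths)
    excess_reads, frac = excess(abundances, min_reads_per_genome, genome_lengths)
    return DepthPlan(
        required_depth=depth,
        per_organism=list(enumerate(per_org)),
        excess_reads=excess_reads,
        redundant_fraction=frac,
    )
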
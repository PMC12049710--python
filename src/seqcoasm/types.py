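"""Core domain containers shared across the pipeline.

Coordinates are 0-based, half-open everywhere. Relative abundances are
organismal fractions (a sample's row sums to 1); read share is the
length-weighted transform of the abundance row.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

_ROW_SUM_TOL = 1e-9


@dataclass(frozen=True)
class ReadPair:
    """One paired-end read: two mates in FR orientation with quality strings."""

    pair_id: str
    mate1: str
    mate2: str
    qual1: str
    qual2: str

    def __post_init__(self):
        if len(self.mate1) != len(self.qual1) or len(self.mate2) != len(self.qual2):
            raise ValueError(f"pair {self.pair_id}: quality/sequence length mismatch")


@dataclass(frozen=True)
class ReadOrigin:
    """Simulation provenance of one pair: origin genome, forward-strand
    fragment start (0-based), and the strand mate1 was sequenced from."""

    genome_id: str
    start: int
    strand: str  # '+' or '-'


@dataclass
class SampleReadSet:
    sample_id: str
    pairs: list[ReadPair]
    truth: list[ReadOrigin] | None = None

    def __post_init__(self):
        if self.truth is not None and len(self.truth) != len(self.pairs):
            raise ValueError(
                f"sample {self.sample_id}: {len(self.truth)} truth records for "
                f"{len(self.pairs)} pairs"
            )

    def __len__(self) -> int:
        return len(self.pairs)

    @property
    def pair_ids(self) -> set[str]:
        return {p.pair_id for p in self.pairs}


class ReferenceSet:
    """Named genome sequences: simulation ground truth and evaluation references."""

    def __init__(self, entries: list[tuple[str, str]]):
        ids = [g for g, _ in entries]
        if len(set(ids)) != len(ids):
            raise ValueError("genome_ids must be unique")
        for gid, seq in entries:
            if not seq or set(seq) - set("ACGT"):
                raise ValueError(f"genome {gid}: sequence must be non-empty and over ACGT")
        self.entries: list[tuple[str, str]] = list(entries)
        self._by_id = dict(entries)

    @property
    def ids(self) -> list[str]:
        return [g for g, _ in self.entries]

    @property
    def lengths(self) -> np.ndarray:
        return np.array([len(s) for _, s in self.entries], dtype=np.int64)

    @property
    def total_length(self) -> int:
        return int(self.lengths.sum())

    def sequence(self, genome_id: str) -> str:
        return self._by_id[genome_id]

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)


@dataclass
class CommunityProfile:
    """Per-sample relative abundances over taxa with presence/absence structure.

    ``abundance`` is (n_samples, n_taxa); every row sums to 1 and
    ``abundance > 0`` exactly where ``presence`` is True.
    """

    taxa: list[str]
    samples: list[str]
    abundance: np.ndarray
    presence: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        self.abundance = np.asarray(self.abundance, dtype=float)
        if self.abundance.shape != (len(self.samples), len(self.taxa)):
            raise ValueError("abundance matrix shape does not match samples x taxa")
        if self.presence is None:
            self.presence = self.abundance > 0
        self.presence = np.asarray(self.presence, dtype=bool)
        self.validate()

    def validate(self) -> None:
        if np.any(self.abundance < 0):
            raise ValueError("abundances must be non-negative")
        sums = self.abundance.sum(axis=1)
        if not np.allclose(sums, 1.0, atol=_ROW_SUM_TOL, rtol=0):
            raise ValueError(f"abundance rows must sum to 1 (got {sums})")
        if not np.array_equal(self.presence, self.abundance > 0):
            raise ValueError("presence must be True exactly where abundance > 0")

    @classmethod
    def from_matrix(cls, samples: list[str], taxa: list[str], matrix) -> "CommunityProfile":
        """Build from an explicit (possibly unnormalised) abundance matrix."""
        m = np.asarray(matrix, dtype=float)
        if m.ndim != 2:
            raise ValueError("explicit abundance matrix must be 2-D")
        if np.any(m < 0):
            raise ValueError("explicit abundances must be non-negative")
        sums = m.sum(axis=1, keepdims=True)
        if np.any(sums <= 0):
            raise ValueError("every sample row must have positive total abundance")
        return cls(taxa=list(taxa), samples=list(samples), abundance=m / sums)

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_samples(self) -> int:
        return len(self.samples)


@dataclass
class Assembly:
    """A set of contigs plus the parameters and inputs that produced them."""

    contigs: list[tuple[str, str]]
    params: dict
    source: list[str] = field(default_factory=list)

    def __post_init__(self):
        ids = [c for c, _ in self.contigs]
        if len(set(ids)) != len(ids):
            raise ValueError("contig_ids must be unique")

    @property
    def n_contigs(self) -> int:
        return len(self.contigs)

    @property
    def lengths(self) -> np.ndarray:
        return np.array([len(s) for _, s in self.contigs], dtype=np.int64)

    @property
    def total_length(self) -> int:
        return int(self.lengths.sum()) if self.contigs else 0

    def __len__(self) -> int:
        return len(self.contigs)

    def __iter__(self):
        return iter(self.contigs)
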
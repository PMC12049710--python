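"""Shared fixtures: tiny deterministic communities and read-set builders."""

from __future__ import annotations

import numpy as np
import pytest

from seqcoasm._codec import revcomp
from seqcoasm.types import ReadPair, SampleReadSet


def make_pairs(fragments: list[str], read_len: int, prefix: str = "p") -> list[ReadPair]:
    """Turn template fragments into FR pairs (mate2 = revcomp of fragment end)."""
    qual = "I" * read_len
    return [
        ReadPair(f"{prefix}{i}", frag[:read_len], revcomp(frag[-read_len:]), qual, qual)
        for i, frag in enumerate(fragments)
    ]


def tiled_readset(
    genome: str,
    sample_id: str = "tiled",
    read_len: int = 100,
    insert: int = 300,
    step: int = 2,
    copies: int = 2,
) -> SampleReadSet:
    """Error-free pairs tiling every ``step``-th fragment start, ``copies`` times.

    Deterministic ~200x coverage including the genome ends, so exact-recovery
    assertions do not hinge on random fragment placement."""
    frags = [
        genome[st : st + insert]
        for st in range(0, len(genome) - insert + 1, step)
        for _ in range(copies)
    ]
    return SampleReadSet(sample_id, make_pairs(frags, read_len, prefix=f"{sample_id}."))


def random_dna(n: int, seed: int) -> str:
    rng = np.random.default_rng(seed)
    return "".join("ACGT"[b] for b in rng.integers(0, 4, n))


@pytest.fixture(scope="session")
def small_community():
    """5 genomes / 4 samples / 2,500 pairs per sample: a fast pipeline workload."""
    import seqcoasm as sq

    refs = sq.generate_genomes(5, (3_000, 6_000), 0.5, seed=7)
    profile = sq.assign_abundances(refs, 4, "lognormal", core_fraction=0.4, seed=7)
    samples = sq.simulate_reads(
        refs, profile, depth=2_500, read_len=100, insert=(300.0, 30.0),
        sub_error_rate=0.002, seed=7,
    )
    return refs, profile, samples
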
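"""Multi-sample metagenome community simulator.

Generates reference genomes, a community profile with log-like ranked
abundances and presence/absence structure (a core of ubiquitous taxa plus
taxa present in only a subset of samples), and paired-end shotgun reads
with full per-pair provenance. Read share is length-weighted by default:
a taxon's chance of contributing a pair is proportional to
``abundance x genome length``, which is what shotgun sequencing of an
organismal abundance profile yields; ``length_weighted=False`` equates
read share with abundance directly.

Determinism: every operation takes a seed; per-sample streams are derived
as ``default_rng([seed, sample_index])`` so adding samples never perturbs
earlier ones.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np

from . import io as _io
from ._codec import decode, encode, revcomp
from .types import CommunityProfile, ReadOrigin, ReadPair, ReferenceSet, SampleReadSet

__all__ = [
    "ReferenceSet",
    "CommunityProfile",
    "SampleReadSet",
    "ReadPair",
    "ReadOrigin",
    "generate_genomes",
    "assign_abundances",
    "simulate_reads",
    "cumulative_abundance_curve",
    "simulate_dataset",
]

_MAX_REGEN = 20


def generate_genomes(
    n_genomes: int,
    length_range: tuple[int, int] = (5_000, 20_000),
    gc: float = 0.5,
    seed: int = 0,
) -> ReferenceSet:
    """Draw i.i.d. random genomes with the requested GC content.

    Lengths are uniform over ``length_range`` (inclusive). No genome is a
    substring of another (offenders are regenerated). Deterministic given
    ``seed``.
    """
    if n_genomes < 1:
        raise ValueError("n_genomes must be >= 1")
    lo, hi = int(length_range[0]), int(length_range[1])
    if lo < 1 or hi < lo:
        raise ValueError(f"invalid length_range {length_range}")
    if not 0.0 < gc < 1.0:
        raise ValueError(f"gc must be in (0, 1), got {gc}")
    rng = np.random.default_rng(seed)
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])  # A C G T
    entries: list[tuple[str, str]] = []

    def draw() -> str:
        length = int(rng.integers(lo, hi + 1))
        return decode(rng.choice(4, size=length, p=probs).astype(np.uint8))

    for i in range(n_genomes):
        seq = draw()
        for _ in range(_MAX_REGEN):
            if not any(seq in other or other in seq for _, other in entries):
                break
            seq = draw()
        else:
            raise RuntimeError("could not generate substring-free genomes")
        entries.append((f"genome_{i:03d}", seq))
    return ReferenceSet(entries)


def assign_abundances(
    refs: ReferenceSet,
    n_samples: int,
    model: str = "lognormal",
    core_fraction: float = 0.25,
    seed: int = 0,
    *,
    sigma: float = 2.0,
    theta: float = 0.7,
    presence_prob: float = 0.3,
    sample_sigma: float = 0.5,
    matrix=None,
    sample_ids: list[str] | None = None,
) -> CommunityProfile:
    """Assign per-sample relative abundances with presence/absence structure.

    ``core_fraction`` of the taxa are present in every sample; each remaining
    taxon is present in a Bernoulli(``presence_prob``)-chosen *strict* subset
    of samples (at least one, never all). Base abundances come from the
    chosen model — ``lognormal`` (exp(N(0, sigma))) or ``log_series``
    (theta^r / r over a random taxon ranking) — and are jittered per sample
    by exp(N(0, sample_sigma)) before renormalisation, so ranked abundances
    fall steeply and the cumulative curve is concave. ``model="explicit"``
    takes ``matrix`` (rows normalised; a non-normalisable row is an error).
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    if not 0.0 <= core_fraction <= 1.0:
        raise ValueError(f"core_fraction must be in [0, 1], got {core_fraction}")
    taxa = refs.ids
    n_taxa = len(taxa)
    if sample_ids is None:
        sample_ids = [f"sample_{i:02d}" for i in range(n_samples)]

    if model == "explicit":
        if matrix is None:
            raise ValueError("model='explicit' requires matrix")
        return CommunityProfile.from_matrix(sample_ids, taxa, matrix)
    if model not in ("lognormal", "log_series"):
        raise ValueError(f"unknown abundance model {model!r}")

    rng = np.random.default_rng(seed)
    if model == "lognormal":
        base = np.exp(rng.normal(0.0, sigma, size=n_taxa))
    else:
        ranks = rng.permutation(n_taxa) + 1
        base = theta**ranks / ranks

    n_core = int(round(core_fraction * n_taxa))
    core = np.zeros(n_taxa, dtype=bool)
    core[rng.choice(n_taxa, size=n_core, replace=False)] = True

    presence = np.zeros((n_samples, n_taxa), dtype=bool)
    presence[:, core] = True
    for j in np.flatnonzero(~core):
        col = rng.random(n_samples) < presence_prob
        if not col.any():
            col[rng.integers(n_samples)] = True
        if col.all() and n_samples > 1:  # non-core taxa occupy a strict subset
            col[rng.integers(n_samples)] = False
        presence[:, j] = col

    abundance = np.zeros((n_samples, n_taxa))
    for i in range(n_samples):
        row = presence[i]
        if not row.any():  # can only happen with core_fraction == 0
            row = presence[i].copy()
            row[rng.integers(n_taxa)] = True
            presence[i] = row
        jitter = np.exp(rng.normal(0.0, sample_sigma, size=int(row.sum())))
        weights = base[row] * jitter
        abundance[i, row] = weights / weights.sum()
    return CommunityProfile(taxa=taxa, samples=sample_ids, abundance=abundance, presence=presence)


def cumulative_abundance_curve(profile: CommunityProfile) -> list[tuple[float, float]]:
    """Cumulative relative abundance (%) vs. fraction of taxa, most-abundant first.

    Taxa are ranked by mean abundance across samples (descending). The curve
    is non-decreasing and ends at 100%.
    """
    mean = profile.abundance.mean(axis=0)
    order = np.argsort(-mean, kind="stable")
    cum = np.cumsum(mean[order])
    cum = 100.0 * cum / cum[-1]
    n = profile.n_taxa
    return [((i + 1) / n, float(cum[i])) for i in range(n)]


def _read_share(profile: CommunityProfile, refs: ReferenceSet, length_weighted: bool) -> np.ndarray:
    w = profile.abundance * (refs.lengths if length_weighted else 1.0)
    return w / w.sum(axis=1, keepdims=True)


def simulate_reads(
    refs: ReferenceSet,
    profile: CommunityProfile,
    depth: int,
    read_len: int = 100,
    insert: tuple[float, float] = (300.0, 30.0),
    sub_error_rate: float = 0.0,
    seed: int = 0,
    *,
    length_weighted: bool = True,
) -> list[SampleReadSet]:
    """Simulate ``depth`` read pairs per sample with full provenance.

    Pair origins are multinomial over taxa with probability proportional to
    ``abundance x genome length`` (or abundance alone when
    ``length_weighted=False``). Fragments are uniform along the origin
    genome, sequenced from a uniformly random strand; mate2 is the reverse
    complement of the fragment end (FR orientation). Substitution errors are
    i.i.d. per base at ``sub_error_rate``; qualities are constant ``'I'``.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    if not 0.0 <= sub_error_rate < 1.0:
        raise ValueError("sub_error_rate must be in [0, 1)")
    ins_mean, ins_sd = float(insert[0]), float(insert[1])
    if ins_mean < 2 * read_len:
        warnings.warn(
            f"insert mean {ins_mean} < 2 x read_len {read_len}: mates will overlap",
            stacklevel=2,
        )
    if profile.taxa != refs.ids:
        raise ValueError("profile taxa do not match reference set")
    short = [g for g, s in refs if len(s) < read_len]
    if short:
        raise ValueError(f"genomes shorter than read_len: {short}")

    share = _read_share(profile, refs, length_weighted)
    glens = refs.lengths
    qual = "I" * read_len
    out: list[SampleReadSet] = []
    for si, sample_id in enumerate(profile.samples):
        rng = np.random.default_rng([seed, si])
        counts = rng.multinomial(depth, share[si])
        mates1: list[str] = []
        mates2: list[str] = []
        truth: list[ReadOrigin] = []
        for ti, (gid, gseq) in enumerate(refs):
            c = int(counts[ti])
            if c == 0:
                continue
            gmax = min(int(glens[ti]), max(read_len, int(ins_mean + 6 * ins_sd)))
            ins = np.clip(np.rint(rng.normal(ins_mean, ins_sd, size=c)), read_len, gmax)
            ins = ins.astype(np.int64)
            starts = rng.integers(0, glens[ti] - ins + 1)
            strands = rng.integers(0, 2, size=c)
            for st, ln, rev in zip(starts, ins, strands):
                frag = gseq[st : st + ln]
                if rev:
                    frag = revcomp(frag)
                mates1.append(frag[:read_len])
                mates2.append(revcomp(frag[-read_len:]))
                truth.append(ReadOrigin(gid, int(st), "-" if rev else "+"))
        if sub_error_rate > 0.0 and mates1:
            mates1 = _mutate(mates1, read_len, sub_error_rate, rng)
            mates2 = _mutate(mates2, read_len, sub_error_rate, rng)
        pairs = [
            ReadPair(f"{sample_id}.{i}", m1, m2, qual, qual)
            for i, (m1, m2) in enumerate(zip(mates1, mates2))
        ]
        out.append(SampleReadSet(sample_id=sample_id, pairs=pairs, truth=truth))
    return out


def _mutate(mates: list[str], read_len: int, rate: float, rng: np.random.Generator) -> list[str]:
    flat = encode("".join(mates)).reshape(len(mates), read_len)
    hit = np.flatnonzero(rng.random(flat.size) < rate)
    if hit.size:
        shift = rng.integers(1, 4, size=hit.size).astype(np.uint8)
        flat.reshape(-1)[hit] = (flat.reshape(-1)[hit] + shift) % 4
    return [decode(row) for row in flat]


def simulate_dataset(
    out_dir: str | Path,
    n_genomes: int = 20,
    n_samples: int = 10,
    depth: int = 20_000,
    read_len: int = 100,
    insert: tuple[float, float] = (300.0, 30.0),
    sub_error_rate: float = 0.002,
    model: str = "lognormal",
    core_fraction: float = 0.25,
    length_range: tuple[int, int] = (5_000, 20_000),
    gc: float = 0.5,
    seed: int = 0,
    length_weighted: bool = True,
) -> tuple[ReferenceSet, CommunityProfile, list[SampleReadSet]]:
    """Generate a full dataset and write refs.fa, profile.tsv, per-sample
    FASTQ pairs and truth.tsv.gz under ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    refs = generate_genomes(n_genomes, length_range, gc, seed)
    profile = assign_abundances(refs, n_samples, model, core_fraction, seed)
    samples = simulate_reads(
        refs, profile, depth, read_len, insert, sub_error_rate, seed,
        length_weighted=length_weighted,
    )
    _io.write_reference_set(refs, out / "refs.fa")
    _io.write_profile(profile, out / "profile.tsv")
    for reads in samples:
        _io.write_fastq_pair(
            reads, out / f"{reads.sample_id}_R1.fq.gz", out / f"{reads.sample_id}_R2.fq.gz"
        )
        _io.write_truth(reads, out / f"{reads.sample_id}_truth.tsv.gz")
    return refs, profile, samples
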
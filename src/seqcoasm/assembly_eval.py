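"""Reference-based and reference-free assembly evaluation.

The reference-based half mirrors the MetaQUAST metric family at desk
scale: contigs are aligned to the references as exact-31-mer-anchored
ungapped blocks, and from the blocks come genome fraction (percent of
reference bases covered at least once), duplication ratio (aligned contig
bases over covered reference bases), mismatch rate per 100 kbp, and
misassembly counts (adjacent blocks of one contig that switch reference
or strand, or whose diagonals disagree by >= 1000 bp, are extensive
misassemblies; disagreements of 50-999 bp are local). The reference-free
half is the overall-read-alignment evaluation: map every sample's reads
back to the assembly and report the per-sample alignment percentages,
whose mean tracks the cumulative read-share of the taxa the assembly
covers.

Ungapped blocks are adequate here because the bundled simulator emits
substitution-only divergence; the thresholds are config-exposed stand-ins
for QUAST's conventions, not a parity claim.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from ._codec import canonical_codes, encode
from .kmer_mapper import MapParams, build_index, partition_sample
from .types import Assembly, ReferenceSet, SampleReadSet

__all__ = [
    "EvalParams",
    "Block",
    "ContigRefAlignment",
    "EvalReport",
    "align_contigs",
    "genome_fraction",
    "duplication_ratio",
    "count_misassemblies",
    "mismatches_per_100kbp",
    "contiguity_stats",
    "read_alignment_eval",
    "evaluate",
    "fit_alignment_vs_log_genome_fraction",
]


@dataclass(frozen=True)
class EvalParams:
    anchor_k: int = 31
    min_block: int = 65  # blocks shorter than this are dropped
    max_anchor_gap: int = 200  # split a diagonal run at larger anchor gaps
    misassembly_bp: int = 1000  # inconsistency >= this is extensive
    local_bp: int = 50  # inconsistency in [local_bp, misassembly_bp) is local
    max_block_overlap: int = 15  # tolerated contig overlap between kept blocks


@dataclass(frozen=True)
class Block:
    """One ungapped contig-to-reference alignment block (0-based half-open)."""

    contig_start: int
    contig_end: int
    ref_id: str
    ref_start: int
    ref_end: int
    strand: str  # '+' or '-'
    mismatches: int

    @property
    def length(self) -> int:
        return self.contig_end - self.contig_start


@dataclass
class ContigRefAlignment:
    contig_id: str
    contig_len: int
    blocks: list[Block]  # ordered by contig_start, non-overlapping (up to tolerance)

    @property
    def unaligned_len(self) -> int:
        return self.contig_len - sum(b.length for b in self.blocks)


@dataclass
class EvalReport:
    """The per-assembly metric bundle used for strategy comparison."""

    aligned_length: int = 0
    genome_fraction: float = 0.0
    duplication_ratio: float | None = None
    misassemblies: int = 0
    local_misassemblies: int = 0
    misassembled_contig_length: int = 0
    mismatches_per_100kbp: float | None = None
    auN: float = 0.0
    N50: int = 0
    total_len_ge_50kbp: int = 0
    total_length: int = 0
    n_contigs: int = 0
    overall_read_alignment: list[float] = field(default_factory=list)

    @property
    def mean_read_alignment(self) -> float:
        return float(np.mean(self.overall_read_alignment)) if self.overall_read_alignment else 0.0


class _RefIndex:
    def __init__(self, refs: ReferenceSet, k: int):
        self.k = k
        self.ids = refs.ids
        self.seqs = [encode(s) for _, s in refs]
        self.lookup: dict[int, list[tuple[int, int, bool]]] = {}
        for ri, arr in enumerate(self.seqs):
            canon, fwd, _ = canonical_codes(arr, k)
            for off, (code, f) in enumerate(zip(canon.tolist(), fwd.tolist())):
                self.lookup.setdefault(code, []).append((ri, off, f))


def _extend_and_count(carr, rarr, c0, c1, r0, r1, strand):
    """Extend block ends while bases match exactly; return new bounds + mismatches."""
    if strand == "+":
        while c0 > 0 and r0 > 0 and carr[c0 - 1] == rarr[r0 - 1]:
            c0 -= 1
            r0 -= 1
        n, rn = carr.size, rarr.size
        while c1 < n and r1 < rn and carr[c1] == rarr[r1]:
            c1 += 1
            r1 += 1
        mism = int(np.count_nonzero(carr[c0:c1] != rarr[r0:r1]))
    else:
        # contig [c0,c1) aligns to revcomp of ref [r0,r1): contig left ~ ref right
        rn = rarr.size
        while c0 > 0 and r1 < rn and carr[c0 - 1] == 3 - rarr[r1]:
            c0 -= 1
            r1 += 1
        n = carr.size
        while c1 < n and r0 > 0 and carr[c1] == 3 - rarr[r0 - 1]:
            c1 += 1
            r0 -= 1
        rc = (3 - rarr[r0:r1][::-1]).astype(np.uint8)
        mism = int(np.count_nonzero(carr[c0:c1] != rc))
    return c0, c1, r0, r1, mism


def _candidate_blocks(carr: np.ndarray, refidx: _RefIndex, params: EvalParams) -> list[Block]:
    k = params.anchor_k
    canon, fwd, _ = canonical_codes(carr, k)
    groups: dict[tuple[int, bool, int], list[int]] = {}
    for cpos, (code, cf) in enumerate(zip(canon.tolist(), fwd.tolist())):
        hits = refidx.lookup.get(code)
        if not hits:
            continue
        for ri, off, rf in hits:
            if cf == rf:  # same orientation: diagonal = off - cpos
                groups.setdefault((ri, True, off - cpos), []).append(cpos)
            else:  # opposite: anti-diagonal = off + cpos
                groups.setdefault((ri, False, off + cpos), []).append(cpos)
    blocks: list[Block] = []
    for (ri, same, diag), cposs in groups.items():
        cposs.sort()
        runs: list[tuple[int, int]] = []
        start = prev = cposs[0]
        for cp in cposs[1:]:
            if cp - prev > params.max_anchor_gap:
                runs.append((start, prev))
                start = cp
            prev = cp
        runs.append((start, prev))
        rarr = refidx.seqs[ri]
        for c0, clast in runs:
            c1 = clast + k
            if same:
                r0, r1 = c0 + diag, c1 + diag
            else:
                r0, r1 = diag - clast, diag - c0 + k
            c0, c1, r0, r1, mism = _extend_and_count(
                carr, rarr, c0, c1, r0, r1, "+" if same else "-"
            )
            if c1 - c0 >= params.min_block:
                blocks.append(Block(c0, c1, refidx.ids[ri], r0, r1,
                                    "+" if same else "-", mism))
    return blocks


def _select_blocks(blocks: list[Block], params: EvalParams) -> list[Block]:
    """Greedy non-overlapping selection on the contig, longest first."""
    blocks = sorted(blocks, key=lambda b: (-b.length, b.ref_id, b.ref_start, b.strand))
    kept: list[Block] = []
    for b in blocks:
        overlap = sum(
            max(0, min(b.contig_end, o.contig_end) - max(b.contig_start, o.contig_start))
            for o in kept
        )
        if overlap <= params.max_block_overlap:
            kept.append(b)
    kept.sort(key=lambda b: b.contig_start)
    return kept


def align_contigs(
    assembly: Assembly, refs: ReferenceSet, params: EvalParams = EvalParams()
) -> list[ContigRefAlignment]:
    """Anchor-and-extend each contig against all references and strands."""
    if len(refs) == 0:
        raise ValueError("empty reference set")
    refidx = _RefIndex(refs, params.anchor_k)
    out: list[ContigRefAlignment] = []
    for cid, seq in assembly:
        carr = encode(seq)
        if carr.size < params.anchor_k:
            out.append(ContigRefAlignment(cid, len(seq), []))
            continue
        cand = _candidate_blocks(carr, refidx, params)
        out.append(ContigRefAlignment(cid, len(seq), _select_blocks(cand, params)))
    return out


def _covered_ref_bases(alignments: list[ContigRefAlignment]) -> dict[str, int]:
    intervals: dict[str, list[tuple[int, int]]] = {}
    for aln in alignments:
        for b in aln.blocks:
            intervals.setdefault(b.ref_id, []).append((b.ref_start, b.ref_end))
    covered: dict[str, int] = {}
    for rid, ivs in intervals.items():
        ivs.sort()
        total, cur_s, cur_e = 0, ivs[0][0], ivs[0][1]
        for s, e in ivs[1:]:
            if s > cur_e:
                total += cur_e - cur_s
                cur_s, cur_e = s, e
            else:
                cur_e = max(cur_e, e)
        covered[rid] = total + cur_e - cur_s
    return covered


def genome_fraction(alignments: list[ContigRefAlignment], refs: ReferenceSet) -> float:
    """Percent of reference bases covered by at least one block (union)."""
    covered = _covered_ref_bases(alignments)
    return 100.0 * sum(covered.values()) / refs.total_length


def duplication_ratio(alignments: list[ContigRefAlignment], refs: ReferenceSet) -> float | None:
    """Aligned contig bases over covered reference bases; None if nothing aligns."""
    covered = sum(_covered_ref_bases(alignments).values())
    if covered == 0:
        return None
    aligned = sum(b.length for aln in alignments for b in aln.blocks)
    return aligned / covered


def count_misassemblies(
    alignments: list[ContigRefAlignment], params: EvalParams = EvalParams()
) -> tuple[int, int, int]:
    """(extensive, local, misassembled contig length) over adjacent block pairs.

    A reference or strand switch, or a diagonal inconsistency >=
    ``misassembly_bp``, is extensive; an inconsistency in
    [``local_bp``, ``misassembly_bp``) is local. A contig with >= 1
    extensive event contributes its full length once.
    """
    extensive = local = mis_len = 0
    for aln in alignments:
        contig_extensive = False
        for a, b in zip(aln.blocks, aln.blocks[1:]):
            if a.ref_id != b.ref_id or a.strand != b.strand:
                extensive += 1
                contig_extensive = True
                continue
            if a.strand == "+":
                inconsistency = abs(
                    (b.ref_start - b.contig_start) - (a.ref_start - a.contig_start)
                )
            else:
                inconsistency = abs(
                    (b.ref_end + b.contig_start) - (a.ref_end + a.contig_start)
                )
            if inconsistency >= params.misassembly_bp:
                extensive += 1
                contig_extensive = True
            elif inconsistency >= params.local_bp:
                local += 1
        if contig_extensive:
            mis_len += aln.contig_len
    return extensive, local, mis_len


def mismatches_per_100kbp(alignments: list[ContigRefAlignment]) -> float | None:
    """1e5 x block mismatches per aligned contig base; None if nothing aligns."""
    aligned = sum(b.length for aln in alignments for b in aln.blocks)
    if aligned == 0:
        return None
    mism = sum(b.mismatches for aln in alignments for b in aln.blocks)
    return 1e5 * mism / aligned


def contiguity_stats(assembly: Assembly) -> tuple[float, int, int, int]:
    """(auN, N50, total length of contigs >= 50 kbp, total length)."""
    if assembly.n_contigs == 0:
        warnings.warn("contiguity stats of an empty assembly are zero", stacklevel=2)
        return 0.0, 0, 0, 0
    lengths = np.sort(assembly.lengths)[::-1]
    total = int(lengths.sum())
    aun = float((lengths.astype(float) ** 2).sum() / total)
    cum = np.cumsum(lengths)
    n50 = int(lengths[np.searchsorted(cum, total / 2)])
    ge50k = int(lengths[lengths >= 50_000].sum())
    return aun, n50, ge50k, total


def read_alignment_eval(
    samples: list[SampleReadSet],
    assembly: Assembly,
    params: MapParams = MapParams(),
) -> dict:
    """Per-sample overall read alignment (%) against an assembly.

    An empty assembly trivially aligns nothing (all zeros)."""
    if assembly.n_contigs == 0:
        values = [0.0] * len(samples)
    else:
        index = build_index(assembly, params.k_index)
        values = [
            partition_sample(s, index, params).overall_read_alignment for s in samples
        ]
    return {
        "per_sample": values,
        "mean": float(np.mean(values)) if values else 0.0,
        "sd": float(np.std(values, ddof=1)) if len(values) > 1 else 0.0,
    }


def fit_alignment_vs_log_genome_fraction(
    genome_fractions: list[float], mean_alignments: list[float]
):
    """Linear model mean overall read alignment ~ log(genome fraction);
    returns the scipy linregress result (slope, intercept, rvalue, ...)."""
    x = np.log(np.asarray(genome_fractions, dtype=float))
    return stats.linregress(x, np.asarray(mean_alignments, dtype=float))


def evaluate(
    assembly: Assembly,
    refs: ReferenceSet | None = None,
    samples: list[SampleReadSet] | None = None,
    eval_params: EvalParams = EvalParams(),
    map_params: MapParams = MapParams(),
) -> EvalReport:
    """Full metric bundle: reference-based if ``refs`` given, read-alignment
    if ``samples`` given."""
    report = EvalReport(n_contigs=assembly.n_contigs)
    if assembly.n_contigs:
        report.auN, report.N50, report.total_len_ge_50kbp, report.total_length = (
            contiguity_stats(assembly)
        )
    if refs is not None and assembly.n_contigs:
        alignments = align_contigs(assembly, refs, eval_params)
        report.aligned_length = sum(b.length for a in alignments for b in a.blocks)
        report.genome_fraction = genome_fraction(alignments, refs)
        report.duplication_ratio = duplication_ratio(alignments, refs)
        (report.misassemblies, report.local_misassemblies,
         report.misassembled_contig_length) = count_misassemblies(alignments, eval_params)
        report.mismatches_per_100kbp = mismatches_per_100kbp(alignments)
    if samples is not None:
        report.overall_read_alignment = read_alignment_eval(
            samples, assembly, map_params
        )["per_sample"]
    return report
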
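"""Single-k de Bruijn graph unitig assembler.

The bundled reference assembler behind every co-assembly step: count
canonical k-mers over both mates of all pairs, drop k-mers rarer than
``min_count`` (which removes most singleton error k-mers), clip
low-coverage tips and weak short side paths (the error k-mers that
survive the count filter at high coverage), and emit the maximal
non-branching paths (unitigs) of the remaining graph as contigs.
Remaining branches terminate unitigs, which keeps the output checkable
against a brute-force k-mer inventory. Output is fully deterministic:
each unitig is emitted in its lexicographically smaller orientation and
contigs are sorted by (length desc, sequence asc).

Adjacency is implicit: two nodes are linked when their (k-1)-overlap
extension is present in the filtered node set, queried in both
orientations of the bidirected graph.
"""

from __future__ import annotations

import subprocess
import tempfile
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from ._codec import (
    canonical_codes,
    check_k,
    code_to_str,
    concat_with_sentinels,
    rc_code,
    revcomp,
)
from .types import Assembly, SampleReadSet

__all__ = ["KmerGraph", "Assembly", "build_graph", "assemble", "megahit_assemble"]

DEFAULT_K = 31
DEFAULT_MIN_COUNT = 2
DEFAULT_MIN_CONTIG_LEN = 200


@dataclass
class KmerGraph:
    """Filtered canonical k-mer multiset; every stored code is canonical."""

    k: int
    counts: dict[int, int]
    n_reads: int = 0
    n_short_skipped: int = 0

    def __len__(self) -> int:
        return len(self.counts)

    def __contains__(self, code: int) -> bool:
        return code in self.counts

    def count(self, kmer_code: int) -> int:
        return self.counts.get(kmer_code, 0)


def _all_sequences(readsets) -> list[str]:
    seqs: list[str] = []
    for rs in readsets:
        if isinstance(rs, str):  # bare sequences are handy for small fixtures
            seqs.append(rs)
            continue
        for p in rs.pairs:
            seqs.append(p.mate1)
            seqs.append(p.mate2)
    return seqs


def build_graph(
    readsets: list[SampleReadSet] | list[str],
    k: int = DEFAULT_K,
    min_count: int = DEFAULT_MIN_COUNT,
) -> KmerGraph:
    """Count canonical k-mers of all mates and filter by ``min_count``.

    ``readsets`` may also be bare sequences (unpaired reads). Reads shorter
    than k are skipped and counted. Empty effective input is an error
    naming the cause.
    """
    check_k(k)
    if min_count < 1:
        raise ValueError("min_count must be >= 1")
    seqs = _all_sequences(readsets)
    if not seqs:
        raise ValueError("no reads supplied to build_graph")
    usable = [s for s in seqs if len(s) >= k]
    n_short = len(seqs) - len(usable)
    if not usable:
        raise ValueError(f"all {n_short} reads are shorter than k={k}")
    big, _ = concat_with_sentinels(usable)
    canon, _, valid = canonical_codes(big, k)
    codes, counts = np.unique(canon[valid], return_counts=True)
    keep = counts >= min_count
    graph_counts = dict(zip(codes[keep].tolist(), counts[keep].tolist()))
    return KmerGraph(k=k, counts=graph_counts, n_reads=len(seqs), n_short_skipped=n_short)


class _Walker:
    """Bidirected-graph helpers over a canonical node set."""

    def __init__(self, counts: dict[int, int], k: int):
        self.counts = counts
        self.k = k
        self.mask = (1 << (2 * k)) - 1
        self.shift = 2 * (k - 1)

    def canon(self, code: int) -> int:
        r = rc_code(code, self.k)
        return code if code <= r else r

    def fwd_exts(self, code: int) -> list[int]:
        base = (code << 2) & self.mask
        return [base | b for b in range(4) if self.canon(base | b) in self.counts]

    def bwd_exts(self, code: int) -> list[int]:
        base = code >> 2
        return [
            (b << self.shift) | base
            for b in range(4)
            if self.canon((b << self.shift) | base) in self.counts
        ]

    def paths(self) -> list[list[int]]:
        """Maximal non-branching paths as oriented code lists; each canonical
        node appears in exactly one path."""
        visited: set[int] = set()
        out: list[list[int]] = []
        for start in sorted(self.counts):
            if start in visited:
                continue
            path = [start]
            in_path = {start}
            cur = start
            while True:  # extend right
                nxt = self.fwd_exts(cur)
                if len(nxt) != 1:
                    break
                v = nxt[0]
                if len(self.bwd_exts(v)) != 1:
                    break
                cv = self.canon(v)
                if cv in visited or cv in in_path:
                    break
                path.append(v)
                in_path.add(cv)
                cur = v
            cur = start
            back: list[int] = []
            while True:  # extend left
                prv = self.bwd_exts(cur)
                if len(prv) != 1:
                    break
                v = prv[0]
                if len(self.fwd_exts(v)) != 1:
                    break
                cv = self.canon(v)
                if cv in visited or cv in in_path:
                    break
                back.append(v)
                in_path.add(cv)
                cur = v
            path = back[::-1] + path
            visited.update(self.canon(c) for c in path)
            out.append(path)
        return out

    def spell(self, path: list[int]) -> str:
        chars = [code_to_str(path[0], self.k)]
        chars.extend("ACGT"[c & 3] for c in path[1:])
        return "".join(chars)


def _clean_graph(graph: KmerGraph, ratio: float, rounds: int) -> KmerGraph:
    """Remove low-coverage tips and weak short side paths.

    A path of at most k nodes that hangs off the rest of the graph (tip:
    one attached end) or bridges it (weak bubble limb: both ends attached)
    is removed when its mean k-mer count is below ``ratio`` times the count
    of its strongest junction neighbour. Sequencing-error k-mers that
    survive the ``min_count`` filter sit exactly in this regime (count
    close to min_count against a true path at the local coverage), while
    uniformly covered paths have ratio ~1 and are never touched, so
    error-free inputs pass through unchanged. Isolated paths (no attached
    end) are always kept.
    """
    counts = graph.counts
    k = graph.k
    for _ in range(rounds):
        walker = _Walker(counts, k)
        doomed: set[int] = set()
        for path in walker.paths():
            if len(path) > k:
                continue
            ends = []  # neighbour counts at each attached end
            first, last = path[0], path[-1]
            in_path = {walker.canon(c) for c in path}
            left = [c for c in walker.bwd_exts(first) if walker.canon(c) not in in_path]
            right = [c for c in walker.fwd_exts(last) if walker.canon(c) not in in_path]
            if left:
                ends.append(max(counts[walker.canon(c)] for c in left))
            if right:
                ends.append(max(counts[walker.canon(c)] for c in right))
            if not ends:
                continue  # isolated component
            mean_count = sum(counts[walker.canon(c)] for c in path) / len(path)
            if mean_count < ratio * max(ends):
                doomed.update(walker.canon(c) for c in path)
        if not doomed:
            break
        counts = {c: n for c, n in counts.items() if c not in doomed}
    return KmerGraph(k=k, counts=counts, n_reads=graph.n_reads,
                     n_short_skipped=graph.n_short_skipped)


def _unitigs(graph: KmerGraph) -> list[str]:
    """Maximal non-branching paths of the bidirected graph, one per k-mer set."""
    walker = _Walker(graph.counts, graph.k)
    return [walker.spell(p) for p in walker.paths()]


def assemble(
    readsets: list[SampleReadSet] | list[str],
    k: int = DEFAULT_K,
    min_count: int = DEFAULT_MIN_COUNT,
    min_contig_len: int = DEFAULT_MIN_CONTIG_LEN,
    clean_ratio: float = 0.25,
    clean_rounds: int = 3,
) -> Assembly:
    """Assemble reads into unitig contigs.

    After ``min_count`` filtering, low-coverage tips and weak short side
    paths are removed for up to ``clean_rounds`` rounds (``clean_ratio=0``
    disables cleaning; see ``_clean_graph``). Contigs shorter than
    ``min_contig_len`` are dropped; the survivors are oriented and ordered
    deterministically and named ``contig_NNNNNN``.
    """
    graph = build_graph(readsets, k=k, min_count=min_count)
    if clean_ratio > 0:
        graph = _clean_graph(graph, clean_ratio, clean_rounds)
    raw = _unitigs(graph)
    oriented = [min(s, revcomp(s)) for s in raw if len(s) >= min_contig_len]
    oriented.sort(key=lambda s: (-len(s), s))
    contigs = [(f"contig_{i:06d}", s) for i, s in enumerate(oriented)]
    return Assembly(
        contigs=contigs,
        params={"k": k, "min_count": min_count, "min_contig_len": min_contig_len,
                "clean_ratio": clean_ratio, "clean_rounds": clean_rounds,
                "backend": "internal"},
        source=[rs.sample_id for rs in readsets if not isinstance(rs, str)],
    )


def megahit_assemble(
    readsets: list[SampleReadSet],
    min_contig_len: int = DEFAULT_MIN_CONTIG_LEN,
    megahit_bin: str = "megahit",
    threads: int = 1,
) -> Assembly:
    """External-assembler adapter satisfying the same backend contract.

    Shells out to MEGAHIT over temporary FASTQ files and reads back the
    contig FASTA. Requires the binary on PATH; not exercised by unit tests.
    """
    from . import io as _io

    with tempfile.TemporaryDirectory() as tmp:
        tmp_path = Path(tmp)
        r1s, r2s = [], []
        for rs in readsets:
            r1 = tmp_path / f"{rs.sample_id}_R1.fq.gz"
            r2 = tmp_path / f"{rs.sample_id}_R2.fq.gz"
            _io.write_fastq_pair(rs, r1, r2)
            r1s.append(str(r1))
            r2s.append(str(r2))
        out = tmp_path / "megahit_out"
        cmd = [
            megahit_bin, "-1", ",".join(r1s), "-2", ",".join(r2s),
            "--min-contig-len", str(min_contig_len), "--mem-flag", "1",
            "-t", str(threads), "-o", str(out),
        ]
        subprocess.run(cmd, check=True, capture_output=True)
        contigs = _io.read_fasta(out / "final.contigs.fa")
    return Assembly(
        contigs=contigs,
        params={"min_contig_len": min_contig_len, "backend": "megahit"},
        source=[rs.sample_id for rs in readsets],
    )
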
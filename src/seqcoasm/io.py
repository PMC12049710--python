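"""Readers and writers for the on-disk formats the pipeline exchanges.

FASTQ is read with pysam (handles gzip transparently) and written as plain
4-line records through a gzip stream with ``mtime=0`` and no embedded file
name, so identical read sets produce byte-identical ``.gz`` files — the
determinism contract the pipeline's resumability and tests rely on. FASTA
goes through Biopython.
"""

from __future__ import annotations

import gzip
from pathlib import Path
from typing import Iterable

import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqIO.FastaIO import FastaWriter
from Bio.SeqRecord import SeqRecord

from .types import ReadOrigin, ReadPair, ReferenceSet, SampleReadSet

FASTA_WRAP = 80


def _open_out(path: str | Path, compress: bool):
    raw = open(path, "wb")
    if compress:
        return gzip.GzipFile(fileobj=raw, mode="wb", mtime=0, filename="")
    return raw


def _is_gz(path: str | Path) -> bool:
    return str(path).endswith(".gz")


def write_fasta(entries: Iterable[tuple[str, str]], path: str | Path) -> None:
    """Write (id, sequence) pairs as FASTA, 80-column wrapped."""
    records = (SeqRecord(Seq(seq), id=name, description="") for name, seq in entries)
    with open(path, "w") as handle:
        FastaWriter(handle, wrap=FASTA_WRAP).write_file(records)


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]


def write_reference_set(refs: ReferenceSet, path: str | Path) -> None:
    write_fasta(refs.entries, path)


def read_reference_set(path: str | Path) -> ReferenceSet:
    return ReferenceSet(read_fasta(path))


def write_fastq_pair(reads: SampleReadSet, r1_path: str | Path, r2_path: str | Path) -> None:
    """Write a sample's pairs as `<sample>_R1/_R2` FASTQ (gzip if path ends .gz)."""
    for path, mate in ((r1_path, 1), (r2_path, 2)):
        with _open_out(path, _is_gz(path)) as fh:
            chunks = []
            for pair in reads.pairs:
                seq = pair.mate1 if mate == 1 else pair.mate2
                qual = pair.qual1 if mate == 1 else pair.qual2
                chunks.append(f"@{pair.pair_id}/{mate}\n{seq}\n+\n{qual}\n")
            fh.write("".join(chunks).encode("ascii"))


def read_fastq_pair(r1_path: str | Path, r2_path: str | Path, sample_id: str | None = None) -> SampleReadSet:
    """Load an R1/R2 FASTQ pair (optionally gzipped) as a SampleReadSet."""
    if sample_id is None:
        sample_id = Path(r1_path).name.split("_R1")[0].split(".")[0]
    pairs = []
    with pysam.FastxFile(str(r1_path)) as f1, pysam.FastxFile(str(r2_path)) as f2:
        for e1, e2 in zip(f1, f2):
            pid1 = e1.name[:-2] if e1.name.endswith("/1") else e1.name
            pid2 = e2.name[:-2] if e2.name.endswith("/2") else e2.name
            if pid1 != pid2:
                raise ValueError(f"mate identifiers disagree: {e1.name!r} vs {e2.name!r}")
            pairs.append(
                ReadPair(
                    pair_id=pid1,
                    mate1=e1.sequence.upper(),
                    mate2=e2.sequence.upper(),
                    qual1=e1.quality or "I" * len(e1.sequence),
                    qual2=e2.quality or "I" * len(e2.sequence),
                )
            )
    return SampleReadSet(sample_id=sample_id, pairs=pairs)


def write_profile(profile, path: str | Path) -> None:
    """Sample x taxon relative-abundance matrix as TSV."""
    df = pd.DataFrame(profile.abundance, index=profile.samples, columns=profile.taxa)
    df.index.name = "sample"
    df.to_csv(path, sep="\t", float_format="%.10g")


def read_profile(path: str | Path):
    from .community_sim import CommunityProfile

    df = pd.read_csv(path, sep="\t", index_col=0)
    return CommunityProfile.from_matrix(list(df.index), list(df.columns), df.to_numpy())


def write_truth(reads: SampleReadSet, path: str | Path) -> None:
    """Per-pair simulation provenance: pair_id, genome_id, 0-based start, strand."""
    if reads.truth is None:
        raise ValueError(f"sample {reads.sample_id} carries no truth records")
    with _open_out(path, _is_gz(path)) as fh:
        lines = ["pair_id\tgenome_id\tstart\tstrand\n"]
        for pair, org in zip(reads.pairs, reads.truth):
            lines.append(f"{pair.pair_id}\t{org.genome_id}\t{org.start}\t{org.strand}\n")
        fh.write("".join(lines).encode("ascii"))


def read_truth(path: str | Path) -> list[ReadOrigin]:
    df = pd.read_csv(path, sep="\t")
    return [ReadOrigin(g, int(s), st) for g, s, st in zip(df.genome_id, df.start, df.strand)]
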
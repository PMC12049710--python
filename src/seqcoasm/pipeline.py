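"""Orchestration of traditional and sequential co-assembly.

Sequential mode runs the three-step procedure: (1) co-assemble a user-named
subset of samples; (2) map every sample — subset samples included — against
that assembly and keep each sample's unaligned pool (pairs that failed
concordant placement); (3) co-assemble the subset samples' full raw reads
together with the unaligned pools of the non-subset samples. Subset pools
are excluded from the step-3 union so no pair enters twice; the raw subset
reads already cover them. Traditional mode is one assembler call over the
concatenation of all samples.

Every stage is timed; the report carries per-sample pool sizes, the step-3
input reduction ratio, and both series (summed) and parallel (max)
accounting of the mapping stage.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import io as _io
from .assembly_eval import EvalParams, EvalReport, evaluate
from .dbg_assembler import (
    DEFAULT_K,
    DEFAULT_MIN_CONTIG_LEN,
    DEFAULT_MIN_COUNT,
    assemble,
)
from .kmer_mapper import MapParams, build_index, partition_sample
from .types import Assembly, ReferenceSet, SampleReadSet

__all__ = [
    "PipelineConfig",
    "RunReport",
    "run_traditional",
    "run_sequential",
    "compare_strategies",
    "rank_subsets",
    "load_config",
]

log = logging.getLogger("seqcoasm.pipeline")


@dataclass
class PipelineConfig:
    """Inputs and parameters for one co-assembly run.

    Provide either in-memory ``samples`` or a ``manifest`` of
    sample_id -> (R1 path, R2 path); ``subset`` names the samples seeding
    step 1 in sequential mode.
    """

    samples: list[SampleReadSet] | None = None
    manifest: dict[str, tuple[str, str]] | None = None
    subset: list[str] = field(default_factory=list)
    mode: str = "sequential"
    k: int = DEFAULT_K
    min_count: int = DEFAULT_MIN_COUNT
    min_contig_len: int = DEFAULT_MIN_CONTIG_LEN
    mapper: MapParams = field(default_factory=MapParams)
    subtract_discordant: bool = False
    workers: int = 1
    seed: int = 0
    out_dir: str | Path | None = None

    def load_samples(self) -> list[SampleReadSet]:
        if self.samples is not None:
            return self.samples
        if not self.manifest:
            raise ValueError("config names no samples (empty manifest)")
        loaded = []
        for sid, (r1, r2) in self.manifest.items():
            try:
                loaded.append(_io.read_fastq_pair(r1, r2, sample_id=sid))
            except (OSError, ValueError) as exc:
                raise RuntimeError(f"cannot read FASTQ for sample {sid!r}: {exc}") from exc
        self.samples = loaded
        return loaded


@dataclass
class RunReport:
    mode: str
    stage_times: dict[str, float] = field(default_factory=dict)
    map_times: dict[str, float] = field(default_factory=dict)  # per-sample step 2
    input_pairs: dict[str, int] = field(default_factory=dict)  # per stage
    pool_sizes: dict[str, int] = field(default_factory=dict)
    status_counts: dict[str, dict[str, int]] = field(default_factory=dict)
    total_pairs: int = 0
    step3_input_pairs: int = 0
    step3_pair_ids: set[str] | None = None  # exact union fed to step 3
    final_assembly_path: str | None = None

    @property
    def step3_input_fraction(self) -> float:
        return self.step3_input_pairs / self.total_pairs if self.total_pairs else 0.0

    @property
    def series_map_time(self) -> float:
        return sum(self.map_times.values())

    @property
    def parallel_map_time(self) -> float:
        return max(self.map_times.values()) if self.map_times else 0.0


def _config_fingerprint(config: PipelineConfig, samples: list[SampleReadSet]) -> str:
    payload = json.dumps(
        {
            "samples": [(s.sample_id, len(s)) for s in samples],
            "subset": list(config.subset),
            "mode": config.mode,
            "k": config.k,
            "min_count": config.min_count,
            "min_contig_len": config.min_contig_len,
            "mapper": vars(config.mapper) if hasattr(config.mapper, "__dict__") else str(config.mapper),
            "subtract_discordant": config.subtract_discordant,
        },
        sort_keys=True,
        default=str,
    )
    return hashlib.sha256(payload.encode()).hexdigest()


def _stage_dir(config: PipelineConfig, name: str) -> Path | None:
    if config.out_dir is None:
        return None
    d = Path(config.out_dir) / name
    d.mkdir(parents=True, exist_ok=True)
    return d


def _stage_done(stage: Path | None, fingerprint: str) -> bool:
    return (
        stage is not None
        and (stage / "DONE").exists()
        and (stage / "DONE").read_text().strip() == fingerprint
    )


def _mark_done(stage: Path | None, fingerprint: str) -> None:
    if stage is not None:
        (stage / "DONE").write_text(fingerprint + "\n")


def _write_assembly(stage: Path | None, assembly: Assembly) -> str | None:
    if stage is None:
        return None
    path = stage / "contigs.fa"
    _io.write_fasta(assembly.contigs, path)
    pd.DataFrame(
        [(cid, len(seq)) for cid, seq in assembly],
        columns=["contig_id", "length"],
    ).to_csv(stage / "assembly_info.tsv", sep="\t", index=False)
    return str(path)


def run_traditional(config: PipelineConfig) -> tuple[Assembly, RunReport]:
    """One-step co-assembly of all samples."""
    samples = config.load_samples()
    if not samples:
        raise ValueError("manifest is empty")
    report = RunReport(mode="traditional")
    report.total_pairs = sum(len(s) for s in samples)
    report.input_pairs["assembly"] = report.total_pairs
    stage = _stage_dir(config, "traditional")
    t0 = time.perf_counter()
    assembly = assemble(samples, config.k, config.min_count, config.min_contig_len)
    report.stage_times["assembly"] = time.perf_counter() - t0
    report.final_assembly_path = _write_assembly(stage, assembly)
    log.info("traditional: %d pairs -> %d contigs in %.1fs",
             report.total_pairs, assembly.n_contigs, report.stage_times["assembly"])
    return assembly, report


def run_sequential(config: PipelineConfig) -> tuple[Assembly, RunReport]:
    """Three-step sequential co-assembly; see module docstring for semantics."""
    samples = config.load_samples()
    by_id = {s.sample_id: s for s in samples}
    if not config.subset:
        raise ValueError("sequential mode requires a non-empty subset")
    missing = [sid for sid in config.subset if sid not in by_id]
    if missing:
        raise ValueError(f"subset samples not in manifest: {missing}")
    subset = [by_id[sid] for sid in config.subset]
    subset_ids = set(config.subset)
    fingerprint = _config_fingerprint(config, samples)

    report = RunReport(mode="sequential")
    report.total_pairs = sum(len(s) for s in samples)
    report.input_pairs["step1"] = sum(len(s) for s in subset)

    # step 1: subset co-assembly (resumable)
    step1_dir = _stage_dir(config, "step1")
    t0 = time.perf_counter()
    if _stage_done(step1_dir, fingerprint):
        log.info("step1: reusing %s", step1_dir)
        contigs = _io.read_fasta(step1_dir / "contigs.fa")
        step1 = Assembly(contigs, params={"resumed": True}, source=list(subset_ids))
    else:
        step1 = assemble(subset, config.k, config.min_count, config.min_contig_len)
        _write_assembly(step1_dir, step1)
        _mark_done(step1_dir, fingerprint)
    report.stage_times["step1"] = time.perf_counter() - t0
    if step1.n_contigs == 0:
        raise RuntimeError(
            "step-1 assembly produced no contigs: the subset is too shallow for "
            f"k={config.k}, min_count={config.min_count}"
        )
    log.info("step1: %d contigs from %d samples", step1.n_contigs, len(subset))

    # step 2: map every sample (subset included) against the step-1 assembly
    t0 = time.perf_counter()
    index = build_index(step1, config.mapper.k_index)
    pools: dict[str, list] = {}
    summary_rows = []
    for s in samples:
        ts = time.perf_counter()
        part = partition_sample(s, index, config.mapper, config.subtract_discordant)
        report.map_times[s.sample_id] = time.perf_counter() - ts
        report.pool_sizes[s.sample_id] = len(part.unaligned_pool)
        report.status_counts[s.sample_id] = dict(part.status_counts)
        pools[s.sample_id] = part.unaligned_pool
        summary_rows.append(
            {
                "sample": s.sample_id,
                "pairs": part.n_pairs,
                "concordant": part.status_counts.get("concordant", 0),
                "discordant": part.status_counts.get("discordant", 0),
                "single": part.status_counts.get("mate1_only", 0)
                + part.status_counts.get("mate2_only", 0),
                "unaligned": part.status_counts.get("unaligned", 0),
                "overall_read_alignment_pct": part.overall_read_alignment,
            }
        )
    report.stage_times["step2"] = time.perf_counter() - t0
    step2_dir = _stage_dir(config, "step2")
    if step2_dir is not None:
        pd.DataFrame(summary_rows).to_csv(
            step2_dir / "mapping_summary.tsv", sep="\t", index=False, float_format="%.4f"
        )
        for s in samples:
            sdir = step2_dir / s.sample_id
            sdir.mkdir(exist_ok=True)
            pool_set = SampleReadSet(s.sample_id, pools[s.sample_id])
            _io.write_fastq_pair(
                pool_set, sdir / "unaligned_R1.fq.gz", sdir / "unaligned_R2.fq.gz"
            )
    log.info("step2: mapped %d samples (series %.1fs, parallel %.1fs)",
             len(samples), report.series_map_time, report.parallel_map_time)

    # step 3: subset raw reads + non-subset unaligned pools
    step3_inputs: list[SampleReadSet] = list(subset)
    for s in samples:
        if s.sample_id in subset_ids:
            continue
        step3_inputs.append(SampleReadSet(f"{s.sample_id}.pool", pools[s.sample_id]))
    report.step3_input_pairs = sum(len(s) for s in step3_inputs)
    report.input_pairs["step3"] = report.step3_input_pairs
    report.step3_pair_ids = {p.pair_id for s in step3_inputs for p in s.pairs}
    step3_dir = _stage_dir(config, "step3")
    t0 = time.perf_counter()
    final = assemble(step3_inputs, config.k, config.min_count, config.min_contig_len)
    report.stage_times["step3"] = time.perf_counter() - t0
    report.final_assembly_path = _write_assembly(step3_dir, final)
    if config.out_dir is not None:
        (Path(config.out_dir) / "report.json").write_text(
            json.dumps(
                {
                    "mode": report.mode,
                    "stage_times": report.stage_times,
                    "pool_sizes": report.pool_sizes,
                    "total_pairs": report.total_pairs,
                    "step3_input_pairs": report.step3_input_pairs,
                    "step3_input_fraction": report.step3_input_fraction,
                },
                indent=2,
            )
        )
    log.info("step3: %d of %d pairs (%.1f%%) -> %d contigs",
             report.step3_input_pairs, report.total_pairs,
             100 * report.step3_input_fraction, final.n_contigs)
    return final, report


def run_subset_only(config: PipelineConfig) -> tuple[Assembly, RunReport]:
    """Co-assembly of the subset samples alone (the step-1 assembly by itself)."""
    samples = config.load_samples()
    by_id = {s.sample_id: s for s in samples}
    subset = [by_id[sid] for sid in config.subset]
    if not subset:
        raise ValueError("subset-only mode requires a non-empty subset")
    report = RunReport(mode="subset_only")
    report.total_pairs = sum(len(s) for s in samples)
    report.input_pairs["assembly"] = sum(len(s) for s in subset)
    t0 = time.perf_counter()
    assembly = assemble(subset, config.k, config.min_count, config.min_contig_len)
    report.stage_times["assembly"] = time.perf_counter() - t0
    return assembly, report


_RUNNERS = {
    "sequential": run_sequential,
    "traditional": run_traditional,
    "subset_only": run_subset_only,
}


def compare_strategies(
    configs: list[PipelineConfig],
    refs: ReferenceSet | None = None,
    labels: list[str] | None = None,
    eval_params: EvalParams = EvalParams(),
) -> pd.DataFrame:
    """Run >= 2 strategies over the same manifest and tabulate their EvalReports."""
    if len(configs) < 2:
        raise ValueError("need at least two configs to compare")
    ids0 = sorted(s.sample_id for s in configs[0].load_samples())
    for cfg in configs[1:]:
        if sorted(s.sample_id for s in cfg.load_samples()) != ids0:
            raise ValueError("configs must share the same sample manifest")
    if labels is None:
        labels = [cfg.mode for cfg in configs]
    rows = []
    for label, cfg in zip(labels, configs):
        assembly, report = _RUNNERS[cfg.mode](cfg)
        ev: EvalReport = evaluate(
            assembly, refs=refs, samples=cfg.load_samples(),
            eval_params=eval_params, map_params=cfg.mapper,
        )
        rows.append(
            {
                "strategy": label,
                "n_contigs": assembly.n_contigs,
                "total_length": ev.total_length,
                "auN": ev.auN,
                "N50": ev.N50,
                "genome_fraction": ev.genome_fraction if refs is not None else float("nan"),
                "duplication_ratio": ev.duplication_ratio if refs is not None else float("nan"),
                "misassemblies": ev.misassemblies if refs is not None else float("nan"),
                "mean_read_alignment": ev.mean_read_alignment,
                "step3_input_fraction": report.step3_input_fraction
                if cfg.mode == "sequential"
                else float("nan"),
            }
        )
    return pd.DataFrame(rows)


def rank_subsets(
    config: PipelineConfig, candidate_subsets: list[list[str]]
) -> pd.DataFrame:
    """Rank candidate step-1 subsets by mean overall read alignment of all
    samples against each candidate's co-assembly (highest first) — the
    subset-selection heuristic for choosing the seed of a sequential run."""
    samples = config.load_samples()
    by_id = {s.sample_id: s for s in samples}
    rows = []
    for subset in candidate_subsets:
        assembly = assemble(
            [by_id[sid] for sid in subset], config.k, config.min_count, config.min_contig_len
        )
        from .assembly_eval import read_alignment_eval

        res = read_alignment_eval(samples, assembly, config.mapper)
        rows.append({"subset": ",".join(subset), "mean_read_alignment": res["mean"]})
    return (
        pd.DataFrame(rows)
        .sort_values("mean_read_alignment", ascending=False)
        .reset_index(drop=True)
    )


def load_config(path: str | Path) -> PipelineConfig:
    """Load a YAML run configuration (manifest, subset, parameters)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    mapper_kwargs = raw.get("mapper", {})
    manifest = {
        sid: (entry["r1"], entry["r2"]) for sid, entry in (raw.get("manifest") or {}).items()
    }
    return PipelineConfig(
        manifest=manifest or None,
        subset=list(raw.get("subset", [])),
        mode=raw.get("mode", "sequential"),
        k=int(raw.get("k", DEFAULT_K)),
        min_count=int(raw.get("min_count", DEFAULT_MIN_COUNT)),
        min_contig_len=int(raw.get("min_contig_len", DEFAULT_MIN_CONTIG_LEN)),
        mapper=MapParams(**mapper_kwargs),
        subtract_discordant=bool(raw.get("subtract_discordant", False)),
        workers=int(raw.get("workers", 1)),
        seed=int(raw.get("seed", 0)),
        out_dir=raw.get("out_dir"),
    )
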
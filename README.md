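# seqcoasm

**Sequential metagenome co-assembly at desk scale.**

Co-assembling shotgun reads from many microbiome samples is dominated by
redundant reads: abundant organisms are sequenced far past the depth needed
to assemble their genomes, and every extra copy costs assembler time and
memory. `seqcoasm` implements the *sequential co-assembly* strategy that
removes this redundancy with nothing but an assembler and a read mapper:

1. **Step 1** — co-assemble reads from a small subset of samples;
2. **Step 2** — map *every* sample's read pairs to that assembly and set
   aside each sample's *unaligned pool*: the pairs that fail to align
   concordantly (same contig, FR orientation, insert within the expected
   window — the semantics of Bowtie 2's `--un-conc-gz` output);
3. **Step 3** — co-assemble the subset samples' full read sets together
   with the non-subset unaligned pools.

Reads from organisms already assembled in step 1 are subtracted; reads from
organisms the subset missed survive to step 3. The final input is a
fraction of the original dataset, while genome recovery stays on par with a
traditional one-step co-assembly of everything.

The package is self-contained: it bundles a multi-sample community
simulator with per-read ground truth, a canonical-k-mer de Bruijn unitig
assembler, a seed-and-extend paired-end mapper, and an evaluation suite
(genome fraction, duplication ratio, misassembly counts, mismatch rate,
auN/N50, and the reference-free overall-read-alignment metric). External
MEGAHIT can be swapped in behind the same assembler interface for real
datasets; nothing external is needed to run or test the pipeline.

## The arithmetic of redundancy

For organism relative abundances $a_1,\dots,a_n$ (summing to 1) and a
per-genome requirement of $m$ reads, the minimum sequencing depth is

$$D = \left\lceil \frac{m}{\min_i a_i} \right\rceil,$$

of which $D - n\,m$ reads are informationally redundant. A 90/5/5
three-organism community with $m = 10{,}000$ needs $D = 200{,}000$ reads —
180,000 of them from the dominant organism, 85% of the dataset redundant.
`seqcoasm.coverage_plan` exposes this planning arithmetic
(`required_depth`, `expected_reads`, `excess`), with optional
genome-length weighting to convert organismal abundance into read share.

Two reference-free quantities drive strategy comparison:

- **overall read alignment** — the percentage of a sample's reads placed at
  least once on an assembly, a proxy for recovered genome content;
- **cumulative relative abundance** — ranked community abundance summed
  over the top taxa, which the overall read alignment of a partial
  assembly tracks.

## Worked example

```python
import seqcoasm as sq

# a 20-genome community, log-normally distributed abundances, 10 samples
refs = sq.generate_genomes(20, (5_000, 20_000), gc=0.5, seed=42)
profile = sq.assign_abundances(refs, n_samples=10, model="lognormal",
                               core_fraction=0.25, seed=42)
samples = sq.simulate_reads(refs, profile, depth=20_000, read_len=100,
                            insert=(300.0, 30.0), sub_error_rate=0.002, seed=42)

subset = [s.sample_id for s in samples[:3]]
seq_asm, report = sq.run_sequential(
    sq.PipelineConfig(samples=samples, subset=subset, mode="sequential"))
trad_asm, _ = sq.run_traditional(
    sq.PipelineConfig(samples=samples, mode="traditional"))

print(f"step-3 input: {100 * report.step3_input_fraction:.1f}% of all pairs")
for name, asm in [("sequential", seq_asm), ("traditional", trad_asm)]:
    ev = sq.evaluate(asm, refs=refs, samples=samples)
    print(f"{name}: genome fraction {ev.genome_fraction:.2f}%, "
          f"duplication {ev.duplication_ratio:.4f}, "
          f"mean read alignment {ev.mean_read_alignment:.2f}%")
```

Output:

```
step-3 input: 39.9% of all pairs
sequential: genome fraction 90.79%, duplication 1.0016, mean read alignment 99.72%
traditional: genome fraction 90.79%, duplication 1.0016, mean read alignment 99.72%
```

The sequential run fed only 39.9% of the reads into the final assembly yet
recovered the same genome fraction as the traditional co-assembly of all
200,000 pairs (the ~9% shortfall from 100% is the rare tail of the
community, which neither strategy has the depth to assemble). The same
objects are reachable from the command line: `seqcoasm simulate`,
`seqcoasm plan`, `seqcoasm assemble`, `seqcoasm subtract`,
`seqcoasm sequential -c config.yml`, `seqcoasm compare`, `seqcoasm eval`.

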
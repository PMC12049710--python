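# Methods

This note documents the models, algorithms, parameter defaults and design
choices behind `seqcoasm`, and what its synthetic benchmarks do and do not
demonstrate about real data.

## Sequential co-assembly semantics

The pipeline's contract is fixed by three rules.

**Subtraction is concordant-only.** Step 2 removes a pair from a sample
only when both mates place on the same contig of the step-1 assembly in
FR orientation with an insert length inside the expected window
(mean ± 4 SD). Discordant pairs, single-mate placements and fully
unaligned pairs all remain in the unaligned pool. This mirrors the
behaviour of a mapper's "un-conc" output and errs on the side of keeping
reads: a pair is only declared redundant when the assembly demonstrably
already contains its locus. A `subtract_discordant` switch removes
discordant pairs as well for users who want a more aggressive reduction.

**Step 3 input is an exact union.** The final co-assembly receives the
subset samples' *raw* read sets plus the unaligned pools of the
*non-subset* samples. Subset samples are still mapped in step 2 (their
alignment rates are informative) but their pools are excluded from the
union so no pair can enter twice. The pipeline report carries the exact
pair-id set fed to step 3; tests assert the set equality
`step3 = subset ∪ (pools \ subset)` rather than just the counts.

**Overall read alignment counts mates.** The reference-free recovery
metric is `100 × (mates with ≥ 1 verified placement) / (2 × pairs)`. A
production mapper's "overall alignment rate" mixes concordant, discordant
and rescued-mate categories in a tool-specific way; the mate-level
definition here is the closest formulation implementable without
replicating one tool's bookkeeping, and it is used consistently for every
strategy being compared, so orderings and differences are meaningful even
though absolute values are not comparable across mappers.

## Community simulator

`community_sim` generates the study conditions, not merely fixtures.

- **Genomes** are i.i.d. random sequences over ACGT with a configurable GC
  fraction (default 0.5) and uniform lengths (default 5–20 kbp). Random
  sequences of this size are effectively repeat-free at k = 31, which is
  deliberate: assembly difficulty then comes from coverage and errors, not
  repeat structure.
- **Abundances** follow a log-normal model (default σ = 2.0), giving the
  steep ranked-abundance curves and concave cumulative-abundance profiles
  characteristic of gut communities; a log-series model (θ^r/r) and
  explicit matrices are also available. A `core_fraction` (default 0.25)
  of taxa is present in every sample; each remaining taxon occupies a
  Bernoulli(0.3)-chosen strict subset of samples. Per-sample multiplicative
  jitter (log-normal, σ = 0.5) differentiates samples before rows are
  renormalised.
- **Reads.** Pair counts per taxon are multinomial with probability
  proportional to abundance × genome length, because shotgun read share
  scales with genome size; `length_weighted=False` equates read share with
  abundance directly, which is the convention of the depth-planning
  arithmetic. Fragments are uniform along the genome, sequenced from a
  random strand; mate 2 is the reverse complement of the fragment end
  (FR). Defaults: 100 bp reads, 300 ± 30 bp inserts, substitution errors
  only at a configurable rate with constant 'I' qualities. Truth records
  (origin genome, forward-strand fragment start, strand) accompany every
  pair.
- **Determinism.** All randomness flows from one seed;
  sample *i* uses the stream `default_rng([seed, i])`, so extending a
  dataset with more samples never changes existing ones, and FASTQ output
  is byte-identical across reruns (gzip written with `mtime=0`).

What the simulator does **not** emulate: indels, chimeric fragments, PCR
duplicates, platform quality profiles, host contamination, strain-level
variation, and shared sequence between genomes. Passing benchmarks
therefore demonstrate the correctness and internal consistency of the
pipeline's accounting and the qualitative behaviour of the strategy —
not performance on real communities with repeats and shared loci, where
the subtraction step can discard reads from regions that are identical
across genomes (see Limitations).

## Depth planning

`coverage_plan` implements the redundancy arithmetic on organismal
abundances: `required_depth = ceil(m / min(a))`, per-organism expected
reads by largest-remainder apportionment (so counts always sum to the
requested depth; remainder ties resolve in favour of the later taxon), and
`excess = required_depth − n·m` with its fraction of total depth. A zero
abundance is rejected — that organism can never reach the minimum.
Optional genome lengths convert abundances to length-weighted read shares
consistent with the simulator's default.

## Assembler

A single-k (default 31, odd, ≤ 31 for 2-bit packing) de Bruijn unitig
assembler over canonical k-mers (numeric minimum of a k-mer and its
reverse complement; odd k excludes self-complementary k-mers).

1. Count canonical k-mers of all mates in one vectorised pass; drop
   k-mers with count < `min_count` (default 2, which removes singleton
   error k-mers).
2. Clean the graph (default `clean_ratio = 0.25`, up to 3 rounds): a
   maximal non-branching path of ≤ k nodes whose mean count is below
   `clean_ratio` × the strongest junction neighbour's count is removed,
   whether it dangles (tip) or bridges (weak bubble limb). This targets
   error k-mers that survive the count filter at high coverage — at 250×
   with a 0.2% substitution rate, identical errors recur often enough
   that pure count filtering leaves a branch every few hundred bases and
   shatters the unitigs. The test is purely relative, so uniform-coverage
   (error-free) graphs pass through untouched and isolated components are
   never removed; `clean_ratio = 0` disables cleaning entirely.
3. Emit maximal non-branching paths of the bidirected graph as contigs.
   A walk never revisits a canonical node, so hairpin structures (a
   sequence containing both a k-mer and its reverse complement) terminate
   paths; every retained k-mer appears in exactly one contig, a property
   tested against a brute-force k-mer inventory.
4. Orientation and order are deterministic: each unitig is emitted as the
   lexicographically smaller of itself and its reverse complement, contigs
   sorted by (length desc, sequence asc), then named. Contigs shorter than
   `min_contig_len` (default 200 bp) are dropped.

The assembler is exactly reproducible run-to-run, unlike multi-threaded
production assemblers. A MEGAHIT adapter (`megahit_assemble`) satisfies
the same interface for real datasets and is not exercised by unit tests.

## Mapper

Seed-and-vote with ungapped verification. The index stores every
canonical 31-mer of every contig with its positions. Each mate samples
seed positions every `seed_stride` bases (default 7, both ends always
included); each seed hit votes for a (contig, diagonal, strand); the
best-supported candidate must collect at least `min_seed_frac` (default
0.25) of the mate's seeds, with ties broken deterministically (lowest
contig, leftmost position, forward strand). Verification compares the
full mate against the contig ungapped and accepts at most `max_mismatch`
(default 0.05) mismatch fraction; placements must lie fully within a
contig. Seeds hitting more than `max_seed_hits` (default 100) positions
are skipped as repetitive. There is no indel alignment — the simulator
emits none — and no rescue of a failed best candidate; an external mapper
can replace this backend for real data.

## Evaluation

Reference-based metrics are computed from exact-31-mer-anchored ungapped
blocks: anchors sharing a (reference, strand, diagonal) are merged when
separated by ≤ 200 bp, extended outward over exact matches, and blocks
shorter than 65 bp are discarded; overlapping candidates on a contig are
resolved greedily longest-first (≤ 15 bp tolerated overlap). From the
blocks:

- **genome fraction** — percent of reference bases covered ≥ 1×
  (union; multiplicity is deliberately ignored here);
- **duplication ratio** — aligned contig bases / covered reference bases
  (≥ 1 whenever anything aligns, and exactly 1 for a single-copy perfect
  sub-assembly);
- **misassemblies** — for adjacent blocks of one contig: a reference or
  strand switch, or a diagonal inconsistency ≥ 1000 bp, is extensive;
  50–999 bp is local. A contig with ≥ 1 extensive event contributes its
  full length to `misassembled_contig_length` once. These thresholds are
  config-exposed stand-ins for the QUAST convention family, not a parity
  claim; ungapped blocks are adequate because divergence is
  substitution-only.
- **mismatches per 100 kbp**, **auN** (Σ L²/Σ L), **N50**, and the total
  length of contigs ≥ 50 kbp round out the bundle.

Genome fraction and duplication ratio are cross-checked in the tests
against an independent per-base coverage counter that locates exact-slice
contigs by string search.

## Benchmark problem sizes

The packaged benchmark community is 20 genomes of 5–20 kbp, log-normal
abundances, 10 samples × 20,000 pairs at a 0.2% substitution rate, with a
3-sample subset seeding the sequential run; the nested-assembly tracking
check uses 5 samples × 5,000 pairs of the same community. These sizes keep
the full test suite and the acceptance script in the minutes range on one
CPU while leaving abundant taxa at several-hundred-fold coverage and rare
taxa below assembly depth — the regime the strategy is about. On this
benchmark the sequential and traditional strategies recover the same
genome fraction to well within one percentage point, both out-align the
subset-only assembly, and the step-3 input falls below 60% of all pairs.

## Known limitations

- Random genomes underestimate the difficulty of real communities:
  repeats within and between genomes both fragment assemblies and make
  concordant subtraction remove reads from shared regions, a bias of the
  method itself that these benchmarks cannot surface.
- The mate-level overall-read-alignment definition is not numerically
  comparable to any specific production mapper's summary statistic.
- Graph cleaning assumes errors are rare relative to local coverage; at
  error rates far above the default, or for taxa at coverage ~`min_count`,
  real variation could be removed (the `clean_ratio` test is relative, so
  only paths several-fold weaker than their junction partners are at risk).
- Wall-clock and memory accounting in the run report are informative only;
  they are recorded per stage (with series and parallel views of the
  mapping stage) but never asserted on.
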
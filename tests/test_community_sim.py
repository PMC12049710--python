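"""Community simulator: genome generation, abundance models, read provenance."""

import numpy as np
import pytest

import seqcoasm as sq
from seqcoasm import io as sqio


class TestGenerateGenomes:
    def test_degenerate_length_range_is_exact(self):
        refs = sq.generate_genomes(1, (1000, 1000), 0.5, seed=7)
        assert len(refs) == 1 and len(refs.entries[0][1]) == 1000

    def test_determinism_gives_byte_identical_fasta(self, tmp_path):
        paths = []
        for i in range(2):
            refs = sq.generate_genomes(5, (1000, 3000), 0.5, seed=7)
            p = tmp_path / f"refs{i}.fa"
            sqio.write_reference_set(refs, p)
            paths.append(p.read_bytes())
        assert paths[0] == paths[1]

    def test_gc_content_matches_request(self):
        refs = sq.generate_genomes(50, (5_000, 20_000), gc=0.4, seed=1)
        pooled = "".join(seq for _, seq in refs)
        gc = (pooled.count("G") + pooled.count("C")) / len(pooled)
        assert abs(gc - 0.4) < 0.02

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            sq.generate_genomes(2, (500, 100), 0.5, seed=0)
        with pytest.raises(ValueError):
            sq.generate_genomes(2, (100, 500), 1.5, seed=0)


class TestAssignAbundances:
    def test_explicit_matrix_is_normalised_and_cumulative(self):
        refs = sq.generate_genomes(3, (1000, 1000), 0.5, seed=0)
        prof = sq.assign_abundances(refs, 1, model="explicit", matrix=[[0.9, 0.05, 0.05]])
        curve = sq.cumulative_abundance_curve(prof)
        assert curve[0] == pytest.approx((1 / 3, 90.0))
        assert curve[1] == pytest.approx((2 / 3, 95.0))
        assert curve[2] == pytest.approx((1.0, 100.0))

    def test_rows_sum_to_one(self):
        refs = sq.generate_genomes(12, (1000, 2000), 0.5, seed=2)
        prof = sq.assign_abundances(refs, 6, "lognormal", core_fraction=0.5, seed=2)
        assert np.allclose(prof.abundance.sum(axis=1), 1.0, atol=1e-9)

    def test_core_fraction_controls_ubiquitous_taxa(self):
        refs = sq.generate_genomes(20, (1000, 2000), 0.5, seed=3)
        prof = sq.assign_abundances(refs, 10, "lognormal", core_fraction=0.25, seed=3)
        n_ubiquitous = int(prof.presence.all(axis=0).sum())
        assert n_ubiquitous == 5

    def test_ranked_abundances_give_concave_cumulative_curve(self):
        refs = sq.generate_genomes(30, (1000, 2000), 0.5, seed=4)
        prof = sq.assign_abundances(refs, 5, "lognormal", core_fraction=0.3, seed=4)
        curve = sq.cumulative_abundance_curve(prof)
        ys = [y for _, y in curve]
        assert all(b >= a - 1e-9 for a, b in zip(ys, ys[1:]))  # non-decreasing
        assert ys[-1] == pytest.approx(100.0, abs=1e-6)
        # log-like: the top 20% of taxa carry well over half the abundance
        assert ys[len(ys) // 5 - 1] > 60.0

    def test_uniform_profile_gives_straight_line(self):
        refs = sq.generate_genomes(4, (1000, 1000), 0.5, seed=5)
        prof = sq.assign_abundances(refs, 2, model="explicit", matrix=[[1, 1, 1, 1]] * 2)
        curve = sq.cumulative_abundance_curve(prof)
        for i, (x, y) in enumerate(curve, start=1):
            assert (x, y) == pytest.approx((i / 4, 100 * i / 4))

    def test_non_normalisable_row_rejected(self):
        refs = sq.generate_genomes(2, (1000, 1000), 0.5, seed=6)
        with pytest.raises(ValueError):
            sq.assign_abundances(refs, 1, model="explicit", matrix=[[0.0, 0.0]])


@pytest.fixture(scope="module")
def one_genome():
    refs = sq.generate_genomes(1, (4000, 4000), 0.5, seed=11)
    prof = sq.assign_abundances(refs, 2, model="explicit", matrix=[[1.0], [1.0]])
    return refs, prof


class TestSimulateReads:
    def test_error_free_mates_are_exact_substrings_at_truth_coordinates(self, one_genome):
        refs, prof = one_genome
        samples = sq.simulate_reads(refs, prof, 300, read_len=80, insert=(250, 20), seed=1)
        genome = refs.entries[0][1]
        for reads in samples:
            for pair, origin in zip(reads.pairs, reads.truth):
                # on '+' the fragment's forward start is mate1's start; on '-'
                # mate2 reads the forward strand from the same coordinate
                mate = pair.mate1 if origin.strand == "+" else pair.mate2
                assert genome[origin.start : origin.start + 80] == mate

    def test_depth_conservation_is_exact(self, one_genome):
        refs, prof = one_genome
        samples = sq.simulate_reads(refs, prof, 1234, read_len=80, insert=(250, 20), seed=2)
        assert all(len(s) == 1234 for s in samples)

    def test_absent_taxon_contributes_no_reads(self):
        refs = sq.generate_genomes(3, (2000, 2000), 0.5, seed=12)
        prof = sq.assign_abundances(refs, 1, model="explicit", matrix=[[0.5, 0.5, 0.0]])
        (reads,) = sq.simulate_reads(refs, prof, 500, read_len=80, insert=(250, 20), seed=3)
        assert all(t.genome_id != "genome_002" for t in reads.truth)

    def test_unweighted_read_share_matches_worked_example(self):
        # 90/5/5 with equal genome lengths at depth 200,000: ~180,000 from taxon A
        refs = sq.generate_genomes(3, (3000, 3000), 0.5, seed=13)
        prof = sq.assign_abundances(refs, 1, model="explicit", matrix=[[0.9, 0.05, 0.05]])
        (reads,) = sq.simulate_reads(
            refs, prof, 200_000, read_len=80, insert=(250, 20), seed=4,
            length_weighted=False,
        )
        n_a = sum(t.genome_id == "genome_000" for t in reads.truth)
        sd = np.sqrt(200_000 * 0.9 * 0.1)  # binomial SD ~ 134
        assert abs(n_a - 180_000) < 3 * sd

    def test_multinomial_fidelity_length_weighted(self):
        refs = sq.generate_genomes(4, (2000, 8000), 0.5, seed=14)
        prof = sq.assign_abundances(refs, 1, "lognormal", core_fraction=1.0, seed=14)
        depth = 100_000
        (reads,) = sq.simulate_reads(refs, prof, depth, read_len=80, insert=(250, 20), seed=5)
        share = prof.abundance[0] * refs.lengths
        share = share / share.sum()
        observed = np.array(
            [sum(t.genome_id == gid for t in reads.truth) for gid in refs.ids]
        )
        sd = np.sqrt(depth * share * (1 - share))
        assert np.all(np.abs(observed - depth * share) < 3 * np.maximum(sd, 1.0))

    def test_fastq_output_is_byte_identical_across_reruns(self, tmp_path, one_genome):
        refs, prof = one_genome
        blobs = []
        for i in range(2):
            samples = sq.simulate_reads(
                refs, prof, 200, read_len=80, insert=(250, 20),
                sub_error_rate=0.01, seed=9,
            )
            r1 = tmp_path / f"run{i}_R1.fq.gz"
            sqio.write_fastq_pair(samples[0], r1, tmp_path / f"run{i}_R2.fq.gz")
            blobs.append(r1.read_bytes())
        assert blobs[0] == blobs[1]

    def test_substitution_rate_is_respected(self, one_genome):
        refs, prof = one_genome
        genome = refs.entries[0][1]
        samples = sq.simulate_reads(
            refs, prof, 2000, read_len=80, insert=(250, 20),
            sub_error_rate=0.01, seed=6,
        )
        reads = samples[0]
        mismatches = bases = 0
        for pair, origin in zip(reads.pairs, reads.truth):
            if origin.strand != "+":
                continue
            ref_mate = genome[origin.start : origin.start + 80]
            mismatches += sum(a != b for a, b in zip(pair.mate1, ref_mate))
            bases += 80
        rate = mismatches / bases
        assert 0.005 < rate < 0.02  # i.i.d. substitutions near the requested 1%


def test_fastq_roundtrip_preserves_pairs(tmp_path, small_community):
    _, _, samples = small_community
    reads = samples[0]
    r1, r2 = tmp_path / "s_R1.fq.gz", tmp_path / "s_R2.fq.gz"
    sqio.write_fastq_pair(reads, r1, r2)
    back = sqio.read_fastq_pair(r1, r2, sample_id=reads.sample_id)
    assert [p.pair_id for p in back.pairs] == [p.pair_id for p in reads.pairs]
    assert all(a.mate1 == b.mate1 and a.mate2 == b.mate2
               for a, b in zip(back.pairs, reads.pairs))
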
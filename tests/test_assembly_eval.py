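"""Evaluation suite: block alignment, coverage metrics, misassemblies, contiguity."""

import numpy as np
import pytest

import seqcoasm as sq
from seqcoasm._codec import revcomp
from seqcoasm.assembly_eval import (
    align_contigs,
    contiguity_stats,
    count_misassemblies,
    duplication_ratio,
    evaluate,
    genome_fraction,
    mismatches_per_100kbp,
    read_alignment_eval,
)
from seqcoasm.types import Assembly

from conftest import random_dna


def brute_force_coverage(contig_seqs, refs):
    """Independent per-base oracle for genome fraction and duplication ratio.

    Locates each contig in the references by exact string search (forward or
    reverse complement) and counts covered/aligned bases directly. Valid for
    fixtures whose contigs are exact reference slices."""
    cover = {gid: np.zeros(len(seq), dtype=int) for gid, seq in refs}
    aligned_contig_bases = 0
    for contig in contig_seqs:
        placed = False
        for gid, seq in refs:
            for query in (contig, revcomp(contig)):
                pos = seq.find(query)
                if pos >= 0:
                    cover[gid][pos : pos + len(query)] += 1
                    aligned_contig_bases += len(query)
                    placed = True
                    break
            if placed:
                break
        assert placed, "brute-force oracle requires exact-slice contigs"
    covered = sum(int((c > 0).sum()) for c in cover.values())
    total = sum(len(seq) for _, seq in refs)
    gf = 100.0 * covered / total
    dup = aligned_contig_bases / covered if covered else None
    return gf, dup


@pytest.fixture(scope="module")
def refs():
    return sq.generate_genomes(2, (6_000, 6_000), 0.5, seed=41)


class TestAlignContigs:
    def test_identical_contig_gives_one_full_block(self, refs):
        gid, seq = refs.entries[0]
        (aln,) = align_contigs(Assembly([("c", seq)], params={}), refs)
        assert len(aln.blocks) == 1
        b = aln.blocks[0]
        assert (b.contig_start, b.contig_end) == (0, len(seq))
        assert (b.ref_id, b.ref_start, b.ref_end, b.strand, b.mismatches) == (
            gid, 0, len(seq), "+", 0,
        )

    def test_reverse_complement_contig_aligns_on_minus_strand(self, refs):
        gid, seq = refs.entries[0]
        (aln,) = align_contigs(Assembly([("c", revcomp(seq))], params={}), refs)
        assert len(aln.blocks) == 1
        b = aln.blocks[0]
        assert (b.ref_id, b.strand) == (gid, "-")
        assert (b.ref_start, b.ref_end) == (0, len(seq))

    def test_chimera_splits_into_two_blocks(self, refs):
        (g1, s1), (g2, s2) = refs.entries
        chimera = Assembly([("c", s1[:3000] + s2[:3000])], params={})
        (aln,) = align_contigs(chimera, refs)
        assert len(aln.blocks) == 2
        assert {b.ref_id for b in aln.blocks} == {g1, g2}

    def test_unalignable_contig_has_no_blocks(self, refs):
        (aln,) = align_contigs(Assembly([("c", random_dna(500, 9))], params={}), refs)
        assert aln.blocks == []


class TestCoverageMetrics:
    def test_perfect_assembly_scores_100_and_ratio_1(self, refs):
        asm = Assembly([(g, s) for g, s in refs], params={})
        aln = align_contigs(asm, refs)
        assert genome_fraction(aln, refs) == pytest.approx(100.0)
        assert duplication_ratio(aln, refs) == pytest.approx(1.0)

    def test_half_covered_single_reference(self):
        single = sq.generate_genomes(1, (10_000, 10_000), 0.5, seed=42)
        gid, seq = single.entries[0]
        aln = align_contigs(Assembly([("c", seq[:5000])], params={}), single)
        assert genome_fraction(aln, single) == pytest.approx(50.0)

    def test_duplicated_references_double_the_ratio(self, refs):
        asm = Assembly(
            [(f"{g}_copy{i}", s) for g, s in refs for i in (1, 2)], params={}
        )
        aln = align_contigs(asm, refs)
        assert duplication_ratio(aln, refs) == pytest.approx(2.0)
        assert genome_fraction(aln, refs) == pytest.approx(100.0)

    def test_overlapping_contigs_inflate_ratio(self):
        single = sq.generate_genomes(1, (1_000, 1_000), 0.5, seed=43)
        _, seq = single.entries[0]
        asm = Assembly([("a", seq[0:600]), ("b", seq[400:1000])], params={})
        aln = align_contigs(asm, single)
        assert duplication_ratio(aln, single) == pytest.approx(1.2)

    def test_empty_alignment_yields_zero_fraction_and_no_ratio(self, refs):
        aln = align_contigs(Assembly([("c", random_dna(500, 10))], params={}), refs)
        assert genome_fraction(aln, refs) == 0.0
        assert duplication_ratio(aln, refs) is None

    def test_genome_fraction_monotone_in_contigs(self, refs):
        _, s1 = refs.entries[0]
        small = align_contigs(Assembly([("a", s1[:2000])], params={}), refs)
        bigger = align_contigs(
            Assembly([("a", s1[:2000]), ("b", s1[3000:5000])], params={}), refs
        )
        assert genome_fraction(bigger, refs) >= genome_fraction(small, refs)

    def test_brute_force_oracle_agreement(self, refs):
        (g1, s1), (g2, s2) = refs.entries
        contig_sets = [
            [s1],
            [s1, s2],
            [s1[:2500], s1[1500:4000], s2[100:3100]],
            [revcomp(s1[500:3500]), s2],
        ]
        for contigs in contig_sets:
            asm = Assembly([(f"c{i}", s) for i, s in enumerate(contigs)], params={})
            aln = align_contigs(asm, refs)
            gf_expected, dup_expected = brute_force_coverage(contigs, refs)
            assert genome_fraction(aln, refs) == pytest.approx(gf_expected, abs=0.05)
            assert duplication_ratio(aln, refs) == pytest.approx(dup_expected, abs=0.005)


class TestMisassemblies:
    def test_perfect_assembly_has_none(self, refs):
        asm = Assembly([(g, s) for g, s in refs], params={})
        assert count_misassemblies(align_contigs(asm, refs)) == (0, 0, 0)

    def test_chimera_counts_one_extensive_event(self, refs):
        (_, s1), (_, s2) = refs.entries
        chimera = Assembly([("c", s1[:3000] + s2[:3000])], params={})
        mis, _, mis_len = count_misassemblies(align_contigs(chimera, refs))
        assert mis >= 1
        assert mis_len == 6000

    def test_reference_gap_of_500_is_local(self, refs):
        _, s1 = refs.entries[0]
        contig = s1[:3000] + s1[3500:6000]
        mis, local, mis_len = count_misassemblies(
            align_contigs(Assembly([("c", contig)], params={}), refs)
        )
        assert (mis, local, mis_len) == (0, 1, 0)

    def test_large_reference_jump_is_extensive(self):
        single = sq.generate_genomes(1, (12_000, 12_000), 0.5, seed=44)
        _, seq = single.entries[0]
        contig = seq[:3000] + seq[8000:11000]  # 5 kbp jump on one reference
        mis, local, mis_len = count_misassemblies(
            align_contigs(Assembly([("c", contig)], params={}), single)
        )
        assert mis == 1 and local == 0 and mis_len == 6000

    def test_strand_flip_is_extensive(self, refs):
        _, s1 = refs.entries[0]
        contig = s1[:3000] + revcomp(s1[3000:6000])
        mis, _, _ = count_misassemblies(
            align_contigs(Assembly([("c", contig)], params={}), refs)
        )
        assert mis >= 1


class TestMismatchRate:
    def test_single_substitution_in_10kbp(self):
        single = sq.generate_genomes(1, (10_000, 10_000), 0.5, seed=45)
        _, seq = single.entries[0]
        mut = list(seq)
        mut[5000] = {"A": "C", "C": "G", "G": "T", "T": "A"}[mut[5000]]
        aln = align_contigs(Assembly([("c", "".join(mut))], params={}), single)
        assert mismatches_per_100kbp(aln) == pytest.approx(10.0)

    def test_perfect_assembly_rate_zero(self, refs):
        asm = Assembly([(g, s) for g, s in refs], params={})
        assert mismatches_per_100kbp(align_contigs(asm, refs)) == 0.0

    def test_two_substitutions_in_100kbp(self):
        single = sq.generate_genomes(1, (100_000, 100_000), 0.5, seed=46)
        _, seq = single.entries[0]
        mut = list(seq)
        for pos in (20_000, 70_000):
            mut[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[mut[pos]]
        aln = align_contigs(Assembly([("c", "".join(mut))], params={}), single)
        assert mismatches_per_100kbp(aln) == pytest.approx(2.0)


class TestContiguity:
    def test_single_contig_identity(self):
        aun, n50, ge50k, total = contiguity_stats(
            Assembly([("a", "A" * 1234)], params={})
        )
        assert (aun, n50, total) == (1234.0, 1234, 1234)

    def test_hand_arithmetic_100_300(self):
        asm = Assembly([("a", "A" * 100), ("b", "C" * 300)], params={})
        aun, n50, ge50k, total = contiguity_stats(asm)
        assert aun == pytest.approx(250.0)
        assert n50 == 300 and ge50k == 0 and total == 400

    def test_short_contigs_do_not_reach_50kbp_bucket(self):
        asm = Assembly([("a", "A" * 10), ("b", "C" * 20)], params={})
        assert contiguity_stats(asm)[2] == 0

    def test_empty_assembly_warns(self):
        with pytest.warns(UserWarning):
            assert contiguity_stats(Assembly([], params={})) == (0.0, 0, 0, 0)


class TestReadAlignmentEval:
    def test_reads_from_assembly_itself_align_fully(self, refs):
        prof = sq.assign_abundances(refs, 2, model="explicit", matrix=[[0.5, 0.5]] * 2)
        samples = sq.simulate_reads(refs, prof, 400, 100, (300, 30), 0.0, seed=8)
        asm = Assembly([(g, s) for g, s in refs], params={})
        res = read_alignment_eval(samples, asm)
        assert all(v == 100.0 for v in res["per_sample"])

    def test_empty_assembly_gives_zero_for_all_samples(self, refs):
        prof = sq.assign_abundances(refs, 2, model="explicit", matrix=[[0.5, 0.5]] * 2)
        samples = sq.simulate_reads(refs, prof, 50, 100, (300, 30), 0.0, seed=9)
        res = read_alignment_eval(samples, Assembly([], params={}))
        assert res["per_sample"] == [0.0, 0.0]

    def test_dominant_genome_assembly_tracks_its_read_share(self):
        # 90/5/5 with equal lengths, unweighted: an assembly of only the
        # dominant genome should align ~90% of the reads
        refs3 = sq.generate_genomes(3, (5_000, 5_000), 0.5, seed=47)
        prof = sq.assign_abundances(
            refs3, 1, model="explicit", matrix=[[0.9, 0.05, 0.05]]
        )
        depth = 5_000
        samples = sq.simulate_reads(
            refs3, prof, depth, 100, (300, 30), 0.0, seed=10, length_weighted=False
        )
        asm = Assembly([refs3.entries[0]], params={})
        res = read_alignment_eval(samples, asm)
        sd_pct = 100 * np.sqrt(0.9 * 0.1 / depth)
        assert abs(res["mean"] - 90.0) < 3 * sd_pct + 1.0  # + edge-pair slack


def test_evaluate_bundles_all_metrics(refs):
    prof = sq.assign_abundances(refs, 2, model="explicit", matrix=[[0.5, 0.5]] * 2)
    samples = sq.simulate_reads(refs, prof, 300, 100, (300, 30), 0.0, seed=11)
    asm = Assembly([(g, s) for g, s in refs], params={})
    report = evaluate(asm, refs=refs, samples=samples)
    assert report.genome_fraction == pytest.approx(100.0)
    assert report.duplication_ratio == pytest.approx(1.0)
    assert report.misassemblies == 0
    assert report.mean_read_alignment == pytest.approx(100.0)
    assert report.N50 == max(len(s) for _, s in refs)
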
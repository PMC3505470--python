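"""Assembler tests: overlaps, consensus, homoeolog separation, filters."""

import numpy as np
import pytest

from homasm import asm, synth
from homasm.align import local_align, revcomp
from homasm.asm import (AsmParams, Contig, assemble_cluster, call_consensus,
                        compute_overlaps, filter_contigs, permissive_params,
                        strict_params)

from conftest import make_read, mutate_seq, rand_seq, tile_reads


def _flip(base):
    return {"A": "C", "C": "G", "G": "T", "T": "A"}[base]


class TestComputeOverlaps:
    def test_perfect_overlap_relative_score_one(self):
        rng = np.random.default_rng(0)
        base = rand_seq(rng, 300)
        reads = [make_read("r1", base[:200]), make_read("r2", base[100:])]
        ovs = compute_overlaps(reads, permissive_params())
        assert len(ovs) == 1
        assert ovs[0].columns == 100
        assert ovs[0].relative_score == 1.0

    def test_two_mismatches_score_arithmetic(self):
        """100-base overlap with 2 substitutions: (100-2-2*2)/100 = 0.94,
        rejected at 0.97 but accepted at 0.90."""
        rng = np.random.default_rng(1)
        base = rand_seq(rng, 300)
        r2 = list(base[100:])
        r2[50] = _flip(r2[50])
        r2[70] = _flip(r2[70])
        reads = [make_read("r1", base[:200]), make_read("r2", "".join(r2))]
        perm = compute_overlaps(reads, permissive_params())
        assert len(perm) == 1
        assert perm[0].relative_score == pytest.approx(0.94)
        assert compute_overlaps(reads, strict_params()) == []

    def test_homoeolog_level_divergence_rejected_in_strict_mode(self):
        """~3% divergence over a 300-base overlap falls far below 0.97."""
        rng = np.random.default_rng(2)
        base = rand_seq(rng, 400)
        diverged = mutate_seq(rng, base, 0.03)
        reads = [make_read("r1", base[:300]), make_read("r2", diverged[:300])]
        assert compute_overlaps(reads, strict_params()) == []

    def test_reverse_complement_overlap_found(self):
        rng = np.random.default_rng(3)
        base = rand_seq(rng, 300)
        reads = [make_read("r1", base[:200]), make_read("r2", revcomp(base[100:]))]
        ovs = compute_overlaps(reads, strict_params())
        assert len(ovs) == 1
        assert ovs[0].orientation == "-"

    def test_short_overlaps_below_minimum_skipped(self):
        rng = np.random.default_rng(4)
        base = rand_seq(rng, 230)
        reads = [make_read("r1", base[:130]), make_read("r2", base[100:])]
        assert compute_overlaps(reads, strict_params(min_overlap=40)) == []


class TestCallConsensus:
    def test_unanimous_column_error_bounded_by_quality(self):
        reads = [make_read(f"r{i}", "ACGTACGTACGT", qual=30) for i in range(5)]
        seq, err = call_consensus([(r, 0, False) for r in reads])
        assert seq == "ACGTACGTACGT"
        assert np.all(err <= 1e-3)

    def test_quality_weighted_majority_wins(self):
        """Three Q40 'A' votes outweigh one Q10 'G' at the middle column."""
        good = "ACGTACGTAAACGTACGTAC"
        bad = good[:10] + "G" + good[11:]
        layout = [(make_read(f"g{i}", good, qual=40), 0, False)
                  for i in range(3)]
        layout.append((make_read("b", bad, qual=10), 0, False))
        seq, err = call_consensus(layout)
        assert seq == good

    def test_single_read_column_is_the_read(self):
        r = make_read("solo", "ACGTACGTACGTACGTACGT", qual=25)
        seq, err = call_consensus([(r, 0, False)])
        assert seq == r.sequence
        assert np.allclose(err, 10 ** -2.5, rtol=1e-6)


class TestAssembleCluster:
    def test_error_free_tiling_reconstructs_transcript(self):
        rng = np.random.default_rng(5)
        transcript = rand_seq(rng, 900)
        reads = tile_reads(transcript, 300, 30, qual=35)
        contigs = assemble_cluster(reads, strict_params())
        assert len(contigs) == 1
        got = contigs[0].consensus
        assert got == transcript or got == revcomp(transcript)

    def test_homoeolog_pair_separates_in_strict_mode(self, triplet_family_reads):
        family, reads = triplet_family_reads
        a, b = family.genome_labels[0], family.genome_labels[1]
        pair_reads = [r for r in reads
                      if r.truth.genome_label in (a, b)]
        contigs = assemble_cluster(pair_reads, strict_params())
        # leftover unplaced single reads are removed by the quality filter
        big = asm.filter_contigs(contigs, strict_params())
        assert len(big) == 2
        truth_ids = {r.read_id: r.truth.genome_label for r in pair_reads}
        for c in big:
            member_labels = {truth_ids[rid] for rid, _, _ in c.members}
            assert len(member_labels) == 1  # no chimeric membership
            ref = family.sequences[member_labels.pop()]
            hit = local_align(c.consensus, ref)
            assert hit.pct_id >= 99.9

    def test_homoeolog_pair_merges_in_permissive_mode(self, triplet_family_reads):
        family, reads = triplet_family_reads
        a, b = family.genome_labels[0], family.genome_labels[1]
        pair_reads = [r for r in reads if r.truth.genome_label in (a, b)]
        contigs = assemble_cluster(pair_reads, permissive_params())
        big = [c for c in contigs if len(c) > 250 and len(c.members) > 1]
        assert len(big) == 1
        truth_ids = {r.read_id: r.truth.genome_label for r in pair_reads}
        labels = {truth_ids[rid] for rid, _, _ in big[0].members}
        assert labels == {a, b}

    def test_conflict_columns_split_merged_haplotypes(self):
        """Two haplotypes 2 SNPs apart merge at 0.97 but are separated by
        the conflict-column bipartition (multi-pass behaviour)."""
        rng = np.random.default_rng(6)
        anc = rand_seq(rng, 600)
        hap_b = list(anc)
        hap_b[280] = _flip(hap_b[280])
        hap_b[320] = _flip(hap_b[320])
        hap_b = "".join(hap_b)
        reads = tile_reads(anc, 400, 25, qual=40, prefix="a") + \
            tile_reads(hap_b, 400, 25, qual=40, prefix="b")
        contigs = assemble_cluster(reads, strict_params())
        seqs = sorted(c.consensus for c in contigs if len(c) > 500)
        assert len(seqs) == 2
        assert {s if s[0] == anc[0] else revcomp(s) for s in seqs} == {anc, hap_b}

    def test_single_pass_keeps_merged_haplotypes(self):
        rng = np.random.default_rng(6)
        anc = rand_seq(rng, 600)
        hap_b = list(anc)
        hap_b[280] = _flip(hap_b[280])
        hap_b[320] = _flip(hap_b[320])
        reads = tile_reads(anc, 400, 25, qual=40, prefix="a") + \
            tile_reads("".join(hap_b), 400, 25, qual=40, prefix="b")
        contigs = assemble_cluster(reads, strict_params(max_passes=1))
        assert len([c for c in contigs if len(c) > 500]) == 1

    def test_deterministic_under_read_order(self, triplet_family_reads):
        family, reads = triplet_family_reads
        a = family.genome_labels[0]
        sub = [r for r in reads if r.truth.genome_label == a][:60]
        c1 = assemble_cluster(sub, strict_params())
        c2 = assemble_cluster(list(reversed(sub)), strict_params())
        assert [(c.name, c.consensus) for c in c1] == \
            [(c.name, c.consensus) for c in c2]

    def test_members_realign_to_their_contig(self):
        rng = np.random.default_rng(7)
        transcript = rand_seq(rng, 800)
        reads = tile_reads(transcript, 250, 40, qual=35)
        by_id = {r.read_id: r for r in reads}
        params = strict_params()
        (contig,) = assemble_cluster(reads, params)
        for rid, _off, flip in contig.members:
            seq = by_id[rid].sequence
            hit = local_align(seq, contig.consensus)
            rel = hit.score / (params.scoring.match * hit.aligned_length)
            assert rel >= params.min_relative_score

    def test_contig_naming_convention(self):
        rng = np.random.default_rng(8)
        reads = tile_reads(rand_seq(rng, 500), 200, 50)
        contigs = assemble_cluster(reads, strict_params(), cluster_id=7)
        assert [c.name for c in contigs] == [f"C7_{i+1}"
                                            for i in range(len(contigs))]


class TestFilterContigs:
    def _contig(self, length, err):
        return Contig(name="c", consensus="A" * length,
                      per_base_error=np.full(length, err), members=[])

    def test_length_and_error_thresholds(self):
        params = AsmParams()
        assert filter_contigs([self._contig(251, 5e-5)], params)
        assert not filter_contigs([self._contig(250, 5e-5)], params)
        assert not filter_contigs([self._contig(1000, 2e-4)], params)

    def test_boundary_is_strict(self):
        params = AsmParams()
        assert not filter_contigs([self._contig(300, 1e-4)], params)


def test_param_validation():
    with pytest.raises(ValueError):
        AsmParams(min_relative_score=0.0)
    with pytest.raises(ValueError):
        AsmParams(insert_min=10, insert_max=5)
    assert permissive_params().min_relative_score == pytest.approx(0.90)
    assert strict_params().min_relative_score == pytest.approx(0.97)
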
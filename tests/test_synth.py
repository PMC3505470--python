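"""Simulator tests: divergence calibration, read models, determinism."""

import filecmp

import numpy as np
import pytest

from homasm import synth
from homasm.align import AlignParams, local_align, revcomp


def _triplet_config(**kw):
    base = dict(n_families=5, ploidy_mix=(1.0, 0.0, 0.0), seed=0)
    base.update(kw)
    return synth.SimConfig(**base)


class TestGenerateFamilies:
    def test_zero_divergence_limit(self):
        cfg = _triplet_config(homoeolog_identity_mean=100.0,
                              homoeolog_identity_sd=0.0)
        for fam in synth.generate_families(cfg):
            seqs = list(fam.sequences.values())
            assert seqs[0] == seqs[1] == seqs[2]
            assert all(v == 100.0
                       for v in fam.realized_pairwise_identity.values())

    def test_fixed_divergence_mutation_counts(self):
        """97% identity, no indels, 1 kb: ~30 mismatches per copy pair."""
        cfg = _triplet_config(
            n_families=10, homoeolog_identity_mean=97.0,
            homoeolog_identity_sd=0.0, indel_fraction_of_variants=0.0,
            transcript_length_median=1000.0, transcript_length_sigma=0.0,
            transcript_length_min=1000, transcript_length_max=1000, seed=3)
        fams = synth.generate_families(cfg)
        idents = [v for f in fams
                  for v in f.realized_pairwise_identity.values()]
        assert np.mean(idents) == pytest.approx(97.0, abs=0.2)
        # alignment-measured mismatch counts: ~30 differing columns
        diffs = [round((100.0 - v) * 1000 / 100) for v in idents]
        assert 20 <= np.mean(diffs) <= 40

    def test_identity_distribution_matches_configured_peak(self):
        """Realised identities reproduce the 97.2 +/- 1.8 homoeolog peak."""
        cfg = _triplet_config(n_families=500, seed=4)
        fams = synth.generate_families(cfg)
        vals = [v for f in fams
                for v in f.realized_pairwise_identity.values()]
        assert np.mean(vals) == pytest.approx(97.2, abs=0.2)
        assert np.std(vals) == pytest.approx(1.8, abs=0.3)

    def test_stored_identities_recomputable_by_alignment(self):
        cfg = _triplet_config(seed=5)
        for fam in synth.generate_families(cfg):
            for (x, y), stored in fam.realized_pairwise_identity.items():
                hit = local_align(fam.sequences[x], fam.sequences[y])
                assert hit.pct_id == pytest.approx(stored, abs=0.1)

    def test_rejects_out_of_range_identity(self):
        with pytest.raises(ValueError):
            _triplet_config(homoeolog_identity_mean=80.0)
        with pytest.raises(ValueError):
            _triplet_config(homoeolog_identity_mean=101.0)
        with pytest.raises(ValueError):
            _triplet_config(ploidy_mix=(0.5, 0.2, 0.2))


class TestSimulateReads:
    def test_error_free_reads_are_exact_substrings(self):
        cfg = _triplet_config(
            n_families=1, long_read_coverage=10.0, short_read_coverage=10.0,
            long_homopolymer_indel_rate=0.0, short_sub_rate_start=0.0,
            short_sub_rate_end=0.0, expression_sigma=0.0, seed=6)
        fams = synth.generate_families(cfg)
        reads = synth.simulate_reads(fams, cfg)
        assert reads
        lookup = {(f.family_id, lab): f.sequences[lab]
                  for f in fams for lab in f.genome_labels}
        for r in reads:
            src = lookup[(r.truth.family_id, r.truth.genome_label)]
            frag = src[r.truth.start : r.truth.end]
            if r.truth.strand == "-":
                frag = revcomp(frag)
            assert r.sequence == frag

    def test_long_read_length_distribution(self):
        cfg = _triplet_config(
            n_families=30, long_read_coverage=40.0, short_read_coverage=0.0,
            long_read_length_sd=60.0, expression_sigma=0.0, seed=7)
        reads = synth.simulate_reads(synth.generate_families(cfg), cfg)
        lens = [len(r.sequence) for r in reads if r.platform == "long"]
        assert len(lens) > 10_000
        assert np.mean(lens) == pytest.approx(363.2, abs=2.0)

    def test_paired_insert_separation_in_range(self):
        cfg = _triplet_config(
            n_families=3, long_read_coverage=0.0, short_read_coverage=20.0,
            expression_sigma=0.0, seed=8)
        reads = synth.simulate_reads(synth.generate_families(cfg), cfg)
        by_id = {r.read_id: r for r in reads}
        pairs_checked = 0
        for r in reads:
            if r.mate_id and r.read_id < r.mate_id:
                mate = by_id[r.mate_id]
                assert mate.mate_id == r.read_id  # symmetric links
                lo = min(r.truth.start, mate.truth.start)
                hi = max(r.truth.end, mate.truth.end)
                assert 250 <= hi - lo <= 300
                assert {r.truth.strand, mate.truth.strand} == {"+", "-"}
                pairs_checked += 1
        assert pairs_checked > 100

    def test_quality_lengths_match_sequences(self):
        cfg = _triplet_config(n_families=2, seed=9)
        for r in synth.simulate_reads(synth.generate_families(cfg), cfg):
            assert len(r.sequence) == len(r.qualities)

    def test_short_transcript_emits_unpaired_short_reads(self):
        cfg = _triplet_config(
            n_families=1, transcript_length_median=180.0,
            transcript_length_sigma=0.0, transcript_length_min=180,
            transcript_length_max=180, long_read_coverage=0.0,
            short_read_coverage=10.0, expression_sigma=0.0, seed=10)
        reads = synth.simulate_reads(synth.generate_families(cfg), cfg)
        assert reads
        assert all(r.mate_id is None for r in reads)


class TestArtifacts:
    ADAPTER = "AGATCGGAAGAGCACACGT"

    def _reads(self, seed=11):
        cfg = _triplet_config(n_families=1, long_read_coverage=5.0,
                              short_read_coverage=0.0, seed=seed)
        return synth.simulate_reads(synth.generate_families(cfg), cfg)

    def test_zero_rates_leave_reads_unchanged(self):
        reads = self._reads()
        out = synth.inject_artifacts(reads, self.ADAPTER,
                                     synth.ArtifactParams())
        assert [r.sequence for r in out] == [r.sequence for r in reads]
        assert [r.truth for r in out] == [r.truth for r in reads]

    def test_adapter_appended_to_every_read(self):
        reads = self._reads()
        out = synth.inject_artifacts(
            reads, self.ADAPTER, synth.ArtifactParams(adapter_fraction=1.0))
        assert all(r.sequence.endswith(self.ADAPTER) for r in out)

    def test_n_runs_injected(self):
        reads = self._reads()
        out = synth.inject_artifacts(
            reads, self.ADAPTER,
            synth.ArtifactParams(n_run_fraction=1.0, n_run_length=5))
        assert all("N" * 5 in r.sequence for r in out)

    def test_short_adapter_rejected(self):
        with pytest.raises(ValueError):
            synth.inject_artifacts(self._reads(), "ACGT",
                                   synth.ArtifactParams())


def test_outputs_byte_identical_for_same_seed(tmp_path):
    cfg = _triplet_config(n_families=3, long_read_coverage=3.0,
                          short_read_coverage=6.0, seed=12)
    for tag in ("a", "b"):
        fams = synth.generate_families(cfg)
        reads = synth.simulate_reads(fams, cfg)
        synth.write_transcripts_fasta(fams, tmp_path / f"{tag}.fasta")
        synth.write_reads_fastq(reads, str(tmp_path / tag))
        synth.write_truth_tsv(reads, tmp_path / f"{tag}.tsv")
    for suffix in (".fasta", "_1.fastq", "_2.fastq", "_single.fastq", ".tsv"):
        assert filecmp.cmp(tmp_path / f"a{suffix}", tmp_path / f"b{suffix}",
                           shallow=False)
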
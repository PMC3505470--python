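"""Evaluation tests: allocation, chimera detection, statistics, coverage."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from homasm import evalhom
from homasm.align import AlignParams
from homasm.evalhom import (benchmark, coverage_profile, detect_chimera,
                            identity_histogram, iterative_allocation,
                            snp_stats, triplet_lower_bound)

from conftest import mutate_seq, rand_seq


def brute_force_allocation_values(matrix: pd.DataFrame) -> list[float]:
    """Greedy highest-match removal implemented independently."""
    cells = [(matrix.iat[i, j], i, j)
             for i in range(matrix.shape[0]) for j in range(matrix.shape[1])
             if not np.isnan(matrix.iat[i, j])]
    out = []
    used_r, used_c = set(), set()
    for val, i, j in sorted(cells, key=lambda t: -t[0]):
        if i not in used_r and j not in used_c:
            out.append(val)
            used_r.add(i)
            used_c.add(j)
    return out


class TestIterativeAllocation:
    def test_worked_three_by_three_example(self):
        """Printed 3x3 matrix allocates contig2->B, then 1->A, then 3->D."""
        m = pd.DataFrame([[99.0, 98.0, 97.0],
                          [99.0, 100.0, 98.0],
                          [97.0, 97.0, 98.0]],
                         index=["contig1", "contig2", "contig3"],
                         columns=["A", "B", "D"])
        alloc = iterative_allocation(m)
        assert alloc.order == [("contig2", "B", 100.0),
                               ("contig1", "A", 99.0),
                               ("contig3", "D", 98.0)]

    def test_single_cell(self):
        m = pd.DataFrame([[97.5]], index=["c"], columns=["A"])
        assert iterative_allocation(m).order == [("c", "A", 97.5)]

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_independent_greedy_on_small_matrices(self, seed):
        rng = np.random.default_rng(seed)
        nr, nc = int(rng.integers(1, 6)), int(rng.integers(1, 6))
        vals = rng.uniform(90, 100, size=(nr, nc))
        vals[rng.random((nr, nc)) < 0.2] = np.nan
        m = pd.DataFrame(vals, index=[f"c{i}" for i in range(nr)],
                         columns=[f"h{j}" for j in range(nc)])
        if m.isna().all().all():
            return
        alloc = iterative_allocation(m)
        assert [p for _, _, p in alloc.order] == \
            pytest.approx(brute_force_allocation_values(m))
        assert len(alloc.order) <= min(nr, nc)

    def test_stable_under_row_column_permutation(self):
        rng = np.random.default_rng(3)
        m = pd.DataFrame(rng.uniform(90, 100, (4, 3)),
                         index=list("wxyz"), columns=list("ABD"))
        base = iterative_allocation(m).order
        perm = iterative_allocation(
            m.iloc[[2, 0, 3, 1], [1, 2, 0]]).order
        assert base == perm

    def test_ties_broken_lexicographically(self):
        m = pd.DataFrame([[99.0, 99.0], [99.0, 99.0]],
                         index=["c1", "c2"], columns=["A", "B"])
        assert iterative_allocation(m).order == [("c1", "A", 99.0),
                                                 ("c2", "B", 99.0)]


class TestDetectChimera:
    @pytest.fixture()
    def family(self):
        rng = np.random.default_rng(11)
        anc = rand_seq(rng, 900)
        return {"F|A": anc, "F|B": mutate_seq(rng, anc, 0.015),
                "F|D": mutate_seq(rng, anc, 0.015)}

    def test_full_length_copy_is_consistent(self, family):
        assert detect_chimera(family["F|A"], family) == "consistent"

    def test_spliced_contig_flagged_chimeric(self, family):
        splice = family["F|A"][:600] + family["F|B"][600:]
        assert detect_chimera(splice, family) == "chimeric"

    def test_middle_third_only_is_consistent(self, family):
        assert detect_chimera(family["F|A"][300:600], family) == "consistent"

    def test_unrelated_contig_unassigned(self, family):
        rng = np.random.default_rng(12)
        assert detect_chimera(rand_seq(rng, 600), family) == "unassigned"

    def test_requires_two_references(self, family):
        with pytest.raises(ValueError):
            detect_chimera(family["F|A"], {"F|A": family["F|A"]})


class TestBenchmark:
    def test_perfect_assembly_metrics(self):
        rng = np.random.default_rng(13)
        families = {}
        contigs = {}
        for i in range(5):
            anc = rand_seq(rng, 700)
            fam = {lab: mutate_seq(rng, anc, 0.015) for lab in "ABD"}
            for lab, seq in fam.items():
                families[f"F{i}|{lab}"] = seq
                contigs[f"k{i}{lab}"] = seq
        metrics = benchmark(contigs, families)
        assert metrics.frac_identified == 1.0
        assert metrics.frac_chimeric == 0.0
        assert metrics.frac_half_length == 1.0
        assert metrics.n_possible == 15

    def test_missing_copies_lower_identification(self):
        rng = np.random.default_rng(14)
        anc = rand_seq(rng, 700)
        fam = {f"F|{lab}": mutate_seq(rng, anc, 0.015) for lab in "ABD"}
        contigs = {"c1": fam["F|A"]}
        metrics = benchmark(contigs, fam)
        assert metrics.n_identified == 1
        assert metrics.frac_identified == pytest.approx(1 / 3)


class TestIdentityHistogram:
    def test_two_identical_contigs_hit_top_bin(self):
        rng = np.random.default_rng(15)
        s = rand_seq(rng, 500)
        hist, _ = identity_histogram({"a": s, "b": s})
        top = hist[hist["bin_start"] == 100.0]
        assert int(top["count"].iloc[0]) == 1
        assert int(hist["count"].sum()) == 1

    def test_unrelated_sequences_give_no_excess(self):
        rng = np.random.default_rng(16)
        contigs = {f"r{i}": rand_seq(rng, 600) for i in range(12)}
        hist, estimate = identity_histogram(contigs)
        assert hist["excess"].sum() == 0
        assert estimate is None

    def test_recovers_configured_peak_roughly(self):
        rng = np.random.default_rng(17)
        contigs = {}
        for i in range(40):
            anc = rand_seq(rng, 800)
            for lab in "ABD":
                contigs[f"F{i}|{lab}"] = mutate_seq(rng, anc, 0.014)
        hist, peak = identity_histogram(contigs)
        assert peak is not None
        assert peak.mean_identity == pytest.approx(97.2, abs=0.8)
        assert peak.excess_hits == pytest.approx(120, rel=0.1)


class TestSnpStats:
    def test_homoeolog_identity_conversion(self):
        stats = snp_stats(97.2)
        assert stats["per_sequence_snp_freq"] == pytest.approx(1.4)
        assert stats["per_sequence_spacing"] == 71

    def test_intercultivar_identity_conversion(self):
        assert snp_stats(99.67)["pairwise_mismatch_spacing"] == 303

    def test_identical_sequences(self):
        stats = snp_stats(100.0)
        assert stats["per_sequence_snp_freq"] == 0.0
        assert math.isinf(stats["per_sequence_spacing"])

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(identity=st.floats(50.0, 99.99))
    def test_round_trip(self, identity):
        freq = snp_stats(identity)["per_sequence_snp_freq"]
        assert 100.0 - 2.0 * freq == pytest.approx(identity)


class TestTripletLowerBound:
    def test_excess_to_triplets(self):
        bound = triplet_lower_bound(83_600)
        assert bound.raw == pytest.approx(27_866.67, abs=0.01)
        assert bound.rounded_to_hundred == 27_900

    def test_trivial_cases(self):
        assert triplet_lower_bound(0).raw == 0.0
        assert triplet_lower_bound(6).raw == 2.0


class TestCoverageProfile:
    def test_identical_contigs_full_coverage(self):
        rng = np.random.default_rng(18)
        refs = {f"t{i}": rand_seq(rng, 600) for i in range(4)}
        prof = coverage_profile(refs, dict(refs))
        for cutoff in (90.0, 98.0, 99.0):
            assert np.allclose(prof.profiles[cutoff], 1.0)
            assert prof.matched_fraction[cutoff] == 1.0
            assert prof.long_alignment_fraction[cutoff] == 1.0

    def test_half_covered_references(self):
        rng = np.random.default_rng(19)
        refs = {f"t{i}": rand_seq(rng, 600) for i in range(4)}
        halves = {f"h{i}": seq[:300] for i, seq in enumerate(refs.values())}
        prof = coverage_profile(refs, halves, pct_id_cutoffs=(90.0,))
        curve = prof.profiles[90.0].to_numpy()
        assert np.allclose(curve[:48], 1.0)
        assert np.allclose(curve[52:], 0.0)
        assert prof.matched_fraction[90.0] == 1.0
        assert prof.long_alignment_fraction[90.0] == 0.0

    def test_matched_fraction_monotone_in_cutoff(self):
        rng = np.random.default_rng(20)
        refs = {f"t{i}": rand_seq(rng, 600) for i in range(6)}
        contigs = {f"c{i}": mutate_seq(rng, seq, rng.uniform(0, 0.06))
                   for i, seq in enumerate(refs.values())}
        prof = coverage_profile(refs, contigs)
        assert prof.matched_fraction[99.0] <= prof.matched_fraction[98.0] \
            <= prof.matched_fraction[90.0]
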
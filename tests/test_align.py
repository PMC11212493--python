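"""DP alignment core: indices, candidate lists, global/diagonal modes, oracle checks."""

import numpy as np
import pytest

from mgalign.align import (
    ToleranceTooLargeError,
    brute_force_align,
    build_candidate_lists,
    build_mass_difference_index,
    diagonal_align,
    dp_align,
    traceback,
    verify_alignment,
)
from mgalign.mass_graph import (
    EnumerationCaps,
    PMG,
    SMG,
    subpath_mass_universe,
)
from mgalign.tolerance import ToleranceProfile, fixed_tolerance, make_profile
from tests.conftest import random_instance, reduced_and_full_profiles


def toy_profile(smg, delta):
    return make_profile(smg, "fixed", delta)


class TestMassDifferenceIndex:
    def test_window_filter(self):
        pmg = PMG.from_edge_masses([50])
        smg = SMG.from_scaled([50, 100])
        uni = subpath_mass_universe(pmg)
        prof = ToleranceProfile(
            delta=np.array([0, 5, 5]), lo=np.array([0, 5, 5]), hi=np.array([0, 5, 5])
        )
        idx = build_mass_difference_index(smg, uni, prof)
        assert idx.triples() == [(50, 0, 1), (50, 1, 2)]  # (100, y0, y2) omitted

    def test_single_node(self):
        pmg = PMG.from_edge_masses([50])
        smg = SMG.from_scaled([])
        idx = build_mass_difference_index(smg, subpath_mass_universe(pmg), fixed_tolerance(smg, 5))
        assert len(idx) == 0

    def test_edge_of_window_kept(self):
        pmg = PMG.from_edge_masses([50])
        smg = SMG.from_scaled([49])
        prof = ToleranceProfile(
            delta=np.array([0, 1]), lo=np.array([0, 1]), hi=np.array([0, 1])
        )
        idx = build_mass_difference_index(smg, subpath_mass_universe(pmg), prof)
        assert idx.triples() == [(49, 0, 1)]  # |49 - 50| <= 2*delta_max


class TestCandidateLists:
    def test_toy_list(self):
        pmg = PMG.from_edge_masses([50, 50])
        smg = SMG.from_scaled([50, 100])
        uni = subpath_mass_universe(pmg)
        prof = ToleranceProfile(
            delta=np.array([0, 5, 5]), lo=np.array([0, 5, 5]), hi=np.array([0, 5, 5])
        )
        idx = build_mass_difference_index(smg, uni, prof)
        lists = build_candidate_lists(smg, pmg, uni, idx, prof)
        assert lists[(2, 2, 50)] == [1]

    def test_empty_universe(self):
        from mgalign.mass_graph import SubpathUniverse

        e = np.array([], dtype=np.int64)
        uni = SubpathUniverse(mass=e, s=e.copy(), j=e.copy())
        pmg = PMG.from_edge_masses([50])
        smg = SMG.from_scaled([50])
        prof = fixed_tolerance(smg, 5)
        idx = build_mass_difference_index(smg, uni, prof)
        assert build_candidate_lists(smg, pmg, uni, idx, prof) == {}

    def test_pair_in_two_mass_lists(self):
        # one peak pair within the window of two distinct sub-path masses
        pmg = PMG.from_edge_masses([120], red={1: [(130, "r")]})
        smg = SMG.from_scaled([125])
        prof = ToleranceProfile(
            delta=np.array([0, 5]), lo=np.array([0, 5]), hi=np.array([0, 5])
        )
        uni = subpath_mass_universe(pmg)
        idx = build_mass_difference_index(smg, uni, prof)
        lists = build_candidate_lists(smg, pmg, uni, idx, prof)
        assert lists[(1, 1, 120)] == [0]
        assert lists[(1, 1, 130)] == [0]


class TestGlobalAlignment:
    def test_toy_instance(self, toy_pmg, toy_smg):
        smg, prof = toy_profile(toy_smg, 2)
        state = dp_align(toy_pmg, smg, prof)
        assert state.best_score() == 3
        aln = traceback(state, smg, toy_pmg)
        assert list(zip(aln.nodes, aln.peaks, aln.corrections)) == [
            (0, 0, 0),
            (1, 1, -1),
            (2, 2, 1),
        ]
        assert verify_alignment(aln, toy_pmg, smg, prof)

    def test_zero_tolerance_breaks_chain(self, toy_pmg, toy_smg):
        smg, prof = toy_profile(toy_smg, 0)
        assert dp_align(toy_pmg, smg, prof).best_score() == 1

    def test_score_at_least_one(self, toy_pmg):
        smg = SMG.from_scaled([])
        smg, prof = toy_profile(smg, 2)
        state = dp_align(toy_pmg, smg, prof)
        assert state.best_score() == 1
        aln = traceback(state, smg, toy_pmg)
        assert (aln.nodes, aln.peaks, aln.corrections) == ([0], [0], [0])

    def test_tie_breaks_lexicographic(self):
        # identical edges: matching y_1 at x_1 or x_2 scores equally
        pmg = PMG.from_edge_masses([100, 100])
        smg = SMG.from_scaled([100])
        smg, prof = toy_profile(smg, 0)
        aln = traceback(dp_align(pmg, smg, prof), smg, pmg)
        assert aln.nodes == [0, 1] and aln.peaks == [0, 1]

    def test_precondition_refusal(self, toy_smg):
        pmg = PMG.from_edge_masses([100, 150])
        smg, prof = toy_profile(toy_smg, 27)  # 4*27 = 108 > 100
        with pytest.raises(ToleranceTooLargeError, match="delta_max"):
            dp_align(pmg, smg, prof)

    def test_adding_peak_never_hurts(self):
        rng = np.random.default_rng(5)
        for trial in range(20):
            pmg, smg = random_instance(rng, delta=2, with_red=trial % 2 == 0)
            s1, p1 = toy_profile(smg, 2)
            base = dp_align(pmg, s1, p1).best_score()
            extra = int(rng.integers(1, int(smg.masses[-1]) + 100))
            if extra in set(smg.masses.tolist()):
                continue
            smg2 = SMG.from_scaled(smg.masses[1:].tolist() + [extra])
            s2, p2 = toy_profile(smg2, 2)
            assert dp_align(pmg, s2, p2).best_score() >= base


class TestBruteForceOracle:
    def test_toy_equals_dp(self, toy_pmg, toy_smg):
        smg, prof = toy_profile(toy_smg, 2)
        assert brute_force_align(toy_pmg, smg, prof).size == 3

    def test_empty_spectrum(self, toy_pmg):
        smg, prof = toy_profile(SMG.from_scaled([]), 2)
        assert brute_force_align(toy_pmg, smg, prof).size == 1

    def test_guard(self):
        pmg = PMG.from_edge_masses([100] * 11)
        smg, prof = toy_profile(SMG.from_scaled([100]), 2)
        with pytest.raises(ValueError, match="brute-force"):
            brute_force_align(pmg, smg, prof)

    @pytest.mark.parametrize("delta", [0, 2, 5])
    def test_random_instances_match(self, delta):
        rng = np.random.default_rng(100 + delta)
        for trial in range(15):
            pmg, smg0 = random_instance(rng, delta, with_red=trial % 2 == 0)
            (smg, prof), (smg_f, prof_f) = reduced_and_full_profiles(smg0, delta)
            dp = dp_align(pmg, smg, prof).best_score()
            bf = brute_force_align(pmg, smg_f, prof_f).size
            assert dp == bf, (delta, trial)


class TestDiagonalAlignment:
    def test_matches_global_with_wide_band(self, toy_pmg, toy_smg):
        smg, prof = toy_profile(toy_smg, 2)
        aln = diagonal_align(toy_pmg, smg, prof, start_node=0, start_peak=0, band=10**9)
        assert aln.size == 3
        assert aln.nodes == [0, 1, 2]

    def test_zero_band_perfect_spectrum(self, table):
        from mgalign.mass_graph import build_pmg

        pmg = build_pmg("GASPV", [], table)
        prefix = pmg.black_prefix()
        smg = SMG.from_scaled(prefix[1:].tolist())
        smg, prof = toy_profile(smg, 0)
        aln = diagonal_align(pmg, smg, prof, start_node=0, start_peak=0, band=0)
        assert aln.size == pmg.n + 1
        assert verify_alignment(aln, pmg, smg, prof)

    def test_start_at_end_gives_singleton(self, toy_pmg, toy_smg):
        smg, prof = toy_profile(toy_smg, 2)
        aln = diagonal_align(toy_pmg, smg, prof, start_node=toy_pmg.n, start_peak=smg.m)
        assert aln.size == 1
        assert aln.nodes == [toy_pmg.n] and aln.peaks == [smg.m]

    def test_out_of_range_start(self, toy_pmg, toy_smg):
        smg, prof = toy_profile(toy_smg, 2)
        with pytest.raises(ValueError, match="start_node"):
            diagonal_align(toy_pmg, smg, prof, start_node=99, start_peak=0)


class TestVerifyAlignment:
    def test_traceback_output_verifies(self, toy_pmg, toy_smg):
        smg, prof = toy_profile(toy_smg, 2)
        aln = traceback(dp_align(toy_pmg, smg, prof), smg, toy_pmg)
        assert verify_alignment(aln, toy_pmg, smg, prof)

    def test_perturbed_correction_fails(self, toy_pmg, toy_smg):
        smg, prof = toy_profile(toy_smg, 2)
        aln = traceback(dp_align(toy_pmg, smg, prof), smg, toy_pmg)
        aln.corrections[1] += 1
        res = verify_alignment(aln, toy_pmg, smg, prof)
        assert not res and "step 1" in res.message

    def test_empty_alignment_vacuous(self, toy_pmg, toy_smg):
        from mgalign.align import Alignment

        smg, prof = toy_profile(toy_smg, 2)
        assert verify_alignment(Alignment([], [], [], []), toy_pmg, smg, prof)


def test_corrected_masses_exact_for_all_pairs():
    """After correction, the mass between EVERY pair of matched peaks equals
    the theoretical sub-path mass chain exactly (transitive summation)."""
    rng = np.random.default_rng(42)
    for trial in range(10):
        pmg, smg0 = random_instance(rng, delta=5, with_red=True)
        smg, prof = toy_profile(smg0, 5)
        aln = traceback(dp_align(pmg, smg, prof), smg, pmg)
        assert verify_alignment(aln, pmg, smg, prof)
        corr = aln.corrected_masses(smg)
        theo = np.concatenate([[0], np.cumsum(aln.step_masses)])
        for q in range(aln.size):
            for qp in range(q + 1, aln.size):
                assert corr[qp] - corr[q] == theo[qp] - theo[q]
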
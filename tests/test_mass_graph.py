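"""Proteoform/spectrum graph construction and sub-path mass enumeration."""

import itertools
import logging

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mgalign.masses import ModificationRule, discretize_mass
from mgalign.mass_graph import (
    EnumerationCaps,
    PMG,
    Provenance,
    SMG,
    build_pmg,
    build_smg,
    path_masses,
    subpath_mass_universe,
)
from tests.conftest import random_instance


def brute_path_masses(pmg: PMG, s: int, j: int, max_red: int) -> set:
    """Independent oracle: exhaustive product over parallel edges."""
    choices = [pmg.edges_at(p) for p in range(s + 1, j + 1)]
    out = set()
    for combo in itertools.product(*choices):
        if sum(1 for e in combo if e[1] == "red") <= max_red:
            out.add(sum(e[0] for e in combo))
    return out


class TestBuildPMG:
    def test_glycine_dipeptide(self, table):
        pmg = build_pmg("GG", [], table)
        assert pmg.n == 2
        assert pmg.black.tolist() == [15642, 15642]
        assert pmg.red == {}

    def test_mutation_red_edge(self, table):
        rule = ModificationRule("K_to_C", "K", "replace", table["C"])
        pmg = build_pmg("K", [rule], table)
        assert pmg.n == 1
        assert pmg.black.tolist() == [discretize_mass(table["K"])]
        assert pmg.red == {1: [(discretize_mass(table["C"]), "K_to_C")]}

    def test_no_rules(self, table):
        pmg = build_pmg("A", [], table)
        assert pmg.n == 1 and pmg.red == {}

    def test_unknown_residue(self, table):
        with pytest.raises(ValueError, match="unknown residue"):
            build_pmg("AXZ", [], table)

    def test_absent_target_warns(self, table, caplog):
        rule = ModificationRule("K_to_C", "K", "replace", table["C"])
        with caplog.at_level(logging.WARNING):
            pmg = build_pmg("GG", [rule], table)
        assert pmg.red == {}
        assert "K_to_C" in caplog.text


class TestBuildSMG:
    def test_complementary(self):
        smg = build_smg([100.0], precursor_mass=1000.0, add_complementary=True)
        assert smg.masses.tolist() == [0, 27433, 246901]
        assert smg.provenance[2] is Provenance.COMPLEMENTARY

    def test_satellites(self):
        smg = build_smg([6000.0], add_complementary=False)
        assert smg.m == 3
        diffs = np.diff(smg.masses[1:])
        assert diffs.tolist() == [275, 275]  # about 274.335215 scaled units apart
        assert smg.provenance[1] is Provenance.SATELLITE
        assert smg.tolerance_class[1] is Provenance.ORIGINAL

    def test_empty_spectrum(self):
        smg = build_smg([], precursor_mass=1000.0)
        assert smg.masses.tolist() == [0]

    def test_negative_complementary_skipped(self, caplog):
        with caplog.at_level(logging.WARNING):
            smg = build_smg([150.0], precursor_mass=100.0, add_complementary=True)
        # only y_0 and the original peak survive
        assert smg.masses.tolist() == [0, discretize_mass(150.0)]
        assert "negative complementary" in caplog.text

    def test_duplicates_merged(self):
        smg = build_smg([100.0, 100.0], precursor_mass=200.0, add_complementary=True)
        # original 100 and complementary 200-100 coincide after discretization
        assert smg.masses.tolist() == [0, 27433]
        assert smg.provenance[1] is Provenance.ORIGINAL  # earliest generation wins

    @settings(max_examples=50, derandomize=True)
    @given(st.permutations([100.0, 355.5, 901.25, 5500.0, 42.0]))
    def test_order_independence(self, peaks):
        smg = build_smg(list(peaks), precursor_mass=6000.0, add_complementary=True)
        ref = build_smg([100.0, 355.5, 901.25, 5500.0, 42.0], 6000.0, True)
        assert smg.masses.tolist() == ref.masses.tolist()
        assert smg.masses[0] == 0
        assert np.all(np.diff(smg.masses) > 0)


class TestPathMasses:
    def test_glycine_pair(self, table):
        pmg = build_pmg("GG", [], table)
        assert path_masses(pmg, 0, 2).masses == (31284,)

    def test_parallel_edges(self, table):
        rule = ModificationRule("K_to_C", "K", "replace", table["C"])
        pmg = build_pmg("K", [rule], table)
        got = path_masses(pmg, 0, 1).masses
        assert got == tuple(sorted([discretize_mass(table["K"]), discretize_mass(table["C"])]))

    def test_single_black_position(self, table):
        pmg = build_pmg("AG", [], table)
        assert path_masses(pmg, 1, 2).masses == (15642,)

    def test_domain_errors(self, table):
        pmg = build_pmg("AG", [], table)
        with pytest.raises(ValueError):
            path_masses(pmg, 1, 1)
        with pytest.raises(ValueError):
            path_masses(pmg, 0, 2, EnumerationCaps(max_gap_residues=1))

    def test_red_edge_cap(self):
        pmg = PMG.from_edge_masses(
            [100, 100], red={1: [(130, "r1")], 2: [(130, "r2")]}
        )
        capped = path_masses(pmg, 0, 2, EnumerationCaps(max_red_edges=1)).masses
        assert capped == (200, 230)
        full = path_masses(pmg, 0, 2, EnumerationCaps(max_red_edges=2)).masses
        assert full == (200, 230, 260)

    @pytest.mark.parametrize("seed", range(12))
    def test_matches_exhaustive_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        pmg, _ = random_instance(rng, delta=0, with_red=seed % 2 == 0)
        caps = EnumerationCaps(max_gap_residues=10, max_red_edges=2)
        for s in range(pmg.n):
            for j in range(s + 1, pmg.n + 1):
                got = set(path_masses(pmg, s, j, caps).masses)
                assert got == brute_path_masses(pmg, s, j, 2), (s, j)


class TestSubpathUniverse:
    def test_glycine_universe(self, table):
        pmg = build_pmg("GG", [], table)
        uni = subpath_mass_universe(pmg, EnumerationCaps(max_gap_residues=2))
        assert uni.mass.tolist() == [15642, 15642, 31284]
        assert set(uni.entries()) == {(15642, 0, 1), (15642, 1, 2), (31284, 0, 2)}

    def test_gap_cap_excludes_long_subpaths(self, table):
        pmg = build_pmg("GG", [], table)
        uni = subpath_mass_universe(pmg, EnumerationCaps(max_gap_residues=1))
        assert set(uni.entries()) == {(15642, 0, 1), (15642, 1, 2)}

    def test_single_residue(self, table):
        pmg = build_pmg("W", [], table)
        uni = subpath_mass_universe(pmg)
        assert uni.L == 1

    def test_sorted_nondecreasing(self):
        rng = np.random.default_rng(3)
        pmg, _ = random_instance(rng, delta=0, with_red=True)
        uni = subpath_mass_universe(pmg)
        assert np.all(np.diff(uni.mass) >= 0)


def test_black_prefix_total_close_to_sequence_mass(table):
    rng = np.random.default_rng(11)
    for _ in range(5):
        seq = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=30))
        pmg = build_pmg(seq, [], table)
        total_da = sum(table[aa] for aa in seq)
        # per-residue floors lose at most one unit each
        assert 0 <= discretize_mass(total_da) - int(pmg.black.sum()) <= len(seq)
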
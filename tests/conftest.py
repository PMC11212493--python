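"""Shared fixtures: residue table, toy instances, random instance factory."""

from __future__ import annotations

import numpy as np
import pytest

from mgalign.masses import ResidueMassTable
from mgalign.mass_graph import PMG, SMG, build_pmg
from mgalign.simdata import AA_ALPHABET
from mgalign.tolerance import (
    disjointify_ranges,
    fixed_tolerance,
    prune_dominated_peaks,
)


@pytest.fixture(scope="session")
def table() -> ResidueMassTable:
    return ResidueMassTable()


@pytest.fixture()
def toy_pmg() -> PMG:
    """Two synthetic edges with scaled masses 100 and 150 (prefixes 100, 250)."""
    return PMG.from_edge_masses([100, 150])


@pytest.fixture()
def toy_smg() -> SMG:
    """Peaks at scaled 101 and 249: one unit off each true prefix."""
    return SMG.from_scaled([101, 249])


def random_instance(rng: np.random.Generator, delta: int, with_red: bool):
    """A small random PMG/SMG pair for oracle comparisons.

    The spectrum mixes perturbed prefix masses of a random proteoform with
    uniform decoys, capped at 8 peaks, so chains of varying length exist.
    """
    from mgalign.masses import ModificationRule

    length = int(rng.integers(3, 9))
    seq = "".join(rng.choice(list(AA_ALPHABET), size=length))
    rules = []
    if with_red:
        targets = sorted(set(seq))
        for t in targets[: int(rng.integers(1, 3))]:
            shift = float(rng.uniform(10.0, 90.0))
            rules.append(ModificationRule(f"shift_{t}", t, "shift", shift))
    pmg = build_pmg(seq, rules)

    # spell one proteoform and take its scaled prefix masses
    reds_left = 2
    prefix = [0]
    for p in range(1, length + 1):
        edges = pmg.edges_at(p)
        reds = [e for e in edges if e[1] == "red"]
        if reds and reds_left > 0 and rng.random() < 0.35:
            mass = reds[int(rng.integers(len(reds)))][0]
            reds_left -= 1
        else:
            mass = edges[0][0]
        prefix.append(prefix[-1] + mass)
    total = prefix[-1]
    peaks = set()
    for p in range(1, length + 1):
        if rng.random() < 0.7:
            err = int(rng.integers(-delta, delta + 1)) if delta else 0
            val = prefix[p] + err
            if 0 < val:
                peaks.add(val)
    for _ in range(int(rng.integers(0, 3))):
        peaks.add(int(rng.integers(1, total + 1)))
    peaks = sorted(peaks)[:8]
    smg = SMG.from_scaled(peaks)
    return pmg, smg


def reduced_and_full_profiles(smg: SMG, delta: int):
    """(pruned SMG, disjointified profile) plus the untouched full-range pair."""
    full = fixed_tolerance(smg, delta)
    smg2, prof2 = prune_dominated_peaks(smg, full)
    reduced = disjointify_ranges(smg2, prof2)
    return (smg2, reduced), (smg, full)
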
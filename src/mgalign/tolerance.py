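"""Per-peak error tolerances, dominated-peak pruning, and range disjointification.

Each peak y_i gets a symmetric tolerance delta_i plus asymmetric bounds
(delta_i^-, delta_i^+) delimiting the closed interval of admissible corrected
positions [m_i - delta_i^-, m_i + delta_i^+].  After pruning and
disjointification these intervals are pairwise disjoint while covering the
same set of integer positions, so the alignment DP examines every candidate
corrected position exactly once.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple

import numpy as np

from .mass_graph import SMG, Provenance

#: Default fixed per-peak tolerance in scaled units.
DEFAULT_DELTA = 27

#: Default relative term of the peak-dependent tolerance (parts per million).
DEFAULT_PPM = 15.0


@dataclass
class ToleranceProfile:
    """Symmetric tolerances and asymmetric corrected-position bounds per node.

    ``delta[i]`` is the symmetric tolerance delta_i; ``lo[i]`` and ``hi[i]``
    are delta_i^- and delta_i^+.  Node y_0 always has all three equal to 0:
    its mass is exact by construction.
    """

    delta: np.ndarray  # int64
    lo: np.ndarray  # int64, >= 0
    hi: np.ndarray  # int64, >= 0

    def __post_init__(self) -> None:
        self.delta = np.asarray(self.delta, dtype=np.int64)
        self.lo = np.asarray(self.lo, dtype=np.int64)
        self.hi = np.asarray(self.hi, dtype=np.int64)
        if not (len(self.delta) == len(self.lo) == len(self.hi)):
            raise ValueError("delta/lo/hi must have equal length")
        if self.delta[0] != 0 or self.lo[0] != 0 or self.hi[0] != 0:
            raise ValueError("node y_0 must have zero tolerance")
        if np.any(self.lo < 0) or np.any(self.hi < 0):
            raise ValueError("bounds must be non-negative")
        if np.any(self.lo > self.delta) or np.any(self.hi > self.delta):
            raise ValueError("bounds may not exceed the symmetric tolerance")

    @property
    def delta_max(self) -> int:
        return int(self.delta.max())

    @property
    def q(self) -> int:
        """Largest interval size delta_i^- + delta_i^+ over all peaks."""
        return int((self.lo + self.hi).max())

    def intervals(self, smg: SMG) -> np.ndarray:
        """(m+1, 2) array of closed corrected-position intervals."""
        return np.stack([smg.masses - self.lo, smg.masses + self.hi], axis=1)

    def subset(self, keep) -> "ToleranceProfile":
        keep = list(keep)
        return ToleranceProfile(
            delta=self.delta[keep], lo=self.lo[keep], hi=self.hi[keep]
        )


def _clamp_lower(smg: SMG, lo: np.ndarray) -> np.ndarray:
    # Corrected positions are masses: keep them >= 1 for real peaks so that
    # nothing collides with y_0's fixed position 0.
    lo = lo.copy()
    if len(lo) > 1:
        lo[1:] = np.minimum(lo[1:], np.maximum(smg.masses[1:] - 1, 0))
    return lo


def fixed_tolerance(smg: SMG, delta: int = DEFAULT_DELTA) -> ToleranceProfile:
    """Constant tolerance ``delta`` (scaled units) for every real peak."""
    if delta < 0:
        raise ValueError("delta must be non-negative")
    d = np.full(smg.m + 1, delta, dtype=np.int64)
    d[0] = 0
    lo = _clamp_lower(smg, d.copy())
    return ToleranceProfile(delta=d, lo=lo, hi=d.copy())


def peak_dependent_tolerance(
    smg: SMG, ppm: float = DEFAULT_PPM, base: int = DEFAULT_DELTA
) -> ToleranceProfile:
    """Mass-dependent tolerance: base + round(ppm * mass / 1e6) scaled units.

    Original-class peaks use their own mass; complementary-class peaks use
    (m_i + M) where M is the scaled precursor mass, since their error budget
    reflects the peak they were derived from.  Satellite peaks follow the
    class of their source peak.
    """
    if ppm < 0:
        raise ValueError("ppm must be non-negative")
    d = np.zeros(smg.m + 1, dtype=np.int64)
    needs_precursor = any(
        c is Provenance.COMPLEMENTARY for c in smg.tolerance_class[1:]
    )
    if needs_precursor and smg.precursor_mass is None:
        raise ValueError(
            "peak-dependent tolerance with complementary peaks requires a precursor mass"
        )
    for i in range(1, smg.m + 1):
        mass = int(smg.masses[i])
        if smg.tolerance_class[i] is Provenance.COMPLEMENTARY:
            mass += int(smg.precursor_mass)
        d[i] = base + round(ppm * mass / 1e6)
    lo = _clamp_lower(smg, d.copy())
    return ToleranceProfile(delta=d, lo=lo, hi=d.copy())


def prune_dominated_peaks(
    smg: SMG, prof: ToleranceProfile
) -> Tuple[SMG, ToleranceProfile]:
    """Delete peaks whose interval is contained in a neighbour's interval.

    Containment of consecutive intervals is iterated to a fixpoint, which
    subsumes chains of dominated peaks.  On mutual containment (identical
    intervals) the later, larger-mass peak survives.  Node y_0 is never
    removed.
    """
    keep = list(range(smg.m + 1))
    a = (smg.masses - prof.lo).tolist()
    b = (smg.masses + prof.hi).tolist()
    changed = True
    while changed:
        changed = False
        t = 1
        while t < len(keep):
            i, jn = keep[t - 1], keep[t]
            if a[jn] <= a[i] and b[i] <= b[jn] and i != 0:
                del keep[t - 1]  # earlier peak dominated (ties keep the later)
                changed = True
            elif a[i] <= a[jn] and b[jn] <= b[i]:
                del keep[t]
                changed = True
            else:
                t += 1
    return smg.subset(keep), prof.subset(keep)


def disjointify_ranges(smg: SMG, prof: ToleranceProfile) -> ToleranceProfile:
    """Shrink overlapping consecutive intervals to disjoint ones.

    Overlapped integer positions are assigned to the nearer peak (midpoint
    split, ties to the earlier peak), preserving the union of covered
    positions exactly.  Dominated peaks must have been pruned first.
    """
    masses = smg.masses
    lo = prof.lo.copy()
    hi = prof.hi.copy()
    orig_a = (masses - lo).tolist()
    orig_b = (masses + hi).tolist()
    for i in range(smg.m):
        b_i = int(masses[i] + hi[i])
        a_n = int(masses[i + 1] - lo[i + 1])
        if a_n > b_i:
            continue  # already disjoint
        contained = (orig_a[i + 1] <= orig_a[i] and orig_b[i] <= orig_b[i + 1]) or (
            orig_a[i] <= orig_a[i + 1] and orig_b[i + 1] <= orig_b[i]
        )
        if contained and i != 0:
            raise ValueError(
                "contained interval encountered; run prune_dominated_peaks first"
            )
        if i == 0:
            # y_0 keeps its exact position {0}; the neighbour starts at 1
            lo[1] = min(lo[1], masses[1] - 1)
            continue
        c = (int(masses[i]) + int(masses[i + 1])) // 2
        hi[i] = c - int(masses[i])
        lo[i + 1] = int(masses[i + 1]) - c - 1
    return ToleranceProfile(delta=prof.delta.copy(), lo=lo, hi=hi)


def make_profile(
    smg: SMG,
    mode: str = "fixed",
    delta: int = DEFAULT_DELTA,
    ppm: float = DEFAULT_PPM,
) -> Tuple[SMG, ToleranceProfile]:
    """Convenience pipeline: tolerance -> prune dominated -> disjointify."""
    if mode == "fixed":
        prof = fixed_tolerance(smg, delta)
    elif mode in ("peak_dependent", "ppm"):
        prof = peak_dependent_tolerance(smg, ppm=ppm, base=delta)
    else:
        raise ValueError(f"unknown tolerance mode {mode!r}")
    smg2, prof2 = prune_dominated_peaks(smg, prof)
    return smg2, disjointify_ranges(smg2, prof2)
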
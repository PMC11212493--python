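"""Error-correction alignment of a spectrum mass graph against a proteoform mass graph.

An alignment is a sequence of triples (x_j, y_i, k): peak y_i, corrected by an
integer k within its tolerance bounds, is matched to bond node x_j, and every
consecutive corrected mass difference equals some sub-path mass of the
proteoform graph *exactly*.  The dynamic program maximizes the number of
triples; because corrections are anchored per peak rather than per edge,
errors cannot accumulate along the alignment.

The table T(i, j, k) is filled through transition tuples obtained by merging
the sorted sub-path mass universe D with the sorted peak-pair mass-difference
index M: a tuple (i', j', i, j, shift) encodes, for a whole contiguous band of
corrections k, the move T(i, j, k) >= T(i', j', k + shift) + 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np

from .mass_graph import (
    DEFAULT_CAPS,
    EnumerationCaps,
    PMG,
    SMG,
    SubpathUniverse,
    path_masses,
    subpath_mass_universe,
)
from .tolerance import ToleranceProfile

_NEG = -(1 << 30)


class ToleranceTooLargeError(ValueError):
    """The corrected-position uniqueness precondition m_small > 4*delta_max failed.

    When the smallest (modified or unmodified) residue edge mass does not
    exceed four times the largest per-peak tolerance, distinct peaks may claim
    the same corrected position with differing alignment values, and the
    overlap-deleting speedup is no longer sound; the aligner refuses to run.
    """


def check_precondition(pmg: PMG, prof: ToleranceProfile) -> None:
    m_small = pmg.min_edge_mass
    if m_small <= 4 * prof.delta_max:
        raise ToleranceTooLargeError(
            f"corrected-position uniqueness precondition violated: smallest "
            f"edge mass {m_small} must exceed 4*delta_max = {4 * prof.delta_max}; "
            f"reduce the error tolerance"
        )


@dataclass
class MassDifferenceIndex:
    """Sorted peak-pair mass differences (m, i', i) with i' < i.

    Pairs whose difference is farther than 2*delta_max from every sub-path
    mass in D can never satisfy the correction condition and are omitted.
    """

    diff: np.ndarray  # int64, sorted nondecreasing
    src: np.ndarray  # int64 peak index i'
    dst: np.ndarray  # int64 peak index i

    def __len__(self) -> int:
        return len(self.diff)

    def triples(self) -> List[Tuple[int, int, int]]:
        return [
            (int(d), int(s), int(t)) for d, s, t in zip(self.diff, self.src, self.dst)
        ]


def build_mass_difference_index(
    smg: SMG, universe: SubpathUniverse, prof: ToleranceProfile
) -> MassDifferenceIndex:
    """Enumerate peak pairs whose difference is within 2*delta_max of some D mass."""
    masses = smg.masses
    m1 = len(masses)
    empty = np.array([], dtype=np.int64)
    if universe.L == 0 or m1 < 2:
        return MassDifferenceIndex(diff=empty, src=empty.copy(), dst=empty.copy())
    w = 2 * prof.delta_max
    dmax = int(universe.mass[-1]) + w
    dmin = max(int(universe.mass[0]) - w, 1)
    lo_i = np.searchsorted(masses, masses - dmax, side="left")
    hi_i = np.searchsorted(masses, masses - dmin, side="right")
    hi_i = np.minimum(hi_i, np.arange(m1))
    counts = np.maximum(hi_i - lo_i, 0)
    total = int(counts.sum())
    if total == 0:
        return MassDifferenceIndex(diff=empty, src=empty.copy(), dst=empty.copy())
    dst = np.repeat(np.arange(m1), counts)
    offs = np.arange(total) - np.repeat(np.cumsum(counts) - counts, counts)
    src = np.repeat(lo_i, counts) + offs
    diff = masses[dst] - masses[src]
    # exact filter: keep pairs with a D mass within w
    pos = np.searchsorted(universe.mass, diff)
    right = universe.mass[np.minimum(pos, universe.L - 1)]
    left = universe.mass[np.maximum(pos - 1, 0)]
    keep = (np.abs(right - diff) <= w) | (np.abs(diff - left) <= w)
    diff, src, dst = diff[keep], src[keep], dst[keep]
    order = np.argsort(diff, kind="stable")
    return MassDifferenceIndex(diff=diff[order], src=src[order], dst=dst[order])


@dataclass
class _Transitions:
    """Flat arrays of DP transition tuples, sorted by target node j."""

    i1: np.ndarray
    j1: np.ndarray
    i2: np.ndarray
    j2: np.ndarray
    shift: np.ndarray  # k' = k + shift
    klo: np.ndarray  # inclusive band of valid k at the target
    khi: np.ndarray
    mu: np.ndarray  # the sub-path mass consumed by the move

    def __len__(self) -> int:
        return len(self.i1)


def _build_transitions(
    smg: SMG,
    universe: SubpathUniverse,
    index: MassDifferenceIndex,
    prof: ToleranceProfile,
) -> _Transitions:
    empty = np.array([], dtype=np.int64)
    if len(index) == 0 or universe.L == 0:
        e = empty
        return _Transitions(e, e.copy(), e.copy(), e.copy(), e.copy(), e.copy(), e.copy(), e.copy())
    w = 2 * prof.delta_max
    dm = universe.mass
    lo_idx = np.searchsorted(index.diff, dm - w, side="left")
    hi_idx = np.searchsorted(index.diff, dm + w, side="right")
    counts = hi_idx - lo_idx
    total = int(counts.sum())
    if total == 0:
        e = empty
        return _Transitions(e, e.copy(), e.copy(), e.copy(), e.copy(), e.copy(), e.copy(), e.copy())
    t_idx = np.repeat(np.arange(universe.L), counts)
    offs = np.arange(total) - np.repeat(np.cumsum(counts) - counts, counts)
    p_idx = np.repeat(lo_idx, counts) + offs
    i1 = index.src[p_idx]
    i2 = index.dst[p_idx]
    j1 = universe.s[t_idx]
    j2 = universe.j[t_idx]
    mu = dm[t_idx]
    shift = index.diff[p_idx] - mu
    klo = np.maximum(-prof.lo[i2], -prof.lo[i1] - shift)
    khi = np.minimum(prof.hi[i2], prof.hi[i1] - shift)
    keep = klo <= khi
    order = np.argsort(j2[keep], kind="stable")

    def pick(a: np.ndarray) -> np.ndarray:
        return a[keep][order]

    return _Transitions(
        i1=pick(i1), j1=pick(j1), i2=pick(i2), j2=pick(j2),
        shift=pick(shift), klo=pick(klo), khi=pick(khi), mu=pick(mu),
    )


def build_candidate_lists(
    smg: SMG,
    pmg: PMG,
    universe: SubpathUniverse,
    index: MassDifferenceIndex,
    prof: ToleranceProfile,
) -> Dict[Tuple[int, int, int], List[int]]:
    """C(i, j): for each (target peak i, node j, sub-path mass m), the sorted
    list of predecessor peaks i' admissible for some correction in the target
    peak's reduced range."""
    trans = _build_transitions(smg, universe, index, prof)
    lists: Dict[Tuple[int, int, int], set] = {}
    for t in range(len(trans)):
        key = (int(trans.i2[t]), int(trans.j2[t]), int(trans.mu[t]))
        lists.setdefault(key, set()).add(int(trans.i1[t]))
    return {k: sorted(v) for k, v in lists.items()}


@dataclass
class DPState:
    """Filled alignment table plus the transitions that produced it.

    ``table`` maps (peak i, node j) to an int array over k in
    [-delta_i^-, delta_i^+] (offset by delta_i^-).  Cells never touched keep
    the implicit initial value 1 (every admissible triple is a size-1
    alignment) unless the run was seeded, in which case unreachable cells are
    effectively minus infinity.
    """

    table: Dict[Tuple[int, int], np.ndarray]
    trans: _Transitions
    prof: ToleranceProfile
    seeded: bool = False
    seed_cells: Optional[Dict[Tuple[int, int], np.ndarray]] = None
    _heads: Optional[Dict[Tuple[int, int], List[int]]] = field(default=None, repr=False)

    def value(self, i: int, j: int, k: int) -> int:
        arr = self.table.get((i, j))
        if arr is None:
            if self.seeded:
                return _NEG
            return 1 if -self.prof.lo[i] <= k <= self.prof.hi[i] else _NEG
        if not -self.prof.lo[i] <= k <= self.prof.hi[i]:
            return _NEG
        return int(arr[k + self.prof.lo[i]])

    def best_cell(self) -> Tuple[int, Tuple[int, int, int]]:
        """Maximum table value and the lexicographically smallest argmax (i, j, k)."""
        best_v = _NEG
        best = None
        for (i, j), arr in self.table.items():
            v = int(arr.max())
            if v < 1 or v < best_v:
                continue
            k = int(np.flatnonzero(arr == v)[0]) - int(self.prof.lo[i])
            if v > best_v or (i, j, k) < best:
                best_v, best = v, (i, j, k)
        if best is None or best_v < 1:
            if self.seeded:
                raise ValueError("seeded DP has no admissible cell")
            return 1, (0, 0, 0)
        if not self.seeded and best_v == 1:
            return 1, (0, 0, 0)
        return best_v, best

    def best_score(self) -> int:
        return self.best_cell()[0]

    def heads(self) -> Dict[Tuple[int, int], List[int]]:
        if self._heads is None:
            heads: Dict[Tuple[int, int], List[int]] = {}
            i2 = self.trans.i2.tolist()
            j2 = self.trans.j2.tolist()
            for t in range(len(self.trans)):
                heads.setdefault((i2[t], j2[t]), []).append(t)
            self._heads = heads
        return self._heads


@dataclass
class Alignment:
    """A sequence of r triples (node j_q, peak i_q, correction k_q).

    ``step_masses[q-1]`` is the sub-path mass consumed between triples q-1 and
    q, so corrected mass differences reproduce the matched proteoform exactly.
    """

    nodes: List[int]
    peaks: List[int]
    corrections: List[int]
    step_masses: List[int]

    @property
    def size(self) -> int:
        return len(self.nodes)

    def corrected_masses(self, smg: SMG) -> List[int]:
        return [int(smg.masses[i]) + k for i, k in zip(self.peaks, self.corrections)]

    def spans(self) -> List[int]:
        """Residues covered by each consecutive sub-path."""
        return [b - a for a, b in zip(self.nodes, self.nodes[1:])]


def _run_engine(
    trans: _Transitions,
    prof: ToleranceProfile,
    seeds: Optional[Dict[Tuple[int, int], np.ndarray]] = None,
) -> Dict[Tuple[int, int], np.ndarray]:
    lo = prof.lo
    table: Dict[Tuple[int, int], np.ndarray] = {}
    seeded = seeds is not None
    if seeded:
        for key, arr in seeds.items():
            table[key] = arr.copy()
    i1 = trans.i1.tolist()
    j1 = trans.j1.tolist()
    i2 = trans.i2.tolist()
    j2 = trans.j2.tolist()
    shift = trans.shift.tolist()
    klo = trans.klo.tolist()
    khi = trans.khi.tolist()
    lo_l = lo.tolist()
    hi_l = prof.hi.tolist()
    for t in range(len(i1)):
        src = table.get((i1[t], j1[t]))
        if src is None and seeded:
            continue
        key = (i2[t], j2[t])
        dst = table.get(key)
        if dst is None:
            size = lo_l[i2[t]] + hi_l[i2[t]] + 1
            dst = np.full(size, _NEG if seeded else 1, dtype=np.int64)
            table[key] = dst
        a = klo[t] + lo_l[i2[t]]
        b = khi[t] + lo_l[i2[t]] + 1
        if src is None:
            seg = dst[a:b]
            np.maximum(seg, 2, out=seg)
        else:
            sa = klo[t] + shift[t] + lo_l[i1[t]]
            seg = dst[a:b]
            np.maximum(seg, src[sa : sa + (b - a)] + 1, out=seg)
    return table


def dp_align(
    pmg: PMG,
    smg: SMG,
    prof: ToleranceProfile,
    caps: EnumerationCaps = DEFAULT_CAPS,
    universe: Optional[SubpathUniverse] = None,
) -> DPState:
    """Fill the global error-correction alignment table.

    Both endpoints are free: the optimum is the maximum over all cells.  The
    corrected-position uniqueness precondition is checked first and a
    :class:`ToleranceTooLargeError` is raised if it fails.
    """
    check_precondition(pmg, prof)
    if universe is None:
        universe = subpath_mass_universe(pmg, caps)
    index = build_mass_difference_index(smg, universe, prof)
    trans = _build_transitions(smg, universe, index, prof)
    table = _run_engine(trans, prof)
    return DPState(table=table, trans=trans, prof=prof)


def traceback(state: DPState, smg: SMG, pmg: PMG) -> Alignment:
    """Recover one optimal alignment; ties resolve to the lexicographically
    smallest (i, j, k) at every choice point."""
    best_v, (i, j, k) = state.best_cell()
    prof = state.prof
    heads = state.heads()
    trans = state.trans
    nodes = [j]
    peaks = [i]
    corrections = [k]
    step_masses: List[int] = []
    v = best_v
    while v > 1:
        cands: List[Tuple[int, int, int, int]] = []
        for t in heads.get((i, j), ()):  # transitions into (i, j)
            if not trans.klo[t] <= k <= trans.khi[t]:
                continue
            kp = k + int(trans.shift[t])
            pv = state.value(int(trans.i1[t]), int(trans.j1[t]), kp)
            if pv == v - 1:
                cands.append((int(trans.i1[t]), int(trans.j1[t]), kp, int(trans.mu[t])))
        if not cands:
            break  # v == 1 cells have no predecessor by definition
        i, j, k, mu = min(cands)
        nodes.append(j)
        peaks.append(i)
        corrections.append(k)
        step_masses.append(mu)
        v -= 1
    nodes.reverse()
    peaks.reverse()
    corrections.reverse()
    step_masses.reverse()
    return Alignment(nodes=nodes, peaks=peaks, corrections=corrections, step_masses=step_masses)


def align_and_trace(
    pmg: PMG,
    smg: SMG,
    prof: ToleranceProfile,
    caps: EnumerationCaps = DEFAULT_CAPS,
    universe: Optional[SubpathUniverse] = None,
) -> Alignment:
    """Convenience wrapper: global DP plus traceback."""
    state = dp_align(pmg, smg, prof, caps, universe)
    return traceback(state, smg, pmg)


def diagonal_align(
    pmg: PMG,
    smg: SMG,
    prof: ToleranceProfile,
    start_node: int,
    start_peak: int,
    band: Optional[int] = None,
    caps: EnumerationCaps = DEFAULT_CAPS,
    universe: Optional[SubpathUniverse] = None,
) -> Alignment:
    """Banded (diagonal) alignment anchored at (x_start_node, y_start_peak).

    The alignment begins with the start triple; every later matched pair
    (x_j, y_i) must satisfy |(m_i - m_i0) - B(j0, j)| <= band, where B is the
    unmodified (black-edge) prefix mass between the start node and x_j.  The
    default band, 2*delta_max plus the largest single edge mass, never cuts an
    optimal in-band path over modification-free stretches.
    """
    check_precondition(pmg, prof)
    n, m = pmg.n, smg.m
    if not 0 <= start_node <= n:
        raise ValueError(f"start_node must be in [0, {n}], got {start_node}")
    if not 0 <= start_peak <= m:
        raise ValueError(f"start_peak must be in [0, {m}], got {start_peak}")
    if band is None:
        band = 2 * prof.delta_max + pmg.max_edge_mass
    if universe is None:
        universe = subpath_mass_universe(pmg, caps)
    index = build_mass_difference_index(smg, universe, prof)
    trans = _build_transitions(smg, universe, index, prof)

    # admissible cells: the anchor itself, or strictly after it and in band
    prefix = pmg.black_prefix()
    bdiag = prefix - prefix[start_node]
    rel = (smg.masses[:, None] - smg.masses[start_peak]) - bdiag[None, :]
    allowed = (
        (np.abs(rel) <= band)
        & (np.arange(m + 1)[:, None] > start_peak)
        & (np.arange(n + 1)[None, :] > start_node)
    )
    allowed[start_peak, start_node] = True
    keep = allowed[trans.i1, trans.j1] & allowed[trans.i2, trans.j2]

    def pick(a: np.ndarray) -> np.ndarray:
        return a[keep]

    ftrans = _Transitions(
        i1=pick(trans.i1), j1=pick(trans.j1), i2=pick(trans.i2), j2=pick(trans.j2),
        shift=pick(trans.shift), klo=pick(trans.klo), khi=pick(trans.khi), mu=pick(trans.mu),
    )
    seed_len = int(prof.lo[start_peak] + prof.hi[start_peak] + 1)
    seeds = {(start_peak, start_node): np.ones(seed_len, dtype=np.int64)}
    table = _run_engine(ftrans, prof, seeds=seeds)
    state = DPState(table=table, trans=ftrans, prof=prof, seeded=True, seed_cells=seeds)
    return traceback(state, smg, pmg)


def brute_force_align(
    pmg: PMG,
    smg: SMG,
    prof: ToleranceProfile,
    caps: EnumerationCaps = DEFAULT_CAPS,
) -> Alignment:
    """Independent oracle: exhaustive search over the unreduced (i, j, k) space.

    Enumerates, for every cell, all predecessor cells directly from the
    definition (memoized longest chain); no mass-difference index, no merged
    candidate lists.  Guarded to small instances because the cell count grows
    as n * m * delta.
    """
    if pmg.n > 10 or smg.m > 10 or prof.delta_max > 30:
        raise ValueError("brute-force oracle is limited to n <= 10, m <= 10, delta_max <= 30")
    d_sets: Dict[Tuple[int, int], Tuple[int, ...]] = {}
    for j in range(1, pmg.n + 1):
        for s in range(max(0, j - caps.max_gap_residues), j):
            d_sets[(s, j)] = path_masses(pmg, s, j, caps).masses
    masses = smg.masses.tolist()
    lo = prof.lo.tolist()
    hi = prof.hi.tolist()

    memo: Dict[Tuple[int, int, int], int] = {}

    def longest(i: int, j: int, k: int) -> int:
        key = (i, j, k)
        if key in memo:
            return memo[key]
        best = 1
        for ip in range(i):
            for jp in range(max(0, j - caps.max_gap_residues), j):
                for mu in d_sets[(jp, j)]:
                    kp = (masses[i] + k) - masses[ip] - mu
                    if -lo[ip] <= kp <= hi[ip]:
                        cand = 1 + longest(ip, jp, kp)
                        if cand > best:
                            best = cand
        memo[key] = best
        return best

    best_v = 1
    best_cell = (0, 0, 0)
    for i in range(smg.m + 1):
        for j in range(pmg.n + 1):
            for k in range(-lo[i], hi[i] + 1):
                v = longest(i, j, k)
                if v > best_v:
                    best_v = v
                    best_cell = (i, j, k)
    # reconstruct one optimal chain (lexicographically smallest predecessors)
    i, j, k = best_cell
    nodes, peaks, corrections, steps = [j], [i], [k], []
    v = best_v
    while v > 1:
        found = None
        for ip in range(i):
            for jp in range(max(0, j - caps.max_gap_residues), j):
                for mu in sorted(d_sets[(jp, j)]):
                    kp = (masses[i] + k) - masses[ip] - mu
                    if -lo[ip] <= kp <= hi[ip] and longest(ip, jp, kp) == v - 1:
                        cand = (ip, jp, kp, mu)
                        if found is None or cand < found:
                            found = cand
        assert found is not None
        i, j, k, mu = found
        nodes.append(j)
        peaks.append(i)
        corrections.append(k)
        steps.append(mu)
        v -= 1
    nodes.reverse(); peaks.reverse(); corrections.reverse(); steps.reverse()
    return Alignment(nodes=nodes, peaks=peaks, corrections=corrections, step_masses=steps)


@dataclass(frozen=True)
class VerificationResult:
    ok: bool
    message: Optional[str] = None

    def __bool__(self) -> bool:
        return self.ok


def verify_alignment(
    a: Alignment,
    pmg: PMG,
    smg: SMG,
    prof: ToleranceProfile,
    caps: EnumerationCaps = DEFAULT_CAPS,
) -> VerificationResult:
    """Check every invariant of an error-correction alignment.

    Consecutive corrected mass differences must be members of the appropriate
    sub-path mass sets (computed independently here via enumeration), indices
    must strictly increase, and every correction must lie within its peak's
    bounds.  The first violated step is named in the diagnostics.
    """
    r = a.size
    if r == 0:
        return VerificationResult(True)
    if not (len(a.peaks) == len(a.corrections) == r and len(a.step_masses) == r - 1):
        return VerificationResult(False, "inconsistent triple/step lengths")
    for q in range(r):
        i, j, k = a.peaks[q], a.nodes[q], a.corrections[q]
        if not 0 <= i <= smg.m or not 0 <= j <= pmg.n:
            return VerificationResult(False, f"step {q}: indices out of range")
        if not -prof.lo[i] <= k <= prof.hi[i]:
            return VerificationResult(
                False, f"step {q}: correction {k} outside [-{prof.lo[i]}, {prof.hi[i]}]"
            )
    corrected = a.corrected_masses(smg)
    for q in range(1, r):
        if a.peaks[q] <= a.peaks[q - 1] or a.nodes[q] <= a.nodes[q - 1]:
            return VerificationResult(False, f"step {q}: indices not strictly increasing")
        span = a.nodes[q] - a.nodes[q - 1]
        if span > caps.max_gap_residues:
            return VerificationResult(False, f"step {q}: span {span} exceeds cap")
        diff = corrected[q] - corrected[q - 1]
        allowed = path_masses(pmg, a.nodes[q - 1], a.nodes[q], caps).masses
        if diff not in allowed:
            return VerificationResult(
                False,
                f"step {q}: corrected difference {diff} is not a sub-path mass "
                f"of d({a.nodes[q - 1]}, {a.nodes[q]})",
            )
        if diff != a.step_masses[q - 1]:
            return VerificationResult(
                False, f"step {q}: annotated sub-path mass disagrees with corrected difference"
            )
    return VerificationResult(True)
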
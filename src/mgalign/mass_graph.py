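"""Proteoform and spectrum mass graphs and sub-path mass enumeration.

A protein plus its variable modifications is encoded as a *proteoform mass
graph* (PMG): a linear chain of n+1 bond nodes x_0..x_n where position p
(1-based) carries one black edge with the unmodified residue's scaled mass and
one red edge per applicable modification rule.  Every source-to-sink path
spells out one proteoform.

A deconvoluted spectrum is encoded as a *spectrum mass graph* (SMG): nodes
y_0..y_m ordered by scaled mass, with y_0 fixed at mass 0, so that the path
length from y_0 to y_i equals the (scaled) prefix mass of peak i.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np

from .masses import (
    ISOTOPE_SPACING_DA,
    ModificationRule,
    ResidueMassTable,
    discretize_mass,
    rules_for_targets,
)

logger = logging.getLogger(__name__)


class Provenance(enum.Enum):
    """How an SMG node came to exist."""

    ORIGINAL = "original"
    COMPLEMENTARY = "complementary"
    SATELLITE = "satellite"


@dataclass(frozen=True)
class Peak:
    """A raw deconvoluted peak: prefix mass in Dalton plus provenance."""

    mass_da: float
    provenance: Provenance = Provenance.ORIGINAL

    def __post_init__(self) -> None:
        if self.mass_da < 0:
            raise ValueError(f"peak mass must be non-negative, got {self.mass_da}")


@dataclass(frozen=True)
class EnumerationCaps:
    """Caps bounding the sub-path mass enumeration d(s, j).

    ``max_gap_residues`` limits the residue span j - s of a sub-path between
    two consecutively matched peaks; ``max_red_edges`` limits the number of
    modified residues inside one sub-path.
    """

    max_gap_residues: int = 10
    max_red_edges: int = 2


DEFAULT_CAPS = EnumerationCaps()


@dataclass
class PMG:
    """Proteoform mass graph: n+1 bond nodes, black + red parallel edges.

    ``black[p-1]`` is the scaled mass of the unmodified residue at position p;
    ``red[p]`` lists ``(scaled_mass, rule_id)`` alternatives for position p.
    """

    black: np.ndarray  # int64, length n
    red: Dict[int, List[Tuple[int, str]]] = field(default_factory=dict)
    sequence: Optional[str] = None
    name: Optional[str] = None

    def __post_init__(self) -> None:
        self.black = np.asarray(self.black, dtype=np.int64)
        if self.black.ndim != 1 or len(self.black) == 0:
            raise ValueError("PMG needs at least one position")
        if np.any(self.black <= 0):
            raise ValueError("all edge masses must be positive")
        for p, alts in self.red.items():
            if not 1 <= p <= self.n:
                raise ValueError(f"red edge at invalid position {p}")
            for m, _ in alts:
                if m <= 0:
                    raise ValueError("all edge masses must be positive")

    @property
    def n(self) -> int:
        """Number of positions; the graph has n+1 nodes x_0..x_n."""
        return len(self.black)

    def edges_at(self, p: int) -> List[Tuple[int, str, Optional[str]]]:
        """All parallel edges at position p as (scaled mass, color, rule id)."""
        out: List[Tuple[int, str, Optional[str]]] = [(int(self.black[p - 1]), "black", None)]
        for m, rid in self.red.get(p, ()):
            out.append((m, "red", rid))
        return out

    @property
    def min_edge_mass(self) -> int:
        """Smallest scaled mass over all black and red edges (m_small)."""
        m = int(self.black.min())
        for alts in self.red.values():
            for mass, _ in alts:
                m = min(m, mass)
        return m

    @property
    def max_edge_mass(self) -> int:
        m = int(self.black.max())
        for alts in self.red.values():
            for mass, _ in alts:
                m = max(m, mass)
        return m

    def black_prefix(self) -> np.ndarray:
        """Cumulative black-edge mass; entry j is the mass of x_0..x_j unmodified."""
        out = np.zeros(self.n + 1, dtype=np.int64)
        np.cumsum(self.black, out=out[1:])
        return out

    @classmethod
    def from_edge_masses(
        cls,
        black: Sequence[int],
        red: Optional[Dict[int, List[Tuple[int, str]]]] = None,
        name: Optional[str] = None,
    ) -> "PMG":
        """Build a synthetic PMG directly from scaled edge masses (for tests)."""
        return cls(black=np.asarray(black, dtype=np.int64), red=dict(red or {}), name=name)


def build_pmg(
    sequence: str,
    rules: Iterable[ModificationRule] = (),
    table: Optional[ResidueMassTable] = None,
    name: Optional[str] = None,
) -> PMG:
    """Construct the proteoform mass graph of ``sequence`` under ``rules``."""
    if not sequence:
        raise ValueError("sequence must be non-empty")
    table = table or ResidueMassTable()
    for aa in sequence:
        if aa not in table:
            raise ValueError(f"unknown residue letter {aa!r} in sequence")
    rules = list(rules)
    by_target = rules_for_targets(rules)
    unused = [r.rule_id for r in rules if r.target not in set(sequence)]
    if unused:
        logger.warning("rules targeting absent residues produce no edges: %s", unused)
    black = np.array([table.scaled(aa) for aa in sequence], dtype=np.int64)
    red: Dict[int, List[Tuple[int, str]]] = {}
    for p, aa in enumerate(sequence, start=1):
        for rule in by_target.get(aa, ()):
            red.setdefault(p, []).append(
                (discretize_mass(rule.modified_mass_da(table)), rule.rule_id)
            )
    return PMG(black=black, red=red, sequence=sequence, name=name)


@dataclass
class SMG:
    """Spectrum mass graph: sorted scaled node masses with provenance.

    ``tolerance_class`` records, for every node, whether its error-tolerance
    formula should be the one for original or for complementary peaks
    (satellite nodes inherit the class of the peak that spawned them).
    """

    masses: np.ndarray  # int64, strictly increasing, masses[0] == 0
    provenance: List[Provenance]
    tolerance_class: List[Provenance]
    precursor_mass: Optional[int] = None  # scaled

    def __post_init__(self) -> None:
        self.masses = np.asarray(self.masses, dtype=np.int64)
        if len(self.masses) == 0 or self.masses[0] != 0:
            raise ValueError("SMG must start with node y_0 at mass 0")
        if np.any(np.diff(self.masses) <= 0):
            raise ValueError("SMG masses must be strictly increasing")
        if not (len(self.provenance) == len(self.tolerance_class) == len(self.masses)):
            raise ValueError("provenance arrays must match the node count")

    @property
    def m(self) -> int:
        """Number of peaks; the graph has m+1 nodes y_0..y_m."""
        return len(self.masses) - 1

    def subset(self, keep: Sequence[int]) -> "SMG":
        """SMG restricted to the given node indices (must include 0)."""
        keep = list(keep)
        if keep[0] != 0:
            raise ValueError("node y_0 must be kept")
        return SMG(
            masses=self.masses[keep],
            provenance=[self.provenance[i] for i in keep],
            tolerance_class=[self.tolerance_class[i] for i in keep],
            precursor_mass=self.precursor_mass,
        )

    @classmethod
    def from_scaled(
        cls,
        masses: Sequence[int],
        precursor_mass: Optional[int] = None,
    ) -> "SMG":
        """Build an SMG directly from scaled masses (for tests); y_0 is added."""
        ms = sorted(set(int(m) for m in masses) | {0})
        return cls(
            masses=np.asarray(ms, dtype=np.int64),
            provenance=[Provenance.ORIGINAL] * len(ms),
            tolerance_class=[Provenance.ORIGINAL] * len(ms),
            precursor_mass=precursor_mass,
        )


def build_smg(
    peaks: Sequence[float],
    precursor_mass: Optional[float] = None,
    add_complementary: bool = True,
    satellite_threshold: float = 5000.0,
) -> SMG:
    """Build a spectrum mass graph from raw peak masses in Dalton.

    Preprocessing order: complementary peaks first (precursor minus each
    original peak), then satellite peaks at +-1.00235 Da for every peak above
    ``satellite_threshold``, then discretization, sorting, and merging of
    exact duplicates (provenance of the earliest-generated copy wins).
    """
    gen: List[Tuple[float, Provenance, Provenance]] = []
    for p in peaks:
        if p < 0:
            raise ValueError(f"peak mass must be non-negative, got {p}")
        gen.append((float(p), Provenance.ORIGINAL, Provenance.ORIGINAL))
    if add_complementary:
        if precursor_mass is None:
            raise ValueError("complementary peaks require a precursor mass")
        for p in peaks:
            comp = float(precursor_mass) - float(p)
            if comp < 0:
                logger.warning("skipping negative complementary peak for mass %s", p)
                continue
            gen.append((comp, Provenance.COMPLEMENTARY, Provenance.COMPLEMENTARY))
    for mass, _prov, cls_ in list(gen):
        if mass > satellite_threshold:
            gen.append((mass - ISOTOPE_SPACING_DA, Provenance.SATELLITE, cls_))
            gen.append((mass + ISOTOPE_SPACING_DA, Provenance.SATELLITE, cls_))

    entries = [(0, -1, Provenance.ORIGINAL, Provenance.ORIGINAL)]
    entries += [
        (discretize_mass(mass), order, prov, cls_)
        for order, (mass, prov, cls_) in enumerate(gen)
    ]
    entries.sort(key=lambda e: (e[0], e[1]))
    masses: List[int] = []
    provenance: List[Provenance] = []
    tol_class: List[Provenance] = []
    for scaled, _order, prov, cls_ in entries:
        if masses and masses[-1] == scaled:
            continue  # duplicate after discretization: earliest provenance kept
        masses.append(scaled)
        provenance.append(prov)
        tol_class.append(cls_)
    return SMG(
        masses=np.asarray(masses, dtype=np.int64),
        provenance=provenance,
        tolerance_class=tol_class,
        precursor_mass=None if precursor_mass is None else discretize_mass(precursor_mass),
    )


@dataclass(frozen=True)
class PathMassSet:
    """Distinct scaled masses of sub-paths from x_s to x_j."""

    s: int
    j: int
    masses: Tuple[int, ...]  # sorted ascending, deduplicated


def path_masses(pmg: PMG, s: int, j: int, caps: EnumerationCaps = DEFAULT_CAPS) -> PathMassSet:
    """Enumerate d(s, j): distinct sums of one edge per position in (s, j].

    At most ``caps.max_red_edges`` red edges may be chosen along the sub-path.
    """
    if not 0 <= s < j <= pmg.n:
        raise ValueError(f"need 0 <= s < j <= n, got s={s}, j={j}, n={pmg.n}")
    if j - s > caps.max_gap_residues:
        raise ValueError(
            f"sub-path span {j - s} exceeds max_gap_residues={caps.max_gap_residues}"
        )
    # frontier: mass -> minimum number of red edges used to reach it
    frontier: Dict[int, int] = {0: 0}
    for p in range(s + 1, j + 1):
        nxt: Dict[int, int] = {}
        black = int(pmg.black[p - 1])
        reds = pmg.red.get(p, ())
        for mass, nred in frontier.items():
            key = mass + black
            if nred < nxt.get(key, caps.max_red_edges + 1):
                nxt[key] = nred
            if nred < caps.max_red_edges:
                for rm, _rid in reds:
                    key = mass + rm
                    if nred + 1 < nxt.get(key, caps.max_red_edges + 1):
                        nxt[key] = nred + 1
        frontier = nxt
    return PathMassSet(s=s, j=j, masses=tuple(sorted(frontier)))


@dataclass
class SubpathUniverse:
    """The union D of all d(s, j) with 1 <= j - s <= max_gap_residues.

    Entries are sorted nondecreasing by mass; ``L`` is the total stored size.
    """

    mass: np.ndarray  # int64, sorted
    s: np.ndarray  # int64 source node per entry
    j: np.ndarray  # int64 target node per entry

    @property
    def L(self) -> int:
        return len(self.mass)

    def entries(self) -> List[Tuple[int, int, int]]:
        return [
            (int(m), int(s), int(j))
            for m, s, j in zip(self.mass, self.s, self.j)
        ]


def subpath_mass_universe(pmg: PMG, caps: EnumerationCaps = DEFAULT_CAPS) -> SubpathUniverse:
    """Enumerate every capped sub-path mass set and pool them sorted by mass."""
    if caps.max_gap_residues < 1:
        raise ValueError("max_gap_residues must be >= 1")
    masses: List[int] = []
    ss: List[int] = []
    jj: List[int] = []
    for s in range(pmg.n):
        # extend forward incrementally, sharing work across j for fixed s
        frontier: Dict[int, int] = {0: 0}
        for j in range(s + 1, min(pmg.n, s + caps.max_gap_residues) + 1):
            nxt: Dict[int, int] = {}
            black = int(pmg.black[j - 1])
            reds = pmg.red.get(j, ())
            for mass, nred in frontier.items():
                key = mass + black
                if nred < nxt.get(key, caps.max_red_edges + 1):
                    nxt[key] = nred
                if nred < caps.max_red_edges:
                    for rm, _rid in reds:
                        key = mass + rm
                        if nred + 1 < nxt.get(key, caps.max_red_edges + 1):
                            nxt[key] = nred + 1
            frontier = nxt
            for mass in frontier:
                masses.append(mass)
                ss.append(s)
                jj.append(j)
    mass_a = np.asarray(masses, dtype=np.int64)
    order = np.argsort(mass_a, kind="stable")
    return SubpathUniverse(
        mass=mass_a[order],
        s=np.asarray(ss, dtype=np.int64)[order],
        j=np.asarray(jj, dtype=np.int64)[order],
    )
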
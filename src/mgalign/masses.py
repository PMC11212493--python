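"""Monoisotopic residue masses, mass discretization, and modification rules.

All graph arithmetic in this package is performed on *scaled integer* masses,
obtained from masses in Dalton by ``floor(m * 274.335215)``.  The scale factor
is chosen so that the scaled masses of the 20 standard residues are far apart
compared with typical deconvolution errors, which makes integer error
corrections meaningful.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, Mapping

#: Scale factor applied before flooring to integers.
SCALE = 274.335215

#: Spacing of the C12/C13 isotope error absorbed by satellite peaks (Da).
ISOTOPE_SPACING_DA = 1.00235

#: Monoisotopic residue (not amino acid) masses in Dalton.
STANDARD_RESIDUE_MASSES_DA: Dict[str, float] = {
    "G": 57.02146,
    "A": 71.03711,
    "S": 87.03203,
    "P": 97.05276,
    "V": 99.06841,
    "T": 101.04768,
    "C": 103.00919,
    "L": 113.08406,
    "I": 113.08406,
    "N": 114.04293,
    "D": 115.02694,
    "Q": 128.05858,
    "K": 128.09496,
    "E": 129.04259,
    "M": 131.04049,
    "H": 137.05891,
    "F": 147.06841,
    "R": 156.10111,
    "Y": 163.06333,
    "W": 186.07931,
}

_STANDARD_20 = frozenset(STANDARD_RESIDUE_MASSES_DA)


def discretize_mass(mass: float) -> int:
    """Convert a mass in Dalton to its scaled integer representation.

    Parameters
    ----------
    mass : float
        Non-negative mass in Dalton.

    Returns
    -------
    int
        ``floor(mass * 274.335215)``.
    """
    if mass < 0:
        raise ValueError(f"mass must be non-negative, got {mass!r}")
    return math.floor(mass * SCALE)


@dataclass(frozen=True)
class ResidueMassTable:
    """Map from one-letter amino-acid codes to monoisotopic residue masses (Da)."""

    masses: Mapping[str, float] = field(
        default_factory=lambda: dict(STANDARD_RESIDUE_MASSES_DA)
    )

    def __post_init__(self) -> None:
        missing = _STANDARD_20 - set(self.masses)
        if missing:
            raise ValueError(f"residue table missing standard residues: {sorted(missing)}")
        for aa, m in self.masses.items():
            if m <= 0:
                raise ValueError(f"residue {aa!r} has non-positive mass {m}")
        smallest = min(self.masses, key=self.masses.__getitem__)
        if smallest != "G":
            raise ValueError(
                f"smallest residue must be glycine, got {smallest!r}"
            )

    def __getitem__(self, aa: str) -> float:
        return self.masses[aa]

    def __contains__(self, aa: str) -> bool:
        return aa in self.masses

    def scaled(self, aa: str) -> int:
        return discretize_mass(self.masses[aa])

    @property
    def min_mass_scaled(self) -> int:
        """Smallest scaled residue mass (glycine for the standard table)."""
        return min(self.scaled(aa) for aa in self.masses)


@dataclass(frozen=True)
class ModificationRule:
    """A variable modification of one residue.

    ``mode='replace'`` gives the modified residue the absolute mass ``mass_da``
    (mutation-style rules, e.g. K->C); ``mode='shift'`` adds ``mass_da`` to the
    target residue's mass (chemical-modification rules, e.g. phosphorylation).
    """

    rule_id: str
    target: str
    mode: str  # 'replace' | 'shift'
    mass_da: float
    label: str = ""

    def __post_init__(self) -> None:
        if self.mode not in ("replace", "shift"):
            raise ValueError(f"mode must be 'replace' or 'shift', got {self.mode!r}")
        if len(self.target) != 1:
            raise ValueError(f"target must be a single residue letter, got {self.target!r}")

    def modified_mass_da(self, table: ResidueMassTable) -> float:
        if self.target not in table:
            raise KeyError(f"rule {self.rule_id!r} targets unknown residue {self.target!r}")
        if self.mode == "replace":
            m = self.mass_da
        else:
            m = table[self.target] + self.mass_da
        if m <= 0:
            raise ValueError(
                f"rule {self.rule_id!r} yields non-positive modified mass {m}"
            )
        return m


def _ptm_rules() -> list[ModificationRule]:
    # Standard UNIMOD monoisotopic shifts; targets are the common variable-mod sites.
    shifts = [
        ("oxidation_M", "M", 15.994915, "UNIMOD:35"),
        ("deamidation_N", "N", 0.984016, "UNIMOD:7"),
        ("deamidation_Q", "Q", 0.984016, "UNIMOD:7"),
        ("phospho_S", "S", 79.966331, "UNIMOD:21"),
        ("phospho_T", "T", 79.966331, "UNIMOD:21"),
        ("phospho_Y", "Y", 79.966331, "UNIMOD:21"),
        ("carbamidomethyl_C", "C", 57.021464, "UNIMOD:4"),
    ]
    return [ModificationRule(r, t, "shift", m, l) for r, t, m, l in shifts]


def _mutation_rules() -> list[ModificationRule]:
    t = STANDARD_RESIDUE_MASSES_DA
    muts = [
        ("K_to_C", "K", t["C"], "UNIMOD:1132"),
        ("T_to_A", "T", t["A"], "UNIMOD:659"),
        ("V_to_G", "V", t["G"], "UNIMOD:672"),
    ]
    return [ModificationRule(r, tgt, "replace", m, l) for r, tgt, m, l in muts]


#: Chemical variable-modification rule set (oxidation, deamidation,
#: phosphorylation, carbamidomethylation).
VARIABLE_PTM_RULES: list[ModificationRule] = _ptm_rules()

#: Mutation-style rule set (K->C, T->A, V->G).
MUTATION_RULES: list[ModificationRule] = _mutation_rules()


def rules_for_targets(rules: Iterable[ModificationRule]) -> Dict[str, list[ModificationRule]]:
    """Group rules by target residue letter."""
    out: Dict[str, list[ModificationRule]] = {}
    for r in rules:
        out.setdefault(r.target, []).append(r)
    return out
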
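"""Alignment-quality metrics: maximum/average pairwise mass error, residue-match histogram.

The maximum mass error (MME) and average mass error (AME) of an alignment are
taken over *all* pairs of matched peaks, comparing raw observed mass
differences with the theoretical sub-path masses the alignment chose.  Because
each peak carries its own correction k bounded by its tolerance, the error of
any pair is |k_q - k_q'| and MME is structurally bounded by twice the
tolerance -- the property that distinguishes anchored error correction from
per-edge tolerance matching, where errors accumulate.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Tuple

import numpy as np

from .align import Alignment, verify_alignment
from .mass_graph import DEFAULT_CAPS, EnumerationCaps, PMG, SMG
from .tolerance import ToleranceProfile


def pairwise_mass_errors(a: Alignment, pmg: PMG, smg: SMG) -> List[int]:
    """|observed - theoretical| for every pair of matched peaks.

    Observed is the raw (uncorrected) mass difference of the two peaks;
    theoretical is the sum of the sub-path masses the alignment chose between
    them.  Returns r*(r-1)/2 values.
    """
    r = a.size
    obs = np.array([int(smg.masses[i]) for i in a.peaks], dtype=np.int64)
    theo = np.zeros(r, dtype=np.int64)
    if r > 1:
        np.cumsum(np.asarray(a.step_masses, dtype=np.int64), out=theo[1:])
    errors: List[int] = []
    for q in range(r):
        for qp in range(q + 1, r):
            errors.append(int(abs((obs[qp] - obs[q]) - (theo[qp] - theo[q]))))
    return errors


def mme(errors: List[int]) -> int:
    """Maximum pairwise mass error; 0 for an empty list."""
    return max(errors) if errors else 0


def ame(errors: List[int]) -> float:
    """Average pairwise mass error; 0.0 for an empty list."""
    return float(np.mean(errors)) if errors else 0.0


def consecutive_signed_errors(a: Alignment, smg: SMG) -> List[int]:
    """Signed observed-minus-theoretical error per consecutive matched pair."""
    out = []
    for q in range(1, a.size):
        obs = int(smg.masses[a.peaks[q]]) - int(smg.masses[a.peaks[q - 1]])
        out.append(obs - a.step_masses[q - 1])
    return out


def residue_match_histogram(a: Alignment, pmg: PMG) -> Tuple[int, int, int]:
    """Counts of consecutive matches spanning 1, 2, and >=3 residues."""
    n1 = n2 = n3 = 0
    for span in a.spans():
        if span == 1:
            n1 += 1
        elif span == 2:
            n2 += 1
        else:
            n3 += 1
    return n1, n2, n3


@dataclass
class AlignmentMetrics:
    size: int
    mme: int
    ame: float
    matches_1: int
    matches_2: int
    matches_3plus: int
    consecutive_errors: List[int]

    def to_json(self) -> Dict:
        return {
            "score": self.size,
            "mme": self.mme,
            "ame": self.ame,
            "matches_1": self.matches_1,
            "matches_2": self.matches_2,
            "matches_3plus": self.matches_3plus,
            "consecutive_errors": list(self.consecutive_errors),
        }


def compute_metrics(
    a: Alignment,
    pmg: PMG,
    smg: SMG,
    prof: ToleranceProfile,
    caps: EnumerationCaps = DEFAULT_CAPS,
) -> AlignmentMetrics:
    """Verify the alignment and compute all quality metrics."""
    check = verify_alignment(a, pmg, smg, prof, caps)
    if not check:
        raise ValueError(f"cannot score an invalid alignment: {check.message}")
    errors = pairwise_mass_errors(a, pmg, smg)
    n1, n2, n3 = residue_match_histogram(a, pmg)
    return AlignmentMetrics(
        size=a.size,
        mme=mme(errors),
        ame=ame(errors),
        matches_1=n1,
        matches_2=n2,
        matches_3plus=n3,
        consecutive_errors=consecutive_signed_errors(a, smg),
    )
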
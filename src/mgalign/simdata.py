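"""Synthetic proteins, proteoforms, and error-bearing spectra with ground truth.

The generator emulates the downstream product of a top-down MS/MS pipeline:
deconvoluted monoisotopic *prefix* masses of a modified protein, with integer
perturbations in scaled units, partial fragment coverage, and uniform noise
peaks.  Instrument physics (charge states, ion types, intensities, isotope
envelopes) is deliberately not modelled -- the aligner consumes prefix-mass
peak lists, and that is what is generated.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .align import dp_align, traceback
from .masses import SCALE, ModificationRule, ResidueMassTable, discretize_mass
from .mass_graph import (
    DEFAULT_CAPS,
    EnumerationCaps,
    build_pmg,
    build_smg,
    subpath_mass_universe,
)
from .metrics import compute_metrics
from .tolerance import make_profile

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class SimConfig:
    """Conditions for synthetic data generation.

    Defaults mirror the whole-protein evaluation protocol: five variable
    modifications per proteoform, 80% fragment coverage, five uniform noise
    peaks, and peak errors drawn as uniform integers in [-27, 27] scaled
    units, i.e. exactly the span of the default alignment tolerance.
    """

    seed: int = 0
    n_proteins: int = 50
    length_range: Tuple[int, int] = (60, 200)
    n_modifications: int = 5
    coverage: float = 0.8
    error_scaled: int = 27
    n_noise_peaks: int = 5

    def __post_init__(self) -> None:
        if not 0.0 <= self.coverage <= 1.0:
            raise ValueError("coverage must be in [0, 1]")
        if self.error_scaled < 0 or self.n_noise_peaks < 0:
            raise ValueError("error and noise settings must be non-negative")
        if self.length_range[0] < 1 or self.length_range[0] > self.length_range[1]:
            raise ValueError("invalid length range")


@dataclass
class GroundTruth:
    """What was simulated: modification sites, kept peaks, true corrections."""

    sequence: str
    sites: Dict[int, str]  # 1-based position -> rule id
    kept_positions: List[int]  # prefix positions with an emitted peak
    true_masses_scaled: List[int]  # unperturbed scaled mass per kept position
    errors_scaled: List[int]  # perturbation per kept position
    noise_masses_da: List[float]
    peptide_span: Optional[Tuple[int, int]] = None  # (start, end) in the parent protein


@dataclass
class SimulatedSpectrum:
    peaks_da: List[float]
    precursor_da: float
    truth: GroundTruth


def random_protein_db(cfg: SimConfig, rng: Optional[np.random.Generator] = None) -> List[str]:
    """Deterministic random database: i.i.d. residues, uniform lengths."""
    rng = rng or np.random.default_rng(cfg.seed)
    lo, hi = cfg.length_range
    out = []
    for _ in range(cfg.n_proteins):
        length = int(rng.integers(lo, hi + 1))
        out.append("".join(rng.choice(list(AA_ALPHABET), size=length)))
    return out


def _undiscretize(scaled: int) -> float:
    # A Dalton value whose discretization is exactly `scaled`.
    return (scaled + 0.5) / SCALE


def simulate_spectrum(
    sequence: str,
    rules: Sequence[ModificationRule],
    cfg: SimConfig,
    rng: Optional[np.random.Generator] = None,
    table: Optional[ResidueMassTable] = None,
) -> SimulatedSpectrum:
    """Simulate one deconvoluted prefix-mass spectrum of a modified protein.

    Exactly ``cfg.n_modifications`` modifiable sites are chosen without
    replacement; the proteoform's prefix masses (positions 1..n, the last
    being the precursor) are thinned to the coverage fraction, perturbed by
    uniform integer errors in scaled units, and mixed with uniform noise.
    """
    rng = rng or np.random.default_rng(cfg.seed)
    table = table or ResidueMassTable()
    by_target: Dict[str, List[ModificationRule]] = {}
    for r in rules:
        by_target.setdefault(r.target, []).append(r)
    modifiable = [p for p, aa in enumerate(sequence, start=1) if aa in by_target]
    if len(modifiable) < cfg.n_modifications:
        raise ValueError(
            f"sequence has {len(modifiable)} modifiable sites, "
            f"need {cfg.n_modifications}"
        )
    chosen = sorted(
        int(p) for p in rng.choice(modifiable, size=cfg.n_modifications, replace=False)
    )
    sites: Dict[int, str] = {}
    residue_scaled: List[int] = []
    for p, aa in enumerate(sequence, start=1):
        if p in chosen:
            rule = by_target[aa][int(rng.integers(len(by_target[aa])))]
            sites[p] = rule.rule_id
            residue_scaled.append(discretize_mass(rule.modified_mass_da(table)))
        else:
            residue_scaled.append(discretize_mass(table[aa]))
    # ground truth lives in graph space: prefix masses are sums of the
    # discretized residue masses, exactly the proteoform path lengths
    prefix_scaled = np.cumsum(residue_scaled)
    precursor_scaled = int(prefix_scaled[-1])
    precursor_da = _undiscretize(precursor_scaled)

    kept = [p for p in range(1, len(sequence) + 1) if rng.random() < cfg.coverage]
    true_scaled: List[int] = []
    errors: List[int] = []
    peaks_da: List[float] = []
    for p in kept:
        ts = int(prefix_scaled[p - 1])
        err = int(rng.integers(-cfg.error_scaled, cfg.error_scaled + 1)) if cfg.error_scaled else 0
        # keep perturbed peaks at or below the precursor mass
        if ts + err > precursor_scaled:
            err = precursor_scaled - ts
        true_scaled.append(ts)
        errors.append(err)
        peaks_da.append(_undiscretize(ts + err))
    noise = [float(x) for x in rng.uniform(0.0, precursor_da, size=cfg.n_noise_peaks)]
    peaks = sorted(peaks_da + noise)
    truth = GroundTruth(
        sequence=sequence,
        sites=sites,
        kept_positions=kept,
        true_masses_scaled=true_scaled,
        errors_scaled=errors,
        noise_masses_da=noise,
    )
    return SimulatedSpectrum(peaks_da=peaks, precursor_da=precursor_da, truth=truth)


def simulate_peptide_spectrum(
    sequence: str,
    rules: Sequence[ModificationRule],
    cfg: SimConfig,
    rng: Optional[np.random.Generator] = None,
    length_range: Tuple[int, int] = (23, 154),
    table: Optional[ResidueMassTable] = None,
    max_tries: int = 50,
) -> SimulatedSpectrum:
    """Simulate a spectrum of a random internal peptide of ``sequence``."""
    rng = rng or np.random.default_rng(cfg.seed)
    lo = min(length_range[0], len(sequence))
    hi = min(length_range[1], len(sequence))
    for _ in range(max_tries):
        length = int(rng.integers(lo, hi + 1))
        start = int(rng.integers(0, len(sequence) - length + 1))
        peptide = sequence[start : start + length]
        try:
            sim = simulate_spectrum(peptide, rules, cfg, rng=rng, table=table)
        except ValueError:
            continue  # too few modifiable sites in this substring; redraw
        sim.truth.peptide_span = (start, start + length)
        return sim
    raise ValueError("could not draw a peptide with enough modifiable sites")


@dataclass
class RecoveryReport:
    rows: pd.DataFrame
    accuracy: float


def benchmark_recovery(
    cfg: SimConfig,
    rules: Sequence[ModificationRule],
    n_spectra: int = 20,
    mode: str = "protein",
    delta: int = 27,
    caps: EnumerationCaps = DEFAULT_CAPS,
    peptide_length_range: Tuple[int, int] = (23, 154),
    table: Optional[ResidueMassTable] = None,
    query_sequences: Optional[Sequence[str]] = None,
) -> RecoveryReport:
    """Simulate spectra and search them against the whole synthetic database.

    Every spectrum is aligned against every database protein with free
    endpoints; proteins are ranked by alignment size, ties broken by smaller
    AME and then database order.  ``mode='peptide'`` simulates spectra of
    random internal peptides instead of whole proteins, so the best local
    (free-endpoint) alignment must locate the peptide inside its parent.

    ``query_sequences``, if given, replaces the drawn query proteins with
    sequences that need not be in the database; such spectra can never be
    scored correct (their truth is absent from the search space).
    """
    if mode not in ("protein", "peptide"):
        raise ValueError(f"unknown benchmark mode {mode!r}")
    table = table or ResidueMassTable()
    db = random_protein_db(cfg)
    pmgs = [build_pmg(seq, rules, table, name=f"P{idx:04d}") for idx, seq in enumerate(db)]
    universes = [subpath_mass_universe(g, caps) for g in pmgs]
    rng = np.random.default_rng([cfg.seed, 1])
    if query_sequences is not None:
        queries = [(seq, -1) for seq in query_sequences][:n_spectra]
        n_spectra = len(queries)
    else:
        chosen = sorted(
            int(i) for i in rng.choice(cfg.n_proteins, size=n_spectra, replace=False)
        )
        queries = [(db[i], i) for i in chosen]

    records = []
    n_correct = 0
    for spec_no, (query_seq, true_idx) in enumerate(queries):
        if mode == "protein":
            sim = simulate_spectrum(query_seq, rules, cfg, rng=rng, table=table)
        else:
            sim = simulate_peptide_spectrum(
                query_seq, rules, cfg, rng=rng,
                length_range=peptide_length_range, table=table,
            )
        smg0 = build_smg(sim.peaks_da, sim.precursor_da, add_complementary=False)
        smg, prof = make_profile(smg0, mode="fixed", delta=delta)
        scores = []
        states = []
        for g, uni in zip(pmgs, universes):
            state = dp_align(g, smg, prof, caps, universe=uni)
            states.append(state)
            scores.append(state.best_score())
        best = max(scores)
        tied = [idx for idx, sc in enumerate(scores) if sc == best]
        ranked = []
        for idx in tied:
            aln = traceback(states[idx], smg, pmgs[idx])
            met = compute_metrics(aln, pmgs[idx], smg, prof, caps)
            ranked.append((met.ame, idx, met))
        ranked.sort(key=lambda t: (t[0], t[1]))
        _, top_idx, top_met = ranked[0]
        correct = top_idx == true_idx
        n_correct += int(correct)
        records.append(
            {
                "spectrum": spec_no,
                "true_protein": f"P{true_idx:04d}" if true_idx >= 0 else "absent",
                "top_protein": f"P{top_idx:04d}",
                "score": best,
                "mme": top_met.mme,
                "ame": top_met.ame,
                "correct": bool(correct),
            }
        )
    rows = pd.DataFrame.from_records(records)
    return RecoveryReport(rows=rows, accuracy=n_correct / n_spectra)
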
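# Methods

## Model

A proteoform mass graph (PMG) encodes a protein of `n` residues as bond nodes
`x_0..x_n`. Position `p` carries one black edge whose mass is the scaled
monoisotopic residue mass, plus one red edge per variable-modification rule
applicable to that residue. Rules come in two flavours: *replace* (the edge
gets the absolute mass of another residue, mutation-style, e.g. K→C) and
*shift* (an additive UNIMOD delta, e.g. phosphorylation +79.966331 Da). A
sub-path mass set `d(s, j)` is the set of distinct sums obtained by choosing
one edge per position in `(s, j]`.

A spectrum mass graph (SMG) holds scaled peak masses `m_0 = 0 < m_1 < … <
m_m`. Preprocessing may add, per original peak, a complementary peak at
(precursor − m) and, for every peak above 5000 Da, two satellite peaks at
±1.00235 Da that absorb one-Dalton deconvolution errors; duplicates arising
after discretization are merged (generation happens first, merging last).

All arithmetic uses scaled integers `⌊m·274.335215⌋`. The scale maps the
standard tolerance of roughly 0.1 Da to 27 integer units; glycine, the
smallest residue, scales to 15642.

An error-correction alignment is a strictly increasing sequence of triples
`(x_jq, y_iq, k_q)` with every consecutive corrected mass difference
`(m_iq + k_q) − (m_iq−1 + k_q−1)` exactly a member of `d(j_{q−1}, j_q)`. The
objective is maximum length. Because corrections anchor to peaks rather than
edges, the observed error between any two matched peaks is `|k_i − k_j|`,
bounded by `2δ` under fixed tolerance — the package's central guarantee,
checked end to end by the test suite.

## Tolerances

Two modes:

* **fixed** — `δ_i = δ` (default 27) for every real peak; `δ_0 = 0` since
  `y_0` is exact by construction.
* **peak-dependent** — `δ_i = 27 + round(ppm·m_i/10⁶)` with `ppm = 15` by
  default; complementary-class peaks use `(m_i + M)` with `M` the scaled
  precursor mass, and satellite peaks inherit the formula of the peak that
  spawned them. The additive and ppm coefficients are both configurable
  because published descriptions of such tolerances vary in typography; the
  15-ppm reading is the field's conventional relative term.

Before alignment the per-peak intervals `[m_i − δ_i⁻, m_i + δ_i⁺]`
(initially symmetric) are:

1. **pruned** — a peak whose interval is contained in a neighbour's is
   deleted; iterated to a fixpoint, which subsumes chains of domination;
   mutual containment keeps the later peak (deterministic tie-break);
2. **disjointified** — each overlapping consecutive pair is split at the
   midpoint of the two peak masses, ties to the earlier peak. The union of
   covered integer positions is preserved exactly and intervals become
   pairwise disjoint (property-tested), so each candidate corrected position
   is examined once. Optimum invariance under this reduction is itself an
   acceptance test.

The aligner refuses to run (`ToleranceTooLargeError`) unless
`m_small > 4·δ_max`, where `m_small` is the smallest modified-or-unmodified
edge mass in the PMG: beyond that point distinct peaks may claim the same
corrected position with different DP values and the reduction would be
unsound. With the standard residue table and δ = 27 the margin is wide
(15642 vs 108).

A degenerate corner: a real peak within δ of mass zero would overlap `y_0`'s
fixed `{0}`. `y_0` never widens (its correction is pinned to 0), so such a
peak's lower bound is clamped to corrected position 1 at profile creation.

## Dynamic program

`T(i, j, k)` is the maximum alignment size ending with peak `y_i`, corrected
to `m_i + k`, matched at node `x_j`; all cells start at 1. Transitions come
from merging two sorted structures: the sub-path universe `D` (all `d(s, j)`
entries with span ≤ `max_gap_residues`, default 10, and at most
`max_red_edges` red choices, default 2) and the peak-pair difference index
`M` (pairs whose difference is within `2δ_max` of some universe mass). Each
(universe entry, peak pair) match yields a *transition tuple*: for a
contiguous band of corrections `k`, `T(i, j, k) ≥ T(i′, j′, k + s) + 1` with
`s = (m_i − m_i′) − μ`. Tuples are applied in ascending target-node order as
vectorized interval maximum updates, so runtime is governed by the number of
tuples (≈ `n·m·q + L` behaviour: tuple count scales with the universe size
`L` and the reduced range size `q = max(δ_i⁻+δ_i⁺)`).

The caps on sub-path enumeration bound the otherwise exponential `d(s, j)`;
gaps longer than 10 residues or containing more than 2 modified residues are
not bridged. Both are configurable.

Global mode leaves both endpoints free and reports the maximum over all
cells. Traceback recovers predecessors by re-scanning transition tuples into
the current cell; ties resolve to the lexicographically smallest `(i, j, k)`
everywhere, making reports byte-reproducible.

Diagonal (local) mode takes start positions `(j₀, i₀)` as the alignment's
first triple and admits a later cell `(i, j)` only if
`|(m_i − m_i₀) − B(j₀, j)| ≤ band`, where `B` is the black-edge prefix mass
between the start node and `x_j`. The default band, `2δ_max` plus the
largest single edge mass, cannot cut an optimal in-band path across
modification-free stretches. The same transition engine runs seeded: only
chains rooted at the anchor propagate.

The brute-force oracle enumerates predecessors of every cell of the full
`(i, j, k)` space directly from the definition (memoized longest chain, no
index structures) and is guarded to `n, m ≤ 10`, `δ_max ≤ 30`. The fast DP
is tested to agree with it on 216 random instances spanning δ ∈ {0, 2, 5}
with and without red edges.

## Metrics

For a verified alignment, the error of a pair of matched peaks is the
absolute difference between their raw mass difference and the sum of the
chosen sub-path masses between them (equivalently `|k_i − k_j|`). MME is the
maximum and AME the mean over all `r(r−1)/2` pairs; signed consecutive
errors are kept in diagnostics. The residue-match histogram buckets each
consecutive pair by sub-path span (1, 2, ≥3 residues); short spans are the
more trustworthy evidence. Theoretical masses use the sub-path actually
chosen (red edges included), i.e. the matched proteoform, not the unmodified
protein.

## Synthetic data

The generator emulates the *output* of a deconvolution pipeline, not the
instrument: it emits prefix-coordinate monoisotopic masses directly. One
simulated spectrum is built by (1) choosing exactly `n_modifications` sites
among residues with applicable rules, (2) forming the proteoform's prefix
masses as cumulative sums of scaled residue masses — graph space, so the
injected perturbations are exactly the corrections the aligner should
recover, (3) keeping each prefix with probability `coverage`, (4) perturbing
each kept peak by a uniform integer in `[−ε, +ε]` scaled units, clamped to
not exceed the precursor, and (5) adding `n_noise_peaks` uniform noise
masses. Defaults: coverage 0.8, ε = 27 (the full span of the default
tolerance), 5 noise peaks, five modifications from the
oxidation/deamidation/phosphorylation/carbamidomethylation rule set, database
of 50 proteins with lengths 60–200 (long enough to host the 23–154-residue
peptides of the peptide-level study).

Not modelled: charge states, ion types, intensities, isotope envelopes,
terminus mixing (all peaks are prefix-coordinate, so benchmark harnesses
disable complementary-peak generation), and correlated mass errors. Passing
recovery tests therefore demonstrates the aligner's behaviour under the
stated error model, not end-to-end performance on raw instrument data.

Benchmarks align each spectrum against every database protein with free
endpoints and rank by alignment size (ties: smaller AME, then database
order). The peptide study uses the same free-endpoint optimum as its local
score: since endpoints are unconstrained, the table maximum *is* the best
local alignment, and unlike the anchored diagonal mode it needs no externally
supplied start positions for the non-true candidates.

## Problem sizes and determinism

The reproduction script runs 50 proteoform/spectrum pairs (lengths 30–60,
2 modifications) for the MME-bound study and 20 spectra × 50 proteins for
each recovery study — sizes chosen so the full set completes in minutes on
one CPU while leaving the observed margins (true-protein scores several
times larger than the best decoy) far from the decision boundary. All
randomness flows from numpy `default_rng` seeded from the command line; the
brute-force-oracle and property tests in the suite run an additional 216
instances at `n, m ≤ 8`.

## Known limitations

* Fixed PTMs are not modelled (graphs carry variable modifications only).
* No raw/mzML deconvolution, isotope-envelope handling, or charge handling;
  input spectra must already be prefix-coordinate mass lists.
* No statistical significance (E-values/FDR) for scores; ranking is by
  alignment size only.
* The sub-path caps mean extremely modification-dense regions (>2 modified
  residues within one gap) cannot be bridged; raise `max_red_edges` at a
  (multiplicative) runtime cost if needed.
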
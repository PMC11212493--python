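# mgalign

Error-correction alignment of top-down MS/MS spectra against proteoform mass
graphs.

## The problem

Top-down mass spectrometry fragments intact proteins, so a deconvoluted MS/MS
spectrum is a list of prefix (or suffix) fragment masses of one *proteoform* —
a protein with a particular combination of post-translational modifications
(PTMs) or sequence variants. Identifying the proteoform means finding, in a
protein database, the modified protein whose theoretical fragment masses best
explain the observed peaks. Enumerating proteoforms explicitly explodes
combinatorially, so both sides are encoded as graphs:

* **Proteoform mass graph (PMG)** — a chain of bond nodes `x_0..x_n`; position
  `p` carries a *black* edge with the unmodified residue mass and one *red*
  edge per applicable variable modification. Every source-to-sink path spells
  one proteoform.
* **Spectrum mass graph (SMG)** — nodes `y_0..y_m` ordered by mass with `y_0`
  at 0, so the path length from `y_0` to `y_i` is the peak mass `m_i`.

All masses are scaled to integers by `⌊m · 274.335215⌋` (Da → scaled units;
the default tolerance of 27 scaled units is ≈ 0.1 Da).

Classical graph alignment tolerates peak errors *per edge*: consecutive
matched peaks may disagree with the database mass by up to δ each, so signed
errors accumulate along the alignment and two distant matched peaks can
disagree by many times δ — strong evidence of an unreliable identification.
This package instead computes **error-correction alignments**: a sequence of
triples `(x_j, y_i, k)` where each matched peak is moved by its own integer
correction `k ∈ [−δ_i⁻, δ_i⁺]` such that *every* corrected mass difference
equals a theoretical sub-path mass exactly. The observed error between any
two matched peaks is then `|k_i − k_j| ≤ 2δ` — bounded regardless of
alignment length.

The optimal alignment (maximum number of triples) is found by dynamic
programming over `T(i, j, k)`, with three efficiency devices:

* per-peak tolerance intervals are pruned (dominated peaks deleted) and
  **disjointified** (overlaps split at the midpoint), so every candidate
  corrected position is examined exactly once;
* transitions are generated by a single merge of the sorted sub-path mass
  universe `D` against the sorted peak-pair mass-difference index `M`;
* a **diagonal (local) mode** restricts the DP to a mass band around given
  start positions.

A brute-force oracle (exhaustive enumeration over the unreduced `(i, j, k)`
space), alignment verification, MME/AME quality metrics, and a synthetic
spectrum simulator with ground truth complete the package.

## Worked example

Simulate a 5-protein database and one spectrum (2 modifications, 3 noise
peaks), then align the spectrum against its true protein:

```sh
mgalign simulate --seed 11 --n-proteins 5 --length-min 40 --length-max 60 \
    --n-mods 2 --noise 3 --outdir demo
mgalign align --fasta demo/true.fasta --mods demo/rules.tsv \
    --spectrum demo/spectrum.txt --no-complementary --out demo/report
```

prints

```
alignment size 32, MME 52, AME 18.86
wrote demo/report.tsv and demo/report.json
```

32 triples were matched; the worst disagreement between any pair of matched
peaks and the theoretical proteoform masses is 52 scaled units (≈ 0.19 Da),
within the structural bound 2δ = 54, and the average is 18.86. The TSV lists
one matched triple per row:

```
node  residue_index  peak  raw_mass  corrected_mass  k    subpath_mass  residues_spanned
0     0              0     0         0               0
2     2              1     68869     68885           16   68885         2
3     3              2     96597     96605           8    27720         1
5     5              3     194307    194298          -9   97693         2
8     8              5     307943    307923          -20  113625        3
...
```

Each peak's raw mass is corrected by `k`; consecutive corrected masses differ
by exactly the annotated sub-path mass. `mgalign verify` re-checks a report
against its inputs, and `mgalign benchmark` runs a full database-search
recovery study on synthetic data.

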
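# Methods

## Problem and model

DNase I hypersensitive sites (DHS) are open-chromatin regions marking
regulatory DNA. Their primary sequences are poorly conserved, but their
dinucleotide composition is biased — CC, CG, GC and GG are elevated relative
to non-DHS background — and DNA local geometry (captured by dinucleotide
step parameters) carries additional signal. `dhspred` therefore encodes a
sequence by pseudo dinucleotide composition (PseDNC) and classifies with a
soft-margin RBF-kernel SVM.

For a sequence `R_1…R_L` (validated A/C/G/T, `L ≥ λ+2`):

* `f_u`, `u = 1..16`: frequencies of the `L−1` overlapping dinucleotides in
  fixed lexicographic order AA, AC, …, TT (this ordering of `d_1..d_16` is a
  package convention, documented here because any consistent ordering would
  do).
* `θ_j = (1/(L−1−j)) Σ_{i=1}^{L−1−j} Θ(R_iR_{i+1}, R_{i+j}R_{i+j+1})`,
  `j = 1..λ`: the j-tier correlation factor, an average structural
  dissimilarity between dinucleotides j positions apart.
* `Θ(x,y) = (1/μ) Σ_ξ (P̃_ξ(x) − P̃_ξ(y))²` over the `μ = 6` standardized
  structural properties (squared-difference, "type-I" correlation).
* `d_u = f_u / (1 + wΣθ_j)` for `u ≤ 16`, else `wθ_{u−16} / (1 + wΣθ_j)`;
  the denominator uses `Σf_i = 1` exactly, so every descriptor is a
  probability vector of dimension `16+λ` (sum-to-one enforced in tests to
  1e−9, which absorbs float accumulation over λ tiers).

Decision rule: `sgn(Σ y_i α_i K(x,x_i) + b)` with
`K(x,y) = exp(−γ‖x−y‖²)`; a decision value of exactly 0 is called positive
(a documented tie-break — libsvm's own sign convention at 0 is arbitrary).
Training uses scikit-learn's libsvm binding, deterministic for fixed inputs.

## Parameters

| parameter | meaning | default | rationale |
|---|---|---|---|
| `w ∈ [0,1]` | weight of the order tiers vs composition | 0.2 | CV-selected operating point |
| `λ ≥ 1` | number of correlation tiers (adds λ features) | 6 | CV-selected; larger λ risks high-dimension overfitting |
| `C > 0` | SVM regularization | 512 = 2⁹ | CV-selected |
| `γ > 0` | RBF width | 2⁻⁷ | CV-selected |
| identity threshold | redundancy cutoff | 0.6 | convention of greedy identity filtering of DHS benchmarks |

The joint search (`grid_search` / `DHSModel.select_parameters`) scores every
`(w, λ, C, γ)` by aggregate stratified k-fold CV accuracy (default 5 folds,
seed 0), encoding once per `(w, λ)`. Default grids: `w` stepped 0.1, `λ`
1..10, `C = 2⁻⁵..2¹⁵`, `γ = 2⁻¹⁵..2⁻⁵` (exponent step 1). Ties prefer
smaller `C`, then `γ`, then `λ`, then `w` — the simplest model; the argmax
is therefore independent of grid enumeration order.

## Structural property table

The packaged table (`dhspred/data/dinucleotide_properties.tsv`) holds the
six B-DNA base-pair step parameters — twist, tilt, roll (degrees), shift,
slide, rise (Å) — as consensus crystallographic-survey averages (in the
style of Olson and colleagues' B-DNA compilations), made exactly
strand-symmetric (tilt and shift change sign under reverse complement).
Values are transcribed at two decimals; the encoder z-scores each property
across the 16 dinucleotides (population SD, divide-by-16) before computing
Θ, so units and offsets cancel and only relative geometry matters.
Standardization of an already-standardized table is a no-op; a
zero-variance property is rejected by name. Any table in the same TSV
dialect can be substituted (`--properties`; a `#standardized=true` pragma
marks pre-scaled tables), and trained models record the table checksum and
refuse to predict against a different table.

## Redundancy filtering

Pairwise identity is defined as the matched-base count of the global
alignment that maximizes matches (match 1, mismatch 0, gap 0 — equivalently
the longest-common-subsequence length) divided by the shorter sequence's
length, the identity ratio convention of greedy clustering tools.
Clustering is greedy longest-first (ties by input order): a sequence joins
the first retained representative at ≥ threshold identity, else founds a
cluster. Classes are clustered separately by default so a DHS sequence is
never discarded for resembling background (`--cross-class` overrides).
Caveat: under this max-match definition two *unrelated* random DNA
sequences already share ≈0.65 identity, so thresholds at or below that
merge aggressively; heuristic tools with banded alignments and word filters
behave less aggressively at equal nominal thresholds, which is why exact
reproduction of any published retained-set size is treated as a
compatibility check, not an invariant.

## Evaluation protocols

`compute_metrics` applies the Sn/Sp/Acc/MCC formulas exactly from integer
confusion counts; a zero factor in the MCC denominator reports MCC = 0 with
an explicit degenerate flag. The jackknife holds each sequence out in turn
and retrains on the remainder with `(w, λ, C, γ)` frozen — parameters are
optimized once, beforehand, by CV; re-searching inside each round would
multiply cost by the grid size and leak protocol choices. k-fold uses a
seeded stratified partition; `k = N` is special-cased to singleton folds
(stratification is vacuous there) and reproduces the jackknife exactly,
while otherwise `2 ≤ k ≤` minority-class size is required.

## Synthetic data

The generator emulates the discriminative structure of the real problem —
elevated CC/CG/GC/GG in positives — with first-order Markov chains: the
background transition matrix is uniform; the positive matrix adds a
log-odds boost `δ` to every transition into C or G, renormalized per row.
First-order chains make dinucleotide frequencies directly controllable,
which i.i.d. bases would not. `δ = 0` yields identically distributed
classes; `δ = 3` makes them essentially separable. Default lengths are
drawn uniformly from 200–400 bp, a plausible regulatory-element scale
chosen as a documented arbitrary default. One master seed spawns per-class,
then per-sequence generator streams, so enlarging either class never
changes already-generated sequences.

What the generator does *not* emulate: real DHS length distributions,
genomic k-mer background (CpG depletion, repeats), chromatin context, or
any higher-order composition. Passing synthetic-recovery tests shows the
pipeline recovers a planted dinucleotide contrast; it does not certify
real-genome accuracy, which only the curated benchmark can.

## Numerical and degenerate-input choices

* Sum-to-one tolerance 1e−9; oracle-equivalence tests at 1e−12.
* Sequences shorter than `λ+2` are rejected (aggregated with ids when
  encoding datasets); `L < 2`, non-ACGT residues, and N's are validation
  errors (N-containing records can instead be dropped with a logged count).
* Lowercase input is upper-cased; strand is taken as given.
* Empty dataset → empty encoding/cluster result, not an error; metrics on
  all-zero counts are an error.
* Decision value 0 → positive; grid ties → simplest model (above).

## Known limitations

* **Leave-one-out on signal-free data is not chance-level.** At the
  operating point `γ = 2⁻⁷`, PseDNC vectors are so close together that the
  RBF kernel is nearly constant; the SVM then behaves as a training-set
  majority vote. Under leave-one-out the held-out sequence's class is
  always the training minority, so on a balanced null dataset (`δ = 0`)
  *every* round errs and the jackknife accuracy is 0, not 0.5 — the classic
  LOO/majority pathology. Cross-checks confirm the mechanism: stratified
  5-fold at the same point gives ≈0.4, and a wide kernel (`γ = 64`) gives
  ≈0.5. Interpret below-chance null accuracies as this artifact, not as
  inverted signal; with real class structure (the regime the operating
  point was selected for) the effect is negligible.
* The same near-constant-kernel effect makes tiny toy sets (a few
  sequences) unstable at `γ ≪ 1`; toy demonstrations should use a kernel
  width matched to their feature spread.
* Jackknife cost is N SVM fits (≈1000-sequence benchmarks run in minutes on
  one CPU core; the test suite uses hundreds of sequences to stay fast).
* The shipped property table is a literature-grade consensus, not the only
  defensible choice; conclusions should be robust to swapping in another
  published step-parameter set (the `--properties` flag exists for exactly
  that sensitivity analysis).
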
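# Methods

`conttest` scores a protein multiple sequence alignment (MSA) by how
well residue–residue contacts can be predicted from it.  The premise:
residues in spatial contact co-evolve, so a better alignment of a
protein family yields cleaner covariation statistics and therefore more
accurate de novo contact predictions.  The package implements the full
benchmark loop — truth extraction from a structure, contact prediction
from the alignment, precision scoring, significance testing — together
with the validation machinery (alignment perturbations, guide-tree
imbalance statistics, reference-based sum-of-pairs scoring) and a
synthetic-data generator that makes every stage testable without any
external downloads.

## Contact truth

A contact is a pair of residues whose representative atoms lie within
8 Å (inclusive): the Cβ atom, or Cα for glycine.  Only long-range
pairs count, with sequence separation `j − i ≥ 24` (at least 23
intervening residues); short-range contacts are trivially predictable
from chain geometry and carry no information about alignment quality.
Residues unresolved in the crystal are absent from the coordinate set
and can never enter the contact set.  Both thresholds are parameters
(`threshold_angstrom`, `min_sep`) with the stated defaults.

PDB input is parsed with a minimal fixed-column ATOM-record reader:
first altloc of 'A' or blank wins, common modified residues (MSE, SEP,
PTR, …) map to their parent one-letter codes, unknown residue names
become 'X'.  Author residue numbering is remapped to serial 1..L in
order of appearance so separation filters see consecutive indices;
replicating results for a real PDB entry with author-numbering gaps may
therefore require an offset table.  Non-glycine residues lacking a Cβ
fall back to Cα with a warning rather than being dropped, which keeps
index continuity.

When the aligned target sequence and the structure's sequence differ,
alignment columns are bridged to structure indices by a global pairwise
alignment (BLOSUM62, gap open −11, extend −1, free end gaps so
expression tags and constructs cost nothing).  Substituted positions
are mapped; positions aligned to a gap on either side are unmapped.  A
mapping whose pairwise identity falls below 30% is refused as a
wrong-chain guard (overridable with `force=True`).

## Mean-field DCA predictor

The built-in predictor is a mean-field direct coupling analysis over
q = 21 states (20 amino acids + gap; ambiguity codes B/Z/X and rare
letters count as gap, since they carry no usable frequency
information):

1. **Reweighting.** Sequence s gets weight `1/|{t : id(s,t) ≥ 0.8}|`
   (self included); the weight sum is the effective sequence number
   Meff.
2. **Frequencies.** Weighted single and pair frequencies are blended
   with a uniform pseudocount, `f̃ = (1−λ)·f + λ·f_uniform` with
   λ = 0.5 (`λ/q` per single state, `λ/q²` per pair state; same-site
   blocks keep their diagonal δ-structure).
3. **Couplings.** The covariance matrix over the first q−1 states per
   column (gap is the gauge state) is inverted; the negated inverse
   blocks are the pair couplings `e_ij(a,b)`.
4. **Scoring.** Each column pair is scored by Direct Information: the
   two-site model `P(a,b) ∝ exp(−e_ij(a,b))·μ_i(a)·μ_j(b)` with fields
   μ iterated until its marginals match the single-site frequencies,
   then `DI = Σ P log(P / f̃_i f̃_j)`.

The fixed-point iteration runs to a tolerance of 1e-6 (max 200
iterations).  This tight tolerance is deliberate: it makes DI symmetric
under column exchange and invariant under row permutation to ~1e-9, so
ranked prediction lists are exactly reproducible; a looser 1e-4
tolerance leaves ~1e-9-scale asymmetries that can flip tie-broken
ranks.  Ties in score are broken lexicographically by (i, j).  Columns
are restricted to those mapped to resolved structure residues, and
columns with > 90% gaps are dropped (degenerate inputs otherwise
produce meaningless covariances).  Raw DI is the ranking score; the
average-product correction is available (`DcaParams(apc=True)`) but off
by default.

Two properties of this estimator matter for interpreting the tests.
First, with effectively one observed sequence (all rows identical) the
data covariance vanishes but the pseudocount blend leaves a constant
offset, so every pair receives exactly the same DI — a flat,
uninformative spectrum rather than DI = 0.  Second, DI is *not*
monotone in the underlying coupling strength: under the strong,
near-deterministic covariation the synthetic generator can produce,
the regularized mean-field inversion saturates and DI peaks at
intermediate coupling.  Rankings (and hence precision) are unaffected
in the regimes the tests use, but validation experiments that expect
score *degradation* must operate below saturation (see Perturbation
response).

External predictor output (PSICOV, FreeContact dialects) is parsed by
field-position presets, deduplicated keeping the maximum score, and
optionally reindexed from alignment columns to structure indices.

## Benchmark scoring

Precision@L/5: predictions are filtered to long range (`j − i ≥ 24`),
ranked, and the top `k = floor(L/5)` (minimum 1) compared against the
truth set; `floor` follows the contact-prediction literature's
convention.  If fewer than k long-range predictions exist the missing
ones count as wrong.  Per test case, each predictor's precision is
averaged over alignment replicates (rows reshuffled per replicate)
*first*; the geometric mean across predictors is taken *second*; the
per-method summary is the arithmetic mean of per-case scores.  The
order matters: the summary is not the geometric mean of the
per-predictor summary columns.  The geometric mean is zero whenever
any predictor's mean precision is zero.

Method ranking compares consecutive pairs with the Wilcoxon
signed-rank test on paired per-case scores.  Zero differences are
dropped (Wilcoxon's original rule, rather than Pratt's); tied absolute
differences get average ranks.  For up to 25 effective pairs the null
distribution is computed exactly by subset-sum convolution over the
(doubled, hence integral) ranks — equivalent to full 2^n sign
enumeration but polynomial; beyond that a normal approximation with
tie and continuity corrections is used.  Significance marks use
Bonferroni-corrected levels (0.05, 0.01, 0.001 divided by the number
of consecutive comparisons).

## Perturbation validation

Two corruption operators create alignments that must score worse:

* **shift**: chosen rows are pushed one column out of register
  (prepend '-', truncate the final character);
* **mutate**: chosen non-gap cells are rewritten to a uniformly chosen
  *different* standard amino acid (gaps never created or destroyed).

Subset sizes are `round(fraction · count)`, half-up.  Rows/cells are
selected as a prefix of a seeded permutation: each fraction is a
uniform draw without replacement, and at a fixed seed a larger
fraction perturbs a superset of a smaller one, so dose-response series
share their randomness and are directly comparable.

The validation experiment (`conttest.validation`) runs the full
predict-and-score loop on batches of synthetic cases.  Mutating f of
the residues removes ≈ 2f of the pairwise covariation signal while
shifting f of the rows removes ≈ f, so shift effects per step are
intrinsically several times smaller than mutation effects; the
experiment therefore uses many cases (100) and several perturbation
subsets per case (5), all paired.  Conditions are L = 60, N = 500
sequences, coupling ρ = 0.16, gap rate 0.05: a weak-signal operating
point where baseline precision sits mid-transition (~0.75).  This is a
deliberate choice — at strong coupling the benchmark saturates
(precision 1.0 cannot fall, and the DI estimator is past its
monotone regime), whereas real protein families also operate near the
detection threshold of these methods.

## Tree imbalance

The Sackin score of a rooted strictly binary tree is the sum over
leaves of their depths in edge counts from the root.  Reference
values, with N leaves:

* chained (caterpillar) maximum: `(N+2)(N−1)/2`;
* balanced reference line: `N·log2(N)` — exact only when N is a power
  of two; for other N it dips slightly below the true discrete minimum
  (6·log2 6 ≈ 15.51 vs the actual 6-leaf minimum of 16) and is kept as
  a continuous reference, not a bound;
* Equal-Rates-Markov (Yule) expectation: `2N·Σ_{i=2..N} 1/i`.  The sum
  starts at i = 2 because the growth process starts from the fixed
  2-leaf tree, whose Sackin score is exactly 2; a sum from i = 1 would
  give 6 at N = 2, contradicting the only possible topology.
* Proportional-to-Distinguishable-Arrangements (uniform) expectation:
  computed exactly for N ≤ 12 by a bipartition counting recursion over
  labeled topologies (equivalent to full enumeration; verified against
  it), asymptotically `√π·N^{3/2}`.  The leading constant is
  configurable because some published reference lines use π instead of
  √π; the exact small-N enumeration is authoritative and matches √π.

Chained guide trees are emitted both as Newick caterpillars and in
MAFFT's `--treein` merge-list dialect (unit branch lengths), covering
the two external-tree conventions of the major aligners.

## Reference-based SPS

The sum-of-pairs score of a test alignment against a reference
alignment of an embedded sequence subset is reference-pair recall: the
fraction of residue pairs co-columned in the reference that are also
co-columned in the test alignment.  Residues are identified by their
ordinal within the de-gapped row, so the score ignores gap placement
outside the subset and does not penalize over-alignment.  Subset rows
must carry identical de-gapped sequences in both alignments.

## Synthetic test cases

A case is a toy structure plus an alignment whose covariation sits
exactly at the structure's contacts:

* **Structure**: a self-avoiding random walk with fixed 3.8 Å steps
  (Cα–Cα virtual bond length) confined to a sphere of radius
  3.0·L^{1/3} Å, mimicking globular packing density; minimum pairwise
  distance 2.0 Å; chains are resampled until at least one long-range
  contact exists.  Every 7th residue is glycine so the Cα-fallback rule
  is exercised; the rest are alanine.  Coordinates are rounded to
  0.001 Å at generation so PDB serialization round-trips exactly.
* **Alignment**: a maximal residue-disjoint subset of the true contacts
  is planted (disjointness avoids three-way couplings that the
  two-site model would split).  Unplanted columns are i.i.d. uniform
  over the 20 amino acids.  For each planted pair, each row covaries
  with probability ρ: both letters derive from one latent letter via a
  pair-specific random bijection; otherwise both are independent
  background.  Cells are then gapped i.i.d. at rate 0.05 (default).
  Row 1 is the ungapped target sequence matching the structure.

The bijection-coupling model gives exact, per-pair control of signal
strength at a fraction of the cost of a Potts sampler, which is what
the tests need.  What it does not emulate: phylogenetic correlation
between rows (all rows are exchangeable), realistic amino-acid
composition, indel structure (gaps are i.i.d., no insertions), entropy
variation across columns, or chained indirect couplings.  Passing
tests therefore demonstrate the pipeline's correctness and its
sensitivity to alignment corruption under controlled signal — not
predictive performance on real protein families.

## Problem sizes and determinism

Default experiment sizes — 5 recovery cases at N = 1000, 100
perturbation cases at N = 500 with 5 subsets per fraction, 100 000
Monte-Carlo Yule trees — were chosen so each validation answers its
question with comfortable statistical margins on a single CPU.  All
randomness flows from explicit integer seeds through
`numpy.random.default_rng`; case generators derive per-stage sub-seeds
from a master seed, so every artifact is reproducible byte-for-byte
from its parameters.

## Known limitations

* The mapping from alignment columns to structure residues assumes a
  single chain and serial renumbering; author-numbering offsets in
  real PDB entries are out of scope.
* The mean-field inversion is dense; alignments with thousands of
  mapped columns would need blocked or sparse treatment.
* PSICOV-style sparse inverse covariance estimation is supported only
  through the external-predictions adapter, not reimplemented.
* The ROC-based alternative scoring is not implemented.
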
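# Methods

## Model

A genetic code is a total map from the 64 RNA codons to the 20 amino
acids plus stop; the standard code (SGC) fixes the reference block
structure — the partition of the 61 sense codons into 20 synonymous
sets — and the three stop codons UAA/UAG/UGA. The null ensemble is the
field's standard label-shuffle: random genetic codes (RGCs) keep blocks
and stops fixed and permute only which amino acid labels which block,
uniformly over the 20! assignments. Codes are sampled with replacement;
at ensemble sizes up to 10⁷ the collision probability within a 2.4×10¹⁸
space is negligible and no deduplication is attempted.

For a property vector P over the 20 amino acids and an error model with
codon-pair weights w, robustness is measured by the weighted mean
squared difference MS = Σ wᵢⱼ(Pᵢ−Pⱼ)²/Σ wᵢⱼ over ordered sense-codon
pairs. Weights involving a stop codon are identically zero, as are
pairs the error model cannot produce. MS is invariant to doubling a
symmetric matrix (the weight appears in numerator and denominator) and
transforms as a² under the affine change P → aP + b, so all rank-based
inference downstream is affine-invariant.

### Error models

* **Uniform mismatch (MS1).** wᵢⱼ = 1 for the 263 unordered (526
  ordered) sense pairs differing at exactly one position.
* **Mistranslation (MS2).** A change at codon position p has weight
  Eₚ·κₚ for transitions (A↔G, C↔U) and Eₚ for transversions. Eₚ is the
  relative per-position error frequency (E₂ ≡ 1) and κₚ the
  per-change transition/transversion *rate ratio* — i.e. already
  corrected for the fact that each nucleotide has one transition but two
  transversions; supply the per-change ratio, not the aggregate-rate
  ratio. Defaults are an explicit all-ones placeholder under which
  MS2 ≡ MS1; empirical values (e.g. estimated from *E. coli*
  proteomics) are read from a flat `E1..E3, kappa1..kappa3` config file.
* **Frameshift (MS3).** A +1 shift of codon n₁n₂n₃ followed by n₄
  yields n₂n₃n₄. Each (sense source, next nucleotide) event with a
  sense outcome has unit weight and next nucleotides are equiprobable,
  giving 232 events; −1 shifts induce exactly the transposed matrix and
  hence identical MS (kept only as a test oracle). An event is
  *mismatch-like* when some codon of the source amino acid's block and
  some codon of the outcome amino acid's block differ at one position —
  a block-level definition, applied identically when the event leaves
  the amino acid unchanged. It depends only on the fixed partition, so
  the 121/111 split is the same for every code in the ensemble.
  MS3-like / MS3-unlike restrict the weight matrix to one class.

### Inference

Empirical P = fraction of RGCs with MS strictly below the focal code's;
the focal code is excluded from its own denominator (N−1 for per-code
scans). P = 0 is reported as 0 — no pseudocount — with the resolution
limit 1/N recorded in run metadata. Benjamini–Hochberg step-up
(statsmodels) controls FDR across properties per metric; the per-code
scan uses one sort per property column plus a vectorized row-wise BH,
which the test suite verifies against a naive per-focal recomputation.

Controls for the byproduct hypothesis:

* **MS-matched**: control RGCs have mismatch MS ≤ the SGC's
  (inclusive, so exactly-matching codes count); the reported fraction of
  controls with frameshift MS strictly < the SGC's is the P value of
  "the SGC's frameshift-robustness exceeds what its mismatch-robustness
  predicts".
* **Band**: control RGCs have their mismatch significance count (N₁ or
  N₂) inside a closed interval, by default 80–120% of the SGC's count;
  the fraction with N₃ strictly greater than the SGC's is reported.
  Endpoints are inclusive and compared without rounding.
* **Joint**: intersects several MS-matched constraints (typically the
  top-k properties by cross-talk correlation with the target's MS3;
  k = 4 by default). Control-set size is always reported so the caller
  can judge resolution; an empty control set is an explicit outcome,
  never a silent zero.

Correlation profiles are Pearson correlations across the RGC draws
(the SGC, a fixed point, is excluded); zero-variance columns yield NaN
with a warning. Distribution-level comparisons use scipy:
Kolmogorov–Smirnov between P-value distributions, Wilcoxon signed-rank
between per-property correlation distributions, and a binomial test on
above/below-diagonal property counts.

## Numerical design

Because all codes share the block partition, MS collapses exactly to a
20×20 quadratic form: W_ab aggregates codon-pair weight between blocks
a and b, and MS = Σ W_ab (x_a − x_b)²/ΣW with x the block labels'
property values. The ensemble engine streams over code blocks (2¹⁶
codes per block): for each block it inverts the label permutations,
gathers each metric's W under the inverse permutation into a
(block × 400) matrix, and evaluates all properties at once with a
single matrix product against the flattened (Pₓ−Pᵧ)² table. One million
codes × one property × three metrics takes ~12 s on one CPU core;
10⁴ codes × 564 properties × five metrics takes a few seconds.
Accumulation order is fixed, so results are bit-reproducible given
(seed, block size). One top-level seed drives a single NumPy
`default_rng` stream consumed block-sequentially; the SGC (identity
permutation) is always row 0 and never consumes randomness.

A closed form anchors the ensemble scale: under a uniform label
permutation the labels of two distinct blocks are an exchangeable pair
of distinct amino acids, so E[MS] = (W_between/W_total) ·
mean_{x≠y}(Pₓ−Pᵧ)², where W_between excludes the synonymous
(within-block) weight. The tests check all three metrics against this
within Monte-Carlo error.

## Data formats and conventions

Codons are RNA (T normalized to U on input), indexed lexicographically
over (A,C,G,U); amino acids are keyed by one-letter code, stored
alphabetically, with three-letter codes and full names normalized on
input. Property tables are a TSV dialect (header `property_id` + the 20
one-letter codes in AAindex order) or AAindex flat files; properties
with any missing value are dropped with a logged reason rather than
erroring, since MS requires a complete vector. Code tables serialize to
a 64-row TSV. Ensembles persist as one TSV per metric plus JSON
metadata; reports as per-property, controls, and distribution-test
TSVs plus run metadata.

The packaged demo property is the classic polar requirement scale
(Woese's chromatographic polarity measure, in its standard
literature transcription), shipped as package data rather than
hard-coded so that users can substitute their own tables unchanged.

## Synthetic data

Fake properties are 20 i.i.d. draws per property from U(−1,1) or
N(0,1) — structureless by construction. They emulate the *shape* of a
real property table (dimensions, format, exchangeability of amino
acids) but none of the inter-property correlation or physicochemical
clustering of real scales; a clean fake-property null therefore shows
that the pipeline does not manufacture significance, not that real
properties behave like noise. The default count of 564 matches the
size of the real property collections used in code-optimality surveys,
so null runs exercise the same multiple-testing regime.

## Problem sizes used in the shipped checks

The test suite replicates the polar-requirement analysis at 10⁶ RGCs
and runs the fake-property null at 564 properties × 10⁴ RGCs — sizes at
which the published reference values are resolvable within binomial /
Monte-Carlo error on a single core in seconds to tens of seconds. The
pipeline itself accepts any ensemble size; per-code significance-count
scans (N₁/N₂/N₃ for every RGC) are the one quadratic-cost stage and are
opt-in (`compute_n_counts`).

## Known limitations

* The mistranslation parameters are consumed, not estimated: deriving
  E and κ from proteomics intensity data is upstream of this package.
* Equal codon frequencies are assumed throughout; codon-usage-weighted
  MS variants are out of scope.
* Only the canonical code's block structure and stops are supported for
  the null (no mitochondrial or otherwise rearranged codes, no nulls
  that move stops or break blocks).
* Empirical P values are bounded below by 1/N; claims about P values
  smaller than the ensemble resolution require enlarging the ensemble.
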
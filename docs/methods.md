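# Methods

## Scope and model

`afseq` implements a sequence-only (alignment-free) pipeline for binary
protein function classification — enzymes versus non-enzymes — built from
four components: combinatorial 0D/1D descriptor generation, lattice-walk 2D
descriptors, three-stage supervised feature selection, and a PUK-kernel SVM
evaluated by repeated stratified cross-validation. Structure-derived (3D)
descriptors, four-color-map embeddings and autocorrelation vicinity
operators are out of scope; the AC operator is present only as an interface
stub.

## Descriptor generation (0D/1D)

Each descriptor is the composition of four maps: residue → index value
(encoding), optional vicinity modification, residue grouping, and invariant
aggregation. The identity of each axis:

- **16 indices** (see `afseq/data/aa_indices/`): Kyte–Doolittle hydropathy
  HP, free-amino-acid mass Mw, isoelectric point IP, Levitt helix/sheet/
  turn preferences pa/pb/pt, the three Hellberg–Wold z-scores Z1–Z3,
  electronic charge index ECI, isotropic surface area ISA, polar area Ap,
  superficial free energy dGsU (computed as HP × total accessible surface
  area from the bundled Tien max-ASA table), nonapeptide formation enthalpy
  dHf, and the compatibility parameters L19 and Xi. Four of these tables
  (Ap, dHf, L19, Xi) are **synthetic stand-ins**: their cited sources could
  not be transcribed reliably, so the shipped files hold constructed,
  clearly-labelled per-residue values (`*.synthetic.tsv`). Every table
  records units and provenance in its header; custom tables can shadow
  bundled ones.
- **Vicinity.** The electrotopological-state operator
  `ES_i = I_i + Σ_{j≠i} (I_i − I_j)/(d_ij + 1)²` with `d_ij = |j − i|`.
  Pairwise terms are antisymmetric, so `Σ ES = Σ I` exactly; the test suite
  asserts this to 1e-9 relative and checks the vectorized implementation
  against a naive double loop to 1e-12. Arrays longer than 1024 residues
  switch to an FFT convolution of the `1/(d+1)²` kernel (same quantity,
  O(n log n)).
- **30 groups**: the 20 single-residue groups (three-letter codes), nine
  physicochemical classes — AHR {AVLIM}, ARM {FWYH}, PLR {STNQCY},
  PCG {KRH}, NCG {DE}, CHG = PCG∪NCG, TRN {GPNDS}, SML {GASCT},
  UNC = PLR∪{G} — and the whole protein PRT. The physicochemical
  memberships follow standard partitions of the alphabet; they are
  configurable because reasonable variants exist.
- **17 operators**: N1/N2/N3 (p-norms), Ar/GM/HM/MD (central tendency),
  MX/MN/VA/SK/KU/Q1/Q3/RG/IQ (dispersion and distribution; VA is the
  population variance, SK/KU the standardized third/fourth central
  moments), SE (Shannon entropy of `|x_k|/Σ|x|` in bits). This set
  instantiates the four published operator categories; the exact original
  operator list is not public, so the identity of the 17 is a package
  choice and each is pinned by closed-form unit tests.

Degenerate-input policy, chosen for totality of the feature map: the empty
sub-array maps to 0 under every operator; GM/HM/SE act on absolute values;
GM and HM are 0 whenever a value is 0; SK/KU of a zero-variance vector are
0; quartiles use linear interpolation (inclusive median), which makes the
values bit-reproducible. Columns constant across a dataset carry no
information and are dropped at featurize time (logged), so realized column
counts are dataset-dependent and below the 16 × |mods| × 30 × 17
combinatorial bound.

## Pseudo-fold 2D descriptors

The default lattice partition steps aromatic residues +x, aliphatic
hydrophobic −x, charged +y and the remaining polar/small residues −y; the
assignment is a representation choice and is configurable. The walk starts
at the origin; every lattice point visited becomes a node and revisits
merge. Node weight is the arithmetic mean of the property values of the
residues that landed on the node — consistent with the stated edge rule
(edge weight = mean of its two node weights). The origin hosts no residue
unless revisited; a residue-less node has weight 0 by convention. The
moment series is `μ_k = tr(M^k)`, k = 0..15, computed by repeated matrix
multiplication and verified against eigenvalue power sums to 1e-8
relative. `M` includes node weights on the diagonal by default
(`include_diagonal=False` gives the pure adjacency variant). High-order
moments grow geometrically; `featurize_2d(log_scale=True)` applies
`sign(μ)·log1p(|μ|)` for modelling while raw values remain available for
verification. The default weighting-property set is the 16 bundled
indices.

## Feature selection

- **Discretization** (needed because IG is defined on discrete variables):
  equal-frequency binning on min-ranks, 10 bins by default; ties share the
  lower bin and a constant column collapses to bin 0. Chosen for
  determinism and brute-force testability.
- **IG filter**: IG = H(X) − Σ_j P(y_j) H(X|y_j) in bits from joint counts;
  the threshold is per-feature, `IG ≥ 0.15·H(X)` (the alternative
  cumulative-budget reading of "15% of the total information content" is
  not used). Output ordered by descending IG.
- **Redundancy reduction**: single-linkage clusters = connected components
  of the graph linking pairs with Spearman `|ρ| ≥ 0.95`. The absolute value
  is deliberate — anticorrelated duplicates are as redundant as correlated
  ones — and `absolute=False` restores the signed behaviour. The cluster
  representative minimizes Euclidean distance to the cluster mean in
  z-scored column space (z-scoring makes "closest to centroid"
  scale-invariant); ties break to the earlier feature.
- **Wrapper**: generational GA over bitmasks — population 20, 20
  generations, crossover 0.6, per-bit mutation 0.033 (the documented
  defaults of the genetic-search tool this emulates), fitness-proportional
  selection with one elite, single-point crossover, empty chromosomes
  repaired by setting a random bit. Fitness is the positive-class F1 of a
  PUK-SVM (C = 1, ω = 1, σ = 1 — a portable stand-in for "tool default"
  parameters) in stratified 5-fold CV; fold count auto-reduces with a
  warning when a class is smaller than the fold count. All randomness
  flows from one seed; fitness values are cached by bitmask.

Stages are nested by construction, so subset sizes never increase.

## SVM protocol

The PUK closed form (see README) is unit-tested against hand-evaluated
points and its Gram matrices are checked positive semidefinite. Features
are z-scored with training-fold statistics by default because PUK distances
are scale-sensitive. Cross-validation is 10 runs × 10 stratified folds;
run r draws folds with seed `base_seed + r`; per-run accuracy pools the
fold predictions, and the report is mean ± sd (ddof = 1) across runs —
the run, not the fold, is the unit of aggregation. Standardization is
refitted inside each training fold; nothing is fitted on test folds.
Probability calibration is a logistic regression on out-of-fold decision
values from an internal 5-fold split of the training data; it is fitted by
`train_svm` but deliberately skipped inside `crossvalidate`, where only
hard predictions are scored. Grid tuning maximizes mean CV accuracy and
breaks ties toward smaller C, then ω, then σ. Models serialize to a
versioned JSON archive (support vectors, dual coefficients, scaler,
calibration, feature recipe) so predictions are machine-portable.

## Synthetic data generator

The generator emulates a two-class composition-shift problem: residues
i.i.d. per sequence from a per-sequence frequency vector drawn from a
Dirichlet centred on the class frequencies. Defaults — the study
conditions used throughout the tests and the acceptance script — are 100
sequences per class, lengths uniform on 50–300 (typical single-domain
protein lengths), uniform base composition (keeps analytic expectations
trivial; a proteome-like preset is included), a 3× frequency boost of
G/H/R in the positive class (the residue types most associated with
catalytic function), and Dirichlet concentration 100 (visible
between-sequence compositional noise without swamping the class signal).
What it does *not* emulate: residue-order structure (unless
`plant_motif` inserts a fixed k-mer into positive sequences, which gives
1D descriptors an edge over 0D), domain architecture, phylogenetic
correlation between sequences, and any 3D structure. Passing tests
therefore demonstrate correctness of the machinery and recoverability of
compositional signal, not real-data performance; the external benchmark
reproduction described in the README is the real-data path.

A pipeline run whose selection stage keeps zero features (expected on
label-shuffled data, where no descriptor clears the IG threshold)
degrades to the majority-class baseline and flags it in the result,
rather than failing — a zero-feature model is the class prior.

## Problem sizes and numerical notes

The end-to-end tests and the acceptance script run the study conditions
(200 sequences, ~15 000 descriptors): sizes at which the full pipeline —
featurization, selection, GA wrapper and 10 × 10-fold CV — completes in
about a minute on one CPU while keeping all statistical checks
well-powered. ES conservation is asserted relative to `Σ|I|` (the natural
scale of the cancellation); Spearman correlations of constant columns are
defined as 0; the IG of a feature is clamped at 0 to absorb −0.0
artifacts.

## Known limitations

- Four index tables are constructed stand-ins (see above); descriptor
  values built from them are internally consistent but not literature
  values.
- The exact memberships of the nine physicochemical groups and the exact
  identity of the 17 operators in the original descriptor software are not
  public; ours are declared substitutes chosen to match the published
  category structure.
- The GA wrapper is a stochastic search: different seeds give different
  (similar-quality) subsets.
- Binary classification only; multi-class IG and multi-class SVMs are out
  of scope.
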
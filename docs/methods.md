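# Methods

## Model

A DNA fragment is represented by the physicochemical profile of its
dinucleotides. Twelve normalized scales map each of the 16 dinucleotides
to a dimensionless value; a 2-bp window with 1-bp step converts a fragment
of length L into an (L−1)-component profile per scale, and the twelve
profiles are concatenated property-major (P1 A-philicity first, P12 Z-DNA
last) into a 12·(L−1)-D feature vector — 1788-D for the canonical 150-bp
fragment. The dinucleotide is read on the given strand only; no
reverse-complement averaging is applied.

Classification uses the covariant (quadratic) discriminant: class g is
summarized by mean μ_g and covariance C_g estimated from training rows of
that class, and a query ξ is assigned to argmin_g F(ξ; g) with
F(ξ; g) = (ξ−μ_g)ᵀC_g⁻¹(ξ−μ_g) + ln|C_g|. With equal priors this is
textbook QDA, which the test suite verifies against an independently
implemented oracle; an optional ln-prior term exists but is off by default
because the intended training sets are balanced.

## Property table

The packaged table (`src/nucphyschem/data/dinucleotide_properties.tsv`) is
the canonical constant set. Its source presentation printed the last four
rows with duplicate labels; by the lexicographic enumeration of the first
twelve rows those are unambiguously TA, TC, TG, TT and are shipped
relabeled. The values are described as min-max normalized to [−1, 1], yet
several cells exceed 1 (bendability TA 2.37, TG 2.02, GA 1.24, GC 1.17;
duplex disrupt energy CG 1.45). The printed values are therefore treated
as ground truth and are *not* regenerated by the package's
`normalize_scale` utility, which implements the plain affine rescale
x ↦ 2(x−min)/(max−min) − 1 for user-supplied raw scales. Note that the P1
(A-philicity) and P2 (base stacking) columns are identical as shipped, so
features from those two blocks at the same position are perfectly
collinear — one reason covariance regularization is mandatory.

## Estimation and numerics

* **Covariance divisor**: N−1 (unbiased), consistent with the F-score's
  variance convention. At the intended training sizes (thousands per
  class) the choice is numerically immaterial.
* **Regularization**: covariances are used via a Cholesky factorization.
  If it fails (Ω ≥ N, duplicate columns), ε·I is added with
  ε = 10⁻⁶·trace(C)/Ω, escalating tenfold until the factorization
  succeeds; the total constant applied is recorded on the model
  (`ridge_used`). An explicit user ridge can be supplied on top.
* **log-determinant**: from the Cholesky diagonal
  (2 Σ ln L_ii), never via a raw determinant.
* **Tie-break**: a query with exactly equal class scores is called
  nucleosome. The reported confidence is the raw margin
  F(linker) − F(nucleosome), not a calibrated probability.
* **Ambiguity policy**: encoding rejects non-ACGT bases by default
  ("strict", with the sequence id and offset in the error); the scanner's
  "skip" mode drops windows overlapping ambiguous bases and breaks merged
  runs there.

## Evaluation protocol

Stratified k-fold cross-validation (default k = 5): each class is
shuffled with a seeded generator and dealt round-robin, so per-class fold
sizes differ by at most one. Miss counts are pooled over folds
(micro-average), matching the global-count definitions
Sn = (N⁺−miss⁺)/N⁺, Sp = (N⁻−miss⁻)/N⁻ and
Acc = (N⁺·Sn + N⁻·Sp)/(N⁺+N⁻); Acc = 1 exactly when no sample is
mispredicted.

Per-property evaluation cross-validates each contiguous 149-feature block
alone, giving twelve reduced working spaces for comparing the scales'
individual discriminative power.

## Feature selection

Features are ranked by the two-class F-score (between-class mean
separation over summed within-class variances, variances with divisor
n−1). Degenerate columns with zero variance in both classes score +∞ if
the class means differ and 0 otherwise; ranking ties break by ascending
original index (stable sort). IFS evaluates nested top-k prefixes of the
ranking by cross-validation with **one fold assignment drawn once from the
run seed and reused across all k**, so curve points differ only in the
feature set. The optimal subset is the smallest k attaining the maximal
Acc. The library default evaluates every k; the CLI defaults to a stride
of 4 with the full set always included as the last point, because a full
sweep at 1788 features means thousands of large covariance factorizations.

A protocol caveat, deliberate and worth knowing: the ranking is computed
on the full labeled dataset and the CV folds then share those selected
features. Under a true null this leaks label information and inflates the
curve above chance, which is why the package's own null calibration
(acceptance script, tests) cross-validates *without* selection.

## Synthetic generators

The generators make every stage testable without the original curated
corpus; they are fixtures, not biological models.

* **Gaussian mode** (`gen_gaussian`): two multivariate normals sharing a
  covariance (identity by default); only the chosen informative
  coordinates carry mean separation (±delta·effect/2). True parameters are
  returned with the data, enabling recovery tests and comparison with the
  closed-form optimal accuracy Φ(Δ/2), Δ the Mahalanobis distance between
  the means.
* **Sequence mode** (`gen_sequences`): the positive class is i.i.d.
  uniform ACGT with one of AA/TT/TA/GC planted every 10 bp (fixed phase,
  planting probability = effect_size), mimicking the rotational
  positioning signal of aligned nucleosomal fragments; the negative class
  interrupts the uniform background with 5–10-bp A/T homopolymer runs
  (run-start probability 0.12·effect_size), mimicking the stiff
  poly(dA:dT) tracts of nucleosome-free regions. At effect_size 0 both
  classes collapse to the same uniform background.

Defaults: 200 sequences per class, 150 bp, effect_size 0.8 — a
moderate-separability desk-scale setting chosen once as the package's
study condition. Real nucleosome data differ in ways the generator does
not emulate (GC-content gradients, imperfect fragment alignment, dyad
phasing variability, genome-wide base composition), so passing tests
demonstrate correctness of the machinery and calibration of the
statistics, not field accuracy on real chromatin.

## Scanner

Window #w (1-based, w = 1 … L−149) covers sequence positions w … w+149;
consecutive equal-label windows merge into segment calls, with no further
smoothing, so expanding the calls reproduces the per-window labels
exactly. BED export uses 0-based half-open [w−1, w+149) spans.

## Problem sizes

The test suite and acceptance script run the pipeline at 60–200 sequences
per class and 10–60 Gaussian features, with the IFS sweep on a coarse
k-grid — sizes chosen so a complete run takes minutes on one core while
every statistical assertion still has power. The full-resolution sweep
(stride 1 over all 1788 subset sizes) remains available through the
library and CLI.

## Known limitations

* The shipped constants cannot be re-derived from the stated min-max
  normalization (values > 1); they are trusted verbatim.
* The exact covariance divisor and fold construction of the original
  protocol are not recoverable; N−1 and one reused stratified split are
  this package's documented choices, so an IFS peak position need not
  reproduce exactly.
* Forward-strand encoding only; no support for IUPAC ambiguity codes
  beyond rejecting or skipping them; no probability calibration of the
  margin.
* The curated 10,000-fragment yeast benchmark is journal supplementary
  material and is not redistributed; the corresponding reproduction test
  fails with an explanatory message unless the user supplies the files
  under `data/benchmark/`.
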
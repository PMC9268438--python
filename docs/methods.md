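# Methods

## Problem and data model

The task is to assign ginseng batches to their cultivation province
(JL, LN, HLJ) from aligned LC-MS peak areas of characteristic
ginsenosides, and to find a small set of *quality markers* — peaks
whose abundance pattern carries the origin signal. The package
operates on per-sample peak lists (m/z in Da, retention time in
minutes, integrated area in counts, charge state, a 0–100 peak
quality score) and on the samples × features area matrix produced by
alignment. A zero in the matrix means *not detected*; no imputation
is performed anywhere, on the grounds that a Z-scored zero behaves as
a genuinely low abundance.

## Preprocessing

* **Screening** keeps ions with area strictly above 1000 counts,
  charge exactly 1, and quality score strictly above 60. The strict
  inequalities are deliberate ("exceeding", "greater than"); a peak
  at the threshold is removed, and the operation is idempotent.
* **Alignment** is greedy area-descending centroid clustering. All
  peaks across samples are processed from largest to smallest area
  (ties by ascending m/z, RT, sample id, making the procedure fully
  deterministic); a peak joins the nearest existing feature within a
  relative m/z window (default 10 ppm) and an absolute RT window
  (default 0.2 min) that does not yet contain a peak from the same
  sample, else it founds a new feature. Consensus coordinates are
  presence-weighted running means. Because larger peaks are placed
  first, when one sample has two candidates for a feature the larger
  one wins. The m/z tolerance is relative and the RT tolerance
  absolute, the usual LC-MS convention.
* **Common-peak filter**: features missing in strictly more than
  80 % of samples are dropped; a feature missing in exactly 80 % is
  kept. Setting the threshold below 1/n forces presence in every
  sample, the stricter reading of "common peak" some workflows use.
* **External batches** are never re-aligned de novo; they are
  projected onto the training feature set (for each feature and
  sample, the largest-area peak within the windows). This keeps
  columns identified with the trained model by construction, which
  matters because independently aligned tables can order or merge
  near-coincident features differently.
* **RSD** (repeatability of QC injections) is 100·sd/mean with the
  n−1 standard deviation.

## Annotation

Molecular formulas are parsed to element counts and summed over
monoisotopic masses (C = 12 exactly, H = 1.0078250319,
O = 15.9949146221, N = 14.0030740052 Da). Ginsenosides ionize in
negative mode mainly as [M−H]⁻ and [M+HCOO]⁻; the default adduct
arithmetic is physically complete (an anion carries one extra
electron, mₑ = 0.0005486 Da), with a `neutral` convention switch
because published tables are not always consistent about the
electron. Features match a reference record when the signed ppm error
against the record's theoretical adduct m/z is within tolerance
(default 15 ppm) and the RT difference within 0.5 min; isomers share
a formula and are disambiguated chromatographically. Diagnostic
aglycone fragments classify compounds into the protopanaxatriol
(475.38), protopanaxadiol (459.38) and oleanolic-acid (455.35)
families within a 0.05 Da window (Q-TOF accuracy scale), precedence
PPT > PPD > OA.

The packaged database transcribes the 69 characteristic ginsenosides
of the source study (name, formula, measured adduct m/z, ion type,
published ppm error, MS/MS fragments). Three entries were corrected
for internal inconsistencies where the printed formula or ion type
contradicts the printed m/z by thousands of ppm while a sibling entry
of the same compound shows the intended value; each correction is
recorded in the CSV's `notes` column. With these corrections every
record's printed m/z is within 15 ppm of theory (largest error
+11 ppm, an outlier the source itself prints).

## Normalization and baselines

*Mean normalization* divides each feature by its across-sample mean;
*Z-score normalization* centers and scales each feature to mean 0 and
unit **population** standard deviation (the intent is a standard
normal scale; an `ddof=1` variant is available). Both store their
training statistics so external data can be transformed without
re-estimation. PCA diagonalizes the sample covariance of the centered
matrix with a deterministic sign convention (largest-magnitude
loading entry positive). PLS-DA decomposes X = T P′ + E against the
column-centered one-hot class matrix Y = T Q′ + F by NIPALS
(covariance-maximizing latent scores, deflation after each
component); the default component count is n_classes − 1 = 2. R²Y is
1 − ‖F‖²/‖Y꜀‖²; Q² is 1 − PRESS/‖Y꜀‖² from seeded stratified ten-fold
cross-validation. The permutation test refits the model under label
shuffles and regresses (R²Y, Q²) on the absolute correlation between
permuted and original one-hot labels, reporting the intercepts at
correlation 0 — the common chemometrics convention.

## SVM

The binary soft-margin dual is solved by sequential minimal
optimization with maximal-violating-pair working-set selection
(the LIBSVM-style rule): the coefficient pair with the largest KKT
violation is updated analytically under the box [0, C] and the
equality Σαy = 0, until the violation falls below `tol` (default
1e−4). The bias averages y − Σαy K over the free support vectors
(0 < α < C), which sit exactly on the margin; if none are free it is
the midpoint of the feasible interval. The decision function is the
kernel expansion; the primal weight vector is only materialized for
the linear kernel. A numba-compiled twin of the solver is used when
available; it is iterate-for-iterate identical to the NumPy
reference (a unit test asserts bitwise-level agreement), so results
do not depend on which backend runs.

Multi-class problems use one-vs-one voting, ties broken by summed
decision values then class order. Hyperparameters default to the
study's choice (C = 1, γ = 0.03, RBF); the grid search spans
C ∈ 2⁻⁵…2¹⁵, γ ∈ 2⁻¹⁵…2³ in log₂ steps of 2 and breaks accuracy ties
toward the smallest C then the smallest γ (prefer the most
regularized cell of the plateau). Cross-validation is stratified,
seeded, and deterministic: per class, indices are shuffled once and
dealt round-robin; every sample is predicted by a model that never
saw it, and training-set reports can alternatively be produced by
resubstitution (`report_mode="resubstitution"`).

## Permutation importance and markers

The importance of feature *k* is imp*k* = s − (1/N) Σₙ s*ₖ,ₙ*, where
s is the baseline score and s*ₖ,ₙ* the score after independently
permuting column *k* (N = 10 repeats by default; the raw-sum variant
is available via `aggregate="sum"` but is dimensionally awkward for
N > 1). The default scorer is the mean stratified ten-fold CV
accuracy of the SVM configuration, with the model refit inside every
evaluation — the conservative choice — and the fold assignment held
fixed so that score changes are attributable to the permutation
alone. For the default scorer the Gram matrix is maintained
incrementally under single-column permutations (updating the pairwise
squared distances for RBF, the inner products for linear), which
makes the n_features × N evaluations cheap without changing results.
Markers are the features with strictly positive importance (IV > 0),
reported in descending order; the model is then re-fit on the markers
alone with a fresh grid search, and external samples are predicted
after transforming them with the training normalization statistics.
Reported accuracies are truncated integer percents (26/31 prints as
83, not 84), matching the convention of the published tables.

## Synthetic data

The generator emulates the study design: three origin classes
(default 10 samples each; the real design's unbalanced 19/4/8 split
is available by passing a tuple), 69 features, 6 planted
origin-discriminative features, log-normal peak areas. Feature areas
are exp(log_mu + class shift + N(0, log_sigma)) · scale, with:

* `log_mu = 11` (typical areas ≈ 6·10⁴ counts, comfortably above the
  1000-count screen),
* `log_sigma = 0.3` — about 30 % between-batch biological CV, a
  typical figure for plant secondary metabolites (instrument
  repeatability is far tighter, ~2 % area RSD in QC injections),
* `scale_spread = 1e3` — per-feature scales drawn log-uniformly over
  three orders of magnitude, the property that makes raw-area RBF
  classification collapse and Z-scoring effective,
* `missing_prob = 0.02` — independent Bernoulli dropout to zero,
  modelling sporadic non-detection among peaks that already passed
  the common-peak filter,
* class structure: the informative features are split into three
  disjoint groups and each class shifts its own group upward by
  `effect_size` log units (per-class multipliers are exposed), so
  every class is separable from both others,
* m/z–RT coordinates drawn uniformly over the instrument ranges
  (400–1700 Da, 1–32 min), or — with `reference_coordinates=True` —
  sampled from the packaged ginsenoside database (restricted to
  mutually resolvable entries: a pair closer than 20 ppm *and*
  0.4 min, such as two real isobaric co-eluting records, would
  scramble alignment) so that synthetic features are annotatable,
* per-occurrence measurement jitter (≤ 5 ppm, ≤ 0.05 min, uniform)
  for exercising alignment.

Structure (coordinates, scales, informative set, shift pattern) is
drawn from the spec seed alone; per-sample noise comes from a
separate `sample_seed`, so held-out test batches from the *same
population* are generated by changing only `sample_seed`. Ground
truth is always returned.

**What the generator does not emulate** — correlated abundances
(pathway co-regulation, shared injection-amount variation), RT drift,
peak-shape or isotope structure, and class-informative signal spread
over many features. Consequences for interpreting test results are
discussed under *Limitations*.

## Numerical choices

Tolerances: SMO KKT tolerance 1e−4 (tests allow 10·tol on margin
equalities); NIPALS convergence 1e−10 relative with a 500-iteration
cap; PCA/PLS identities asserted at 1e−8; Z-score idempotence at
1e−9. Degenerate inputs raise informative errors: zero-mean or
zero-variance features in normalization (named by feature id),
single-class label vectors, empty marker sets, missing marker columns
in external tables (named by marker). Grid-search ties and vote ties
have documented deterministic tie-breaks. All stochastic stages take
explicit seeds; the pipeline derives stage seeds from a master seed
via a fixed `SeedSequence([master, counter])` scheme, and two runs
with the same config are byte-identical (checksummed manifests).

## Design notes

* The alignment algorithm is unspecified in the source workflow
  (done there by vendor software); greedy area-descending centroid
  clustering was chosen because it is deterministic, order-independent
  given distinct areas, and standard in open implementations.
* Formula ambiguities resolved: Z-scoring is applied per feature
  across samples; the permutation-importance aggregation is read as a
  mean over repeats; the permutation-test intercept convention is the
  regression-through-all-points one.
* The scorer refits the model for every permuted matrix rather than
  scoring a fixed model; both are defensible, refitting is the more
  conservative (it credits a feature only if the *class of models*
  needs it).

## Limitations

* **IV > 0 over-selects on this synthetic geometry.** With 63
  independent unit-variance noise features at n = 30, every model on
  the (C, γ) grid leaves a few out-of-fold samples with functional
  margins smaller than the perturbation a single-column permutation
  induces, so null features acquire small positive importances and
  strict IV > 0 admits many of them (precision is low even though
  the planted features rank at the very top — see the worked example,
  where the top six by importance are exactly the six planted
  features). The published workflow reported exactly six markers on
  real data, which plausibly reflects strongly correlated
  class-informative peaks and a flip-robust 100 % CV ceiling that
  independent synthetic noise cannot reproduce. Users who need a
  small panel should take the top of the ranking rather than rely on
  the sign threshold.
* Z-scoring caps the achievable class separation of a shifted-subset
  feature at √((1−p)/p) ≈ 2.1 standardized units (p = fraction of
  samples shifted), independent of the raw effect size; passing
  tests on synthetic data therefore certify the machinery, not
  real-data accuracy figures.
* The published R²Y = 0.87 / Q² = 0.56, the 33 % PCA variance share
  and the 0.371/0.277 permutation intercepts depend on the
  undeposited raw data and are treated as context, not targets; the
  package reports its own synthetic-data analogues.
* Peak lists are taken as given (vendor raw-file parsing, RT
  warping, isotope grouping and MS/MS spectral scoring are out of
  scope).
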
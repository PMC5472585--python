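# Methods

## What the package computes

`rxnaudit` asks, for a corpus of organic reactions with reported outcomes,
whether a binary outcome (high/low yield, slow/rapid reaction) is predictable
from a given feature representation — and when it is not, whether the
residual error is the classifier's fault or intrinsic to the representation.
The audit has four parts:

1. **Data preparation** (`reaction_io`): reaction SMILES parsing, rejection
   of unusable records with reason codes, agent-insensitive deduplication,
   and strict-threshold binary labeling.
2. **Feature families** (`descriptors`, `fingerprints`, `cld`): ~200
   whole-molecule descriptors per side (substrates, products) plus solvent
   and temperature; signed atom-pair difference fingerprints folded to a
   fixed length; and binary maximum-common-substructure ("chemical word")
   features.
3. **Classifier curves** (`classify`): random-forest / extremely-randomized
   trees / L1-logistic misclassification rates under stratified four-fold
   cross-validation, traced against the number of features and the number
   of reactions.
4. **Irreducible-error bracketing** (`bayes_bounds`): the Cover–Hart
   nearest-neighbor bracket on the Bayes error R*,

       (1 − √(1 − 2·R_NN)) / 2  ≤  R*  ≤  R_NN        (binary),

   with R_NN the leave-one-out 1-NN error on standardized features. If the
   cross-validated error is close to the bracket, no classifier on the same
   features can do much better: the error is irreducible.

## Data-preparation rules

* A reaction SMILES must contain exactly two `>` separators, at least one
  reactant and one product; every component must parse. Records that report
  neither yield nor time, out-of-range yields (outside [0, 100]) or
  non-positive times are rejected with a logged reason code.
* The dedup key is the pair (sorted canonical reactant SMILES, sorted
  canonical product SMILES). Agents, solvent and temperature are ignored:
  the same transformation reported under different conditions counts as a
  duplicate report. Among duplicates the most favorable outcome survives —
  the highest yield, or the shortest time.
* Labels use a strict inequality, label = 1 iff value > threshold, so a
  median threshold puts the median record itself in the low class. Defaults:
  65 (% yield; a typical corpus median) and 12 (h; the boundary between
  well-specified times and "left overnight" reports). For time the positive
  class is SLOW. The sample median uses the lower-middle convention for even
  n. Both choices are config-overridable; neither is forced by the science,
  so they are fixed once and documented here.

## Feature construction

* **Descriptors.** The default list is rdkit's descriptor collection minus
  `qed`, `SPS`, `Ipc`, `AvgIpc` and the `BCUT2D_*` block (post-hoc additions
  to the classic set, numerically fragile on odd inputs, and the costliest
  entries) — 198 names. Multi-molecule sides are aggregated by elementwise
  SUM: sums preserve the extensivity of count-type descriptors and match the
  fingerprint convention below. Failed or non-finite values become 0 and are
  counted per column. Agents contribute no descriptor block; conditions
  enter as an integer solvent code (vocabulary learned on the training
  split; unseen solvents map to a reserved `unknown` code) and temperature
  in °C (training-median imputed).
* **Fingerprints.** Atom-pair features (atom type, atom type, topological
  distance ≤ 3 bonds), with the classic atom typing: element, aromaticity
  flag, heavy-neighbor count. The reaction fingerprint is Σ reactants − Σ
  products as signed counts; folding maps index i to i mod L (L = 256 by
  default) and sums collisions, which conserves the signed total and is
  linear. Counts stay signed through subtraction; a binary clamp exists but
  is off by default. The native index space is the triangular pair encoding
  over 2048 type codes × 3 distances (~6.3M); only the folded behavior
  matters downstream.
* **Chemical words (CLDs).** The maximum (by atom count) connected common
  substructure of sampled molecule pairs, mined with rdkit's FMCS engine:
  elements must match, bond orders must match exactly (aromatic distinct
  from single/double), ring-bond matching not enforced, minimum word size 3
  heavy atoms. Patterns are aggregated by canonical form and ranked by
  frequency; ties in atom count among maximal candidates are resolved by
  the engine, which is deterministic run-to-run but not guaranteed
  lexicographic. CLD features are binary presence of the top-K words in any
  reactant or product. Pair sampling is uniform without replacement and
  seeded; a vocabulary is a pure function of (molecules, n_pairs, seed).

## Cross-validation protocol

Stratified four-fold splits; the model trains on three parts and is scored
on the fourth; fold errors are averaged. When feature selection is active,
features are re-ranked by |point-biserial correlation| with the label
*inside each training fold* — no test-fold information reaches selection,
solvent vocabularies or penalty tuning (a leakage test reconstructs the
per-fold selections from training rows alone). A `selection_scope="global"`
switch reproduces the leaky protocol for sensitivity checks only. Rows are
processed in row-id-sorted order, making results invariant to input
permutation. Subsamples for size curves are stratified, seeded and nested,
so curves reflect sample size rather than resampling noise.

Model defaults: 500 trees, √p features per split, unlimited depth; ERT
identical but with random split thresholds; L1-logistic with the penalty
chosen by 3-fold internal CV on the training folds. All exposed in
`ModelSpec`. Tests and the acceptance script run 50–100-tree forests: at
the audit's problem sizes (n ≤ 20,000, p ≈ 400) the fold errors of 100 and
500 trees agree to well within the fold-to-fold spread, at a fraction of
the single-CPU cost; problem sizes per experiment are stated in the test
and script docstrings.

## Bayes-error bracketing

R_NN is computed exactly by chunked brute-force Euclidean distances on
per-feature standardized columns (zero mean, unit variance; constant
columns pass through). Determinism is total: distance ties resolve to the
lower row index, tied k-votes to class 0. Leave-one-out is used rather than
held-out splitting for its lower variance at desk-scale n. The Cover–Hart
bracket is asymptotic; at finite n the NN error is biased upward (the
curse-of-dimensionality regime), which widens the bracket upward rather
than invalidating the lower bound — the calibration experiment quantifies
this on analytic ground truth. k-NN (k > 1) is available; the bracket then
still uses the conservative 1-NN form, and estimates are labelled with the
estimator that produced them. The multi-class lower bound
((c−1)/c)(1 − √(1 − cR/(c−1))) is provided for completeness.

## Synthetic study conditions

Real audit corpora (reaction databases) are proprietary, so the study
conditions are synthetic with known answers:

* **Gaussian oracle**: two unit-variance classes at ±δ/2 on the first of d
  axes; Bayes error Φ(−δ/2) for equal priors (closed form for unequal
  priors). Defaults d = 5, δ = 2, n = 20,000 — a regime where the
  leave-one-out NN error is near its asymptote, so bracket calibration is a
  test of the estimator, not of finite-sample slack.
* **Planted reaction corpus**: substrates are alkyl chains (2–8 carbons)
  decorated with up to ten signal fragments (nitrile, nitro, carboxylic
  acid, benzene, pyridine, thiol, hydroxyl, amine, ketone, ether), each
  independently present with probability ½, plus label-neutral distractors
  (halogens, methyl). Products append a terminal group via one of three
  templates (chlorination, bromination, hydroxylation). The hidden label is
  a threshold on the signed fragment count with ±1 weights; signs pair
  chemically related fragments oppositely so that aggregate descriptors
  (molecular weight, total carbonyl/aromatic/H-donor counts) carry no
  signal and the planted information lives in fragment-specific columns.
  Observed labels flip with probability ε, which is then exactly the Bayes
  error of the observed labels (a finite logistic effect size is available,
  with the resulting Bayes error computed in closed form from the discrete
  score distribution). Yields are back-generated (class 1 uniform on
  [70, 100], class 0 on [0, 60]) so the 65-threshold labeling reproduces
  the planted labels exactly; times are log-uniform on [0.25 h, 96 h] —
  the heavy right tail of "left overnight" reporting — and deliberately
  uninformative. Duplicate reports (same RSMI, perturbed same-class
  outcome) and missing solvent/temperature/time fields are injected at
  stated rates. Substrate/template pairs are unique by construction, so
  dedup arithmetic is exact.
* **Messy CSV**: a seeded mixture of valid rows, malformed RSMI,
  unparseable SMILES, missing-outcome rows, out-of-range yields and
  conflicting duplicate reports, with a manifest computed from generator
  bookkeeping (never by running the cleaning code) stating every expected
  count.

What the generators do NOT emulate: real reaction-class frequency
distributions, condition–outcome interactions, stoichiometric imbalance, or
descriptor distributions of drug-like molecules. Passing tests therefore
demonstrate correctness of the machinery and of the irreducibility logic on
controlled truth — not that any particular real corpus is (un)predictable.

## Informative-feature recovery under collinearity

Real descriptor sets are collinear: several named descriptors count the
same structural motif, and a few surface-area bins happen to be exact
affine functions of a single fragment's presence on this scaffold grammar.
"Recovery" of planted signal by correlation ranking is therefore measured
against the full informative set of the realized feature matrix — every
column whose values coincide (|r| ≥ 0.9999) with a planted fragment
indicator (`synthetic_data.informative_columns`), about 43 columns for the
default grammar — not only the ten canonical fragment descriptors. A
name-level recall against the canonical columns alone would penalize the
ranking for preferring an exact alias, which carries identical information.

## Numerical choices and degenerate inputs

* Point-biserial correlation of a constant column is defined as 0 (ranked
  last, ties by column name).
* PCA components follow the sign convention "largest-magnitude loading
  positive"; scores are computed on standardized columns.
* RF regression folds are rank-stratified on the target, then shuffled
  within strata; RMSE is pooled over all held-out predictions.
* Single-atom molecules have empty atom-pair fingerprints (no pairs) — not
  an error. Identity reactions give exactly empty difference fingerprints.
* `fold` requires L ≥ 1; the empty fingerprint folds to the zero vector.
* MCS timeouts return the best-so-far substructure flagged `approximate`.
* A constant regression target returns RMSE 0 with a warning.

## Known limitations

* The Cover–Hart bracket is asymptotic; on small high-dimensional samples
  the upper bound (R_NN) inflates. Curves over dataset size make this
  visible rather than hiding it.
* The MCS tie-break among equal-atom-count candidates is engine-internal;
  only the atom count, matching rules and determinism are contractual.
* The scaffold grammar keeps molecules small and oracle-enumerable by
  design; fingerprint folding collision rates on it are not representative
  of diverse drug-like corpora.
* No 3D/conformer or quantum-chemical descriptors — deliberately out of
  scope: the audit's question is what the standard connectivity-level
  representations can support.
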
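# Methods

## PseAAC encoding

The encoder implements type-II (amphiphilic) pseudo amino acid
composition. Six physicochemical scales are shipped as a versioned TSV
asset (`src/acescreen/data/property_scales.tsv`): a Tanford-derived
hydrophobicity scale in the form conventional for PseAAC work, Hopp–Woods
hydrophilicity, side-chain mass, and α-carboxyl pKa (pK₁), α-amino pKa
(pK₂) and isoelectric point (pI) at 25 °C from standard biochemistry
tables. Each row carries its literature source in the file header, and
`load_property_table` accepts any substitute TSV with the same layout, so
the scales are data, not constants baked into code.

Numerical conventions, all of which change downstream values and are
therefore pinned:

- **Standardization** uses the population (divide-by-n) SD over the 20
  residues, not the sample SD.
- **Correlation factors** are mean *products* `H(R_j)·H(R_{j+m})` — the
  amphiphilic form — not the squared differences of type-I PseAAC.
  They are signed; the feature vector still sums to 1 because the same
  normalizer `1 + ω Στ` divides both blocks.
- **Block order** is lag-major, property-minor (all six properties at
  lag 1, then lag 2, …). Irrelevant at the default λ = 1 but pinned for
  deeper correlations.
- **Defaults** λ = 1, ω = 0.05, six properties → 26 dimensions.
  ω balances composition against order information; at ω → 0 the vector
  degenerates to plain amino acid composition.
- **Degenerate inputs:** peptides shorter than λ + 1 cannot supply a
  lag-λ pair and are skipped with a report (`encode_batch`) or raise
  (`encode`). A blending denominator within 1e−8 of zero raises; with
  ω = 0.05 and λ = 1 this cannot occur for real scales (|τ| is bounded
  well below 1/(6ω) ≈ 3.3 per property in practice) but the guard is
  kept for user-supplied scales.

The encoder is verified against a brute-force oracle (explicit loops over
`str.count` frequencies and pairwise products, independent of numpy and
of the implementation) to 1e−12 on random peptides.

## Datasets and negative sampling

Negatives are contiguous fragments of background proteins, not whole
entries: full-length proteins are two orders of magnitude longer than
typical ACE-inhibitory peptides (2–12 residues), so only fragment
sampling can honor the requirement that negatives match the positives'
average length. Fragment lengths are drawn from the positives' empirical
length distribution; the achieved mean is checked post hoc (warning
beyond 10% deviation) rather than enforced by resampling. Rejection
sampling (budget 1,000 attempts per negative) enforces that no negative
equals a positive or another negative; exhausting the budget raises
rather than looping forever on tiny pools. Disjointness of I⁺ and I⁻ and
within-label uniqueness are re-validated by the `LabeledDataset`
constructor itself, so no code path can emit a violating dataset.

## The synthetic benchmark

The generator emulates one well-established feature of real
ACE-inhibitory peptide sets: their residue composition. Positives are
drawn i.i.d. per residue from a law with Pro = Leu = 0.12 and
Cys = Met = Trp = 0.01 (remaining mass uniform over the other 15
residues); negatives from a uniform 0.05-per-residue background. Both
classes share one length law over 2–15 residues with its mode at 3–8 and
mean ≈ 6, matching the short lengths that dominate curated inhibitor
sets. Sampling is deterministic per seed.

What the generator does *not* emulate: positional motifs (real ACE
inhibitors favor Pro/aromatic residues at the C-terminus), sequence
dependence between neighboring residues, database redundancy/homology
structure, and label noise. Passing benchmarks on this generator
therefore demonstrate that the pipeline is wired correctly and can
extract a compositional signal — not that real-data accuracies of any
particular level will be reached.

An i.i.d.-composition generator also has a computable performance
ceiling: the optimal classifier is the summed per-residue log-likelihood
ratio, whose AUC is Φ(0.384·√L) at length L under the default laws,
≈ 0.83 averaged over the length mixture (and ≈ 0.82 for any classifier
restricted to the 26 PseAAC features, which discard length). Observed
cross-validated AUCs — roughly 0.73 (k-NN) to 0.80 (random forest) at
800 instances — sit where small-sample estimation on a ceiling of that
height puts them. Stronger benchmark numbers would require either longer
peptides or stronger enrichment, i.e. a different synthetic condition,
not a better implementation.

## Classifiers

Hyperparameters are fixed (no search is performed; re-tuning them is a
non-goal): gradient-boosted trees with learning_rate 0.01, n_estimators
1000, max_depth 4, min_child_weight 1, gamma 0, subsample 0.8; RBF SVM
with C 1.0 and gamma 0.001; random forest with n_estimators 80, max_depth
13, min_samples_split 150, min_samples_leaf 15, max_features 7 (features
considered per split), oob_score on, random_state 10; k-NN with K 5.

Notes on the defaults:

- The forest's split limits (min_samples_split 150) are sized for
  datasets of a few thousand instances; below ~300 training instances
  the trees cannot split at all and the forest degenerates to the class
  prior. Tests on small fixtures override these two parameters.
- The SVM produces probabilities through explicit Platt-style sigmoid
  calibration (`CalibratedClassifierCV(SVC(), method="sigmoid", cv=5,
  ensemble=False)`). libsvm's built-in estimates collapse to a constant
  0.5 here because at gamma 0.001 the decision values span only ≈ ±0.03.
  Calibration keeps the uniform 0.5 decision threshold meaningful for
  every family.
- k-NN probabilities are the fraction of positive labels among the K
  nearest neighbors; equidistant neighbors are resolved by training
  input order (scikit-learn's behavior), which fixes the tie-break.
- Determinism: every family yields identical probabilities when refit
  with the same seed and inputs; a SHA-256 fingerprint of (features,
  labels, seed) is stored on each fitted model.

## Evaluation

Folds are stratified (the datasets are balanced by construction, and
stratification removes needless fold-to-fold class-ratio variance) and
partition the data exactly. Peptides are encoded once before splitting:
the encoding of a peptide depends only on its own sequence and fixed
property scales, so pre-encoding cannot leak test information into
training. The decision threshold is strictly greater-than 0.5; a
probability of exactly 0.5 is a negative call. Metrics with zero
denominators (e.g. precision when nothing is called positive) are
reported as undefined and excluded from means with a warning — zeroing
them would silently bias confidence intervals. The 95% CI is the normal
approximation 1.96·SD/√n with sample SD over fold (or repeat) values;
raw per-fold values are always retained in the report for re-analysis.
AUC and ROC points come from scikit-learn and are cross-checked in the
test suite against an O(n²) pair-counting oracle with ties counted ½.

The cross-dataset protocol reports the sequence overlap between training
and test sets rather than forbidding it, since legitimate uses include
partially overlapping database snapshots; a 100% overlap is flagged.

## Screening

"Cutting" a protein means exhaustive linear sliding-window extraction of
every substring of length 2–9 (for length L ≥ 9 that is 8L − 36 windows;
duplicated sequences are scored once). Circular cutting was considered
and rejected — these proteins are linear. Coordinates are 1-based
inclusive, following UniProt convention, and every emitted k-mer
re-extracts exactly from its recorded coordinates. Full-entry sequences
(including signal peptides) are screened; mature-chain trimming is left
to the caller.

The candidate rule is deliberately conservative: the model is retrained
`n_repeats = 3` times with distinct seeds and a k-mer qualifies only if
its positive probability exceeds 0.99 in every run, filtering out scores
that depend on training stochasticity. Control bins collect k-mers whose
probabilities all round, at two decimals (±0.005), to 0.00 (confident
negatives) or 0.50 (maximally uncertain) — useful contrast groups for
downstream validation such as docking. Lowering the candidate threshold
can only add candidates (monotonicity is property-tested).

## Problem sizes

The shipped tests and the acceptance script run the benchmark at 400
positives + 400 negatives, screening at a few synthetic proteins of
120–150 residues (1,000–3,500 k-mers), and oracle checks at 200–1,000
random instances — sizes chosen so the full pipeline, including four
cross-validated families, completes in well under a minute on one core
while leaving every statistical conclusion stable across seeds.

## Known limitations

- Peptide–protein docking, IC50 regression and any wet-lab validation
  stage are out of scope; the screening output is a ranked shortlist.
- The shipped property values are standard published scales; other
  PseAAC implementations using different hydrophobicity variants will
  produce numerically different (though similarly behaving) features.
- Binary labels only; no multiclass or activity-strength support.
- The synthetic benchmark bounds what can be claimed about real-data
  performance (see above); users with access to curated databases
  (BIOPEP-UWM, FeptideDB, BioPepDB) should build real datasets with
  `build_dataset` against a UniProt background pool.
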
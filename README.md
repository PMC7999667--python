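# acescreen

A toolkit for predicting antihypertensive (ACE-inhibitory) peptides and
screening proteins for new ones. Food-derived peptides that inhibit the
angiotensin-converting enzyme (ACE) lower blood pressure; curated databases
list a few thousand of them, and the practical question is which of the
myriad short fragments of a food protein — milk caseins are the classic
source — are likely inhibitors. `acescreen` answers it with a classical
machine-learning pipeline aimed at bioinformaticians and food scientists who
want a reproducible, scriptable screening stage before wet-lab validation.

## The method

**Encoding.** Each peptide `R₁R₂…R_L` becomes a type-II (amphiphilic)
pseudo amino acid composition (PseAAC) vector. With residue frequencies
`f_u` (u = 1…20) and, for each of six physicochemical scales
(hydrophobicity, hydrophilicity, side-chain mass, pK₁, pK₂, pI)
standardized to zero mean and unit population SD over the 20 residues,
the lag-λ sequence-order correlation factors

    τ_{p,m} = (1/(L−m)) Σ_{j=1}^{L−m} H_p(R_j) · H_p(R_{j+m}),   m = 1…λ,

the feature vector is

    x_u      = f_u / (1 + ω Σ τ),          u ≤ 20
    x_{20+j} = ω τ_j / (1 + ω Σ τ),        j = 1…6λ,

which sums to 1 identically. At the defaults λ = 1, ω = 0.05 this is a
26-dimensional vector.

**Datasets.** A labeled dataset is a positive set I⁺ of known inhibitors
plus an equally sized negative set I⁻ of protein fragments sampled from a
background pool, length-matched to the positives and with I⁺ ∩ I⁻ = ∅
enforced. A synthetic generator emulates the compositional signature of
real ACE-inhibitory peptides (Pro/Leu enriched, Cys/Met/Trp rare) so the
pipeline is fully testable without database downloads.

**Models.** Four families behind one `fit`/`predict_proba` interface:
gradient-boosted trees (XGBoost), an RBF-kernel SVM with Platt-calibrated
probabilities, a random forest, and k-NN — each with fixed, documented
hyperparameters. Evaluation uses stratified 5-fold cross-validation
(Acc/Sens/Spec/Prec at the strict 0.5 threshold, plus ROC/AUC, with 95%
CIs over folds) and a cross-dataset train-on-A/test-on-B protocol.

**Screening.** A protein is cut into every k-mer (k = 2…9); a model is
trained three times with different seeds, and a k-mer is a *candidate*
inhibitor only if its predicted positive probability exceeds 0.99 in all
three runs. k-mers scoring 0.00 or 0.50 in every run are kept as
negative/uncertain control bins.

## Worked example

```bash
python examples/03_cross_validation.py
```

prints, for the default synthetic benchmark (400 positives + 400
negatives, seed 0):

```
                  family     Acc    Sens    Spec     AUC   ±AUC
  gradient_boosted_trees  0.6950  0.6900  0.7000  0.7730 0.0294
                 rbf_svm  0.7350  0.6850  0.7850  0.7750 0.0421
           random_forest  0.7087  0.6850  0.7325  0.7985 0.0286
                     knn  0.6762  0.7000  0.6525  0.7271 0.0464
```

Every family clearly beats chance (AUC 0.5) using composition alone; the
last column is the 95% confidence half-width over the five folds. The
other examples encode peptides (`01`), inspect the generator's
compositional signal (`02`), and screen a protein end to end (`04`),
printing a TSV report whose rows look like

```
sequence  source    start  k  p1      p2      p3      mean_p  bin
GRP       SYNPROT1  77     3  0.9725  0.9726  0.9717  0.9722  other
```

— per-repeat probabilities, their mean, and the assigned bin.

The same workflow is available from the shell:

```bash
acescreen simulate --n-pos 400 --seed 0 --out synth.tsv
acescreen cv --dataset synth.tsv --family xgb --seed 0 --out report.json
acescreen screen --proteins milk.fasta --dataset synth.tsv --family xgb \
    --repeats 3 --threshold 0.99 --seed 0 --out hits.tsv
```

(`examples/fetch_milk_proteins.py` can download the six bovine milk
protein sequences from UniProt when network access is available.)

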
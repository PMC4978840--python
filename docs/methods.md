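# Methods

## The classification problem

G protein-coupled receptors (GPCRs) share a seven-transmembrane (7TM)
architecture: seven hydrophobic helices of roughly 18–25 residues
crossing the membrane, joined by loops of mixed composition. Because this
topology leaves a strong footprint in residue composition and in how
residue classes are arranged along the chain, GPCRs can be separated from
other proteins using sequence-derived features alone — no alignment,
profile or structure required. `gpcrforest` implements this as a binary
classifier: label +1 for GPCR, −1 for non-GPCR.

## The 188D feature encoding

Each sequence maps to a fixed vector of 188 values:

* **Positions 1–20 — amino-acid composition (AAC).** `count(a)/L` for each
  of the 20 standard residues, alphabetical by one-letter code (A, C, D, …,
  Y). The alphabetical order is chosen because it is reproducible without
  any reference implementation.
* **Positions 21–188 — eight 21-value CTD blocks.** For each
  physicochemical property, the 20 residues are partitioned into three
  classes and the sequence is rewritten over {1,2,3}; from that class
  string we compute:
  - *Composition* (3 values): the fraction of residues in each class
    (sums to 1);
  - *Transition* (3 values): for the pairs (1,2), (1,3), (2,3), the number
    of adjacent residue pairs crossing between those classes in either
    direction, divided by L−1. A length-1 sequence has no pairs and
    yields (0,0,0) rather than an error, so degenerate inputs survive
    batch encoding;
  - *Distribution* (15 values): for each class with n occurrences at
    sorted positions p₁ < … < pₙ, the five values 100·p_m/L for
    m = m(first), m(25%), m(50%), m(75%), m(100%), where m(first) = 1 and
    m(q) = max(1, ceil(q·n/100)). An absent class contributes five zeros.

Block order is fixed — hydrophobicity, normalized van der Waals volume,
polarity, polarizability, charge, surface tension, secondary structure,
solvent accessibility — and within each block C1,C2,C3, T12,T13,T23, then
the five distribution anchors for class 1, 2, 3. Both the property order
and the class order are part of the public feature contract.

**Distribution anchor rounding.** Published CTD implementations disagree on
whether the occurrence index at quantile q uses floor, round or ceil.
We use `m(q) = max(1, ceil(q·n/100))`, which guarantees m(100%) = n and
m(q) ≥ 1 with no special cases. The choice is isolated in one function
(`feature_encoding._anchor_index`) so recalibrating against any surviving
reference output is a one-line change.

**Property partitions.** The three-class partitions follow the classical
SVM-Prot/PROFEAT tables (e.g. hydrophobicity: polar RKEDQN / neutral
GASTPHY / hydrophobic CLVIMFW; charge: positive KR / neutral rest /
negative DE). Since single-residue assignments vary between published
copies of these tables, the defaults can be exported
(`gpcrforest export-property-table`) and replaced via `--property-table`;
a replacement file must still define eight pairwise-disjoint partitions
covering the 20 residues.

## Input handling

FASTA input is validated against the 20-letter alphabet under one of three
policies: `strict` (any nonstandard residue is an error naming the record
and character), `drop` (nonstandard residues removed), and the default
`map` (B→D, Z→E, U→C, O→K, J→L; X, stops and gaps removed). `map` is the
default because it keeps the most signal while guaranteeing the alphabet
the encoders require. Cleaning is idempotent; records that clean to an
empty sequence are dropped with a warning.

An optional greedy redundancy filter reduces homology bias before
encoding: sequences are processed longest-first, identity between two
sequences is *estimated* as the fraction of the shorter one's distinct
5-mers present in the other, and a sequence joins the first retained
representative at ≥ the identity threshold (default 0.80) or becomes a new
representative. This is an estimator, not an aligner: it has no banded
alignment or short-word pruning, and is intended for pre-clustering small
to medium sets, not as a replacement for a dedicated clustering tool.

## Cross-validation and rebalancing

`make_folds` shuffles positives and negatives *separately* (seeded) and
cuts each into k near-equal parts — floor(n/k) each, remainder parts (one
extra sample) at the highest fold indices; fold i tests on part i. With
2495 positives and 10386 negatives at k = 5 this yields 499 test positives
per fold and 2077 test negatives in folds 1–4 with 2078 in fold 5 — the
canonical design for these class sizes.

Training folds are rebalanced with SMOTE: each minority vector x spawns
percent/100 synthetic vectors x + u·(x_nn − x), u ~ Uniform(0,1), with
x_nn drawn from x's k = 5 nearest minority neighbours (exact brute-force
Euclidean search; distance ties break to the lower input index for
determinism). At the default percent = 300 the minority class quadruples —
e.g. 1996 training positives become 7984 against 8309 negatives, near
equilibrium for a 1:4 imbalanced set. SMOTE is applied strictly inside
each fold and only to the training partition; synthetic points never reach
a test set, which is the leakage-safe ordering of split-then-resample.
`percent` interprets the classic SMOTE convention (synthetic amount as a
percentage of the minority size); the alternative "multiply to 300%"
reading would leave the classes clearly unbalanced and is not used.

## Classifier

The ensemble is scikit-learn's `RandomForestClassifier` (bootstrap per
tree, √d candidate features per split, unlimited depth, min leaf 1,
seeded; 100 trees by default — the tree count is a convention, not a
tuned value). The positive-class score is computed from per-tree votes,
not averaged leaf probabilities, so every score is an exact multiple of
1/n_trees; the label is +1 iff score ≥ 0.5, ties going to the positive
class (arbitrary but fixed). Models persist to a single versioned joblib
file that stores the configuration, feature count, training-set
fingerprint and the property groupings used at encoding time, so
`predict` on FASTA input always re-encodes with the table the model was
trained on.

## Evaluation

From the confusion counts (positive class = GPCR): Sn = TP/(TP+FN),
Sp = TN/(TN+FP), weighted accuracy (TP+TN)/total, balanced accuracy
(Sn+Sp)/2, and MCC. Both accuracy conventions are always reported because
they genuinely differ on imbalanced data and different summaries of the
same experiment are often quoted in either form; the weighted form equals
(Sn·P + Sp·N)/(P+N) identically. A metric whose denominator is zero is
reported as NaN and flagged — except MCC, which follows the standard
zero-marginal convention of 0 (also flagged). ROC is built by sweeping
thresholds from high to low with tied scores processed as a single step;
AUC is the trapezoidal area, equal to the normalized Mann-Whitney U
statistic with ties counted ½. Fold aggregation reports the arithmetic
mean and the sample (n−1) standard deviation.

## Synthetic data generator

The generator emulates only the *compositional* signature of the two
populations:

* positives: 7 helix segments (lengths 18–25) whose residues carry 0.8
  probability mass on the hydrophobic set {C,L,V,I,M,F,W}, alternating
  with uniform-composition loops; total length 280–520 residues;
* negatives: i.i.d. residues from a near-uniform table with 1.8× weight on
  the abundant residues A, G, L, S, E, K; same length range.

Defaults of 100 positives vs 400 negatives mirror the ~1:4 class imbalance
of curated receptor/non-receptor datasets so SMOTE is exercised
realistically. The two streams use decoupled seeds, so changing the
positive count never perturbs the negative sample.

What the generator does **not** emulate: real transmembrane topology
(helix periodicity, signal peptides, termini conventions), conserved
sequence motifs, phylogenetic correlation between sequences, or the
label noise of database annotation. The hydrophobicity gap between the
populations is large by construction, so the end-to-end pipeline separates
them essentially perfectly (weighted accuracy and AUC ≈ 1.0 at these
defaults). Passing tests therefore demonstrate that every stage is wired
and computed correctly — not that this accuracy transfers to real
proteomes, where reported performance for this family of pipelines is in
the low-90% accuracy range with AUC ≈ 0.93.

## Problem sizes and numerical choices

The test suite and the acceptance script run the full pipeline at
500 sequences (100 + 400), 5 folds, 100 trees — a few seconds on one CPU —
and verify fold arithmetic at the full 2495/10386 scale using synthetic
vectors (splitting does not need real features). CTD encoders are checked
against exhaustive brute-force enumeration over all class strings of
length ≤ 6, and the AUC implementation against pairwise counting and
scikit-learn's `roc_auc_score`. ARFF numeric output carries 6 significant
digits, so an ARFF round trip is exact on labels and accurate to ~1e-5
relative on values.

## Known limitations

* The redundancy filter's k-mer identity is a heuristic lower-variance
  stand-in for alignment identity; near the threshold its clustering can
  differ from an aligner's.
* The encoder supports only the categorical 3-class CTD encodings — no
  continuous amino-acid indices, PseAAC, or profile features.
* Training is in-memory and brute-force SMOTE is O(n²) in the minority
  size; both are comfortable at tens of thousands of vectors but not
  millions.
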
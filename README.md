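# gpcrforest

Sequence-based classification of G protein-coupled receptors (GPCRs) versus
non-GPCRs from primary amino-acid sequence alone.

GPCRs — the seven-transmembrane (7TM) receptor superfamily — share a strong
compositional signature: seven hydrophobic membrane-spanning helices
separated by mixed-composition loops. `gpcrforest` turns that signal into a
classical machine-learning pipeline for anyone who needs to flag candidate
receptors in a protein set without alignments or profile databases:

1. **188D SVM-Prot feature encoding.** Each sequence becomes a fixed
   188-value vector: the 20 amino-acid composition (AAC) frequencies, plus,
   for each of eight physicochemical properties (hydrophobicity, normalized
   van der Waals volume, polarity, polarizability, charge, surface tension,
   secondary structure, solvent accessibility), a 21-value CTD block —
   **C**omposition (3 class fractions), **T**ransition (3 cross-class
   adjacent-pair frequencies) and **D**istribution (the sequence positions,
   as percent of length, at which the first/25%/50%/75%/100% of each class's
   residues are reached). 20 + 8×21 = 188.
2. **Stratified 5-fold splitting** — positives and negatives are shuffled
   and partitioned separately, so every fold tests on both classes.
3. **SMOTE rebalancing** of the training minority class at 300% (three
   synthetic interpolants per minority sample), applied inside each fold
   and never to test data.
4. **Random-Forest classification** (100 trees by default); the
   positive-class score is the fraction of trees voting GPCR.
5. **Evaluation battery**: Sn = TP/(TP+FN), Sp = TN/(TN+FP), weighted
   accuracy (TP+TN)/total, balanced accuracy (Sn+Sp)/2, Matthews
   correlation coefficient, and trapezoidal ROC/AUC, aggregated as
   mean ± SD across folds.

A seeded synthetic-sequence generator produces receptor-like (seven
hydrophobic-stretch) and globular-background populations so the whole
pipeline runs and validates offline, with no database access.

## Worked example

```bash
gpcrforest simulate --n-pos 100 --n-neg 400 --seed 1 --out-dir run/
gpcrforest encode --positives run/positives.fasta \
                  --negatives run/negatives.fasta --out run/data.arff
gpcrforest crossval --arff run/data.arff --k 5 --smote-percent 300 \
                    --n-trees 100 --seed 1 --out run/report.tsv
```

The cross-validation report (also written to `run/report.tsv`) ends with:

```
fold  TP  FN  TN   FP  Sn      Sp      Acc_weighted  Acc_balanced  MCC     AUC
1     20  0   80   0   1.0000  1.0000  1.0000        1.0000        1.0000  1.0000
...
mean±SD             1.0000±0.0000  1.0000±0.0000  1.0000±0.0000  1.0000±0.0000  1.0000±0.0000  1.0000±0.0000
```

Each row is one held-out fold: TP/FN/TN/FP are the confusion counts, Sn the
fraction of true receptors recovered, Sp the fraction of background
correctly rejected, and AUC the threshold-free ranking quality. On the
synthetic populations the compositional gap is large, so the forest
separates the classes perfectly; real proteomes are harder (see
`docs/methods.md`).

The same steps are available as library calls:

```python
from gpcrforest import (GeneratorConfig, generate_both, encode_many,
                        combine, run_crossval)

pos, neg = generate_both(GeneratorConfig(n_pos=100, n_neg=400, seed=1))
data = combine(encode_many(pos, label=+1) + encode_many(neg, label=-1))
reports, agg = run_crossval(data, k=5, smote_percent=300, seed=1)
print(agg["acc_weighted"])   # (1.0, 0.0) — mean, SD across folds
```

`gpcrforest train` / `gpcrforest predict` fit and apply a persistent model
to new FASTA or ARFF inputs; `gpcrforest export-property-table` writes the
eight amino-acid groupings to a plain-text file that `--property-table`
accepts back, so alternative residue partitions need no code change.

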
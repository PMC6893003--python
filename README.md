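# raackit

Reduced amino-acid alphabet features for protein sequence analysis and
binary classification.

Many protein-function prediction problems work better on a *reduced*
alphabet: the 20 standard amino acids are partitioned into R clusters of
physico-chemically or evolutionarily similar residues (Murphy BLOSUM-based
groups, hydrophobic/polar splits, Dayhoff-style chemistry groups, ...), and
every sequence is rewritten over one representative letter per cluster.
Reduction shrinks feature spaces (R^K instead of 20^K tuple columns), cuts
redundancy, and makes loosely conserved motifs easier to count. `raackit`
is for bioinformaticians who want those features as plain matrices — for
classifier training, logo/heat-map visualisation, or export to other tools.

## The method

Given a reduction scheme with R clusters and a sequence of length L, the
package counts **K-tuple reduced composition** under three parameters:

- **K** — tuple size (K=1 monopeptide, K=2 dipeptide, K=3 tripeptide);
- **g** — gap between successive window *start* positions minus one
  (`g=0`: R1R2, R2R3, R3R4, ...; `g=1`: R1R2, R3R4, R5R6, ...);
- **λ** — residues skipped between adjacent members *inside* a window
  (stride λ+1; with K=3, λ=1, g=2 the windows are R1R3R5, R4R6R8, R7R9R11).
  λ=2 with K=2 captures CXXC-style motifs as the tuple CC.

A window covers positions `s, s+(λ+1), ..., s+(K−1)(λ+1)`, spanning
`(K−1)(λ+1)+1` residues; each window's residues are mapped through the
scheme and the normalised R^K-vector of reduced-tuple frequencies is the
sequence's feature row.

For two-class problems the `ml` layer builds labelled feature matrices from
positive/negative FASTA files, runs stratified k-fold (default 5) or
leave-one-out cross-validation with SVM, KNN or random-forest classifiers,
and reports pooled confusion counts, sensitivity (Sn), specificity (Sp),
accuracy (Acc), the Matthews correlation coefficient

    MCC = (TP·TN − FP·FN) / √((TP+FP)(TP+FN)(TN+FP)(TN+FN)),

and the ROC curve with its rank-statistic AUC.

## Worked example

Generate a synthetic two-class set (positives enriched 3× in F/W/Y), then
cross-validate an SVM on dipeptide features over the Murphy size-8 alphabet:

```sh
raac synth --n-pos 50 --n-neg 50 --effect 3 --seed 7 \
     --pos-out pos.fa --neg-out neg.fa
raac train --pos pos.fa --neg neg.fa --type t1 --size 8 -K 2 \
     --clf svm --folds 5 --seed 7 -o run
```

prints

```
classifier : svm
scheme     : t1 (size 8)
tuple      : K=2 g=0 lambda=0
folds      : 5   seed: 7
confusion  : TP=38 FN=12 TN=50 FP=0
Sn=0.7600  Sp=1.0000  Acc=0.8800  MCC=0.7829  AUC=0.9976
```

i.e. pooled over the five held-out folds the SVM recovered 38 of 50
positives with no false positives; the AUC close to 1 says the decision
scores rank nearly every positive above every negative.  `run/` also holds
the ROC points (`roc.tsv`), the feature matrix (`features.csv`,
`features.libsvm`), the echoed config and the serialised model.

Other subcommands: `raac list` (browse/filter the scheme registry),
`raac reduce` (rewrite FASTA over a reduced alphabet), `raac features`
(matrix export only), `raac logo` (position-frequency/logo tables of a
pre-aligned FASTA).

As a library:

```python
import raackit as rk

scheme = rk.load_curated_registry().get("t1", 10)
seqs = rk.read_fasta("pos.fa")
matrix = rk.extract_features(seqs, scheme, rk.TupleSpec(K=2, g=0, lam=0))
matrix.to_dataframe()  # id + 100 dipeptide columns, rows on the simplex
```

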
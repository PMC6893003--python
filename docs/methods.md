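# Methods

## Reduction schemes and the registry

A reduction scheme is a disjoint, exhaustive partition of the 20 standard
one-letter amino-acid codes into R clusters, 2 ≤ R ≤ 20, with one
representative letter per cluster.  Validation is strict: parsing a scheme
table rejects any row whose clusters miss, duplicate, or go outside the
standard alphabet, naming the offending letters and line.  The
representative is the **first letter of the cluster as written in the
table** — scheme authors rarely name representatives, and first-letter is
deterministic and matches common practice in reduced-alphabet feature
tools.  Registry keys are `(type_id, size)`; display order sorts type ids
numerically on their trailing integer so `t2` precedes `t10`.

The bundled `data/curated_schemes.tsv` holds a small set of well-known
published alphabets (Murphy BLOSUM50 clusterings at sizes 2/4/8/10/15, the
Wang–Wang interaction-matrix 5-letter alphabet, a hydrophobic–polar split,
Dayhoff-style chemistry groups, GBMR4, and the size-20 identity).
`alphabets.synthetic_registry_text()` additionally generates, from a fixed
seed, a **synthetic** stand-in registry at full database scale — 74 type
families, 673 schemes, all valid partitions — used to exercise
registry-scale parsing, filtering and validation.  Its cluster memberships
are random and carry no biological meaning; results on it say nothing
about any real alphabet's merit, only that the machinery handles the
scale.

## Sequence reduction

Residues map through the scheme's residue→representative table.  Input is
case-insensitive; `*` is stripped at FASTA read time.  The ambiguity codes
B, Z, X, U, O are tolerated in input but treated as non-standard: the
default policy masks them (placeholder `X` plus a per-position flag), and
alternatives `drop` (with 1-based source-position bookkeeping) and `error`
are available.  B/Z/U/O are **not** silently translated to D/E/C/K —
silent translation would alter compositions invisibly; an explicit
`translate_ambiguous` step / `--translate-ambiguous` flag applies the
conventional mapping when the user wants it.  `-` is tolerated as the
alignment gap character for pre-aligned inputs.

Reduction commutes with concatenation and is idempotent (representatives
map to themselves); the size-20 identity scheme is the identity map.  Both
are property-tested.

## Window enumeration and K-tuple composition

The (K, g, λ) semantics were fixed against the worked patterns the three
parameters are defined by:

- window s covers `s, s+(λ+1), ..., s+(K−1)(λ+1)` — adjacent in-window
  residues are separated by λ skipped residues (λ=0 contiguous; K=3, λ=1
  gives R1R3R5);
- successive window starts differ by `g+1` (g=1 with K=2 gives R1R2, R3R4,
  R5R6; K=3, g=2, λ=1 gives starts 1, 4, 7).  The alternative reading of g
  as an end-to-start gap contradicts the λ example and is rejected.
- the window count is `floor((L − span)/(g+1)) + 1` for L ≥ span
  (span = `(K−1)(λ+1)+1`), else 0.

One textual constraint in the source literature ("λ is an integer greater
than 2 and less than L−K") contradicts its own worked examples (λ=1 and
λ=2); the implementation accepts any λ ≥ 0 and bounds only by span ≤ L.

Feature rows are normalised by the **number of counted windows**, not L,
so that skipping windows that touch masked positions keeps rows on the
simplex.  Column labels are representative-letter strings ("AC"), ordered
as the lexicographic product of the scheme's own cluster order (not
alphabetically), so columns stay aligned with the scheme file.  Vectors
are dense internally (R^K is small for practical R, K); sparsity appears
only in libsvm export.  Defaults K=2, g=0, λ=0.  Sequences yielding no
windows are dropped with a logged warning and recorded as rejects; a run
where every sequence is rejected errors out.

## Classification and evaluation

Datasets are built positives-then-negatives (+1/−1), extracted per class so
labels never depend on sequence ids (duplicate ids across files are warned
about, not fatal).  Folds are stratified (per-fold class counts within 1 of
proportional) via a seeded shuffle; leave-one-out puts each row in its own
fold.  Classifiers are scikit-learn's SVC (RBF, C=1, gamma=1/n_features),
KNeighborsClassifier (k=5) and RandomForestClassifier (100 trees), all
overridable; a single seed drives fold shuffling and classifier internals
and is echoed in every report.

Metrics are computed on predictions **pooled across folds** — evaluation
reports in this field quote single Sn/Sp/Acc/MCC values per run — with
per-fold values additionally recorded.  The confusion threshold is each
classifier's native decision boundary (margin sign, majority vote); no
ROC-optimised cut is applied, since none is published for the protocols
this mirrors.  MCC uses the closed form with the 0-on-zero-denominator
convention.  AUC is the rank (Mann–Whitney) statistic with midranks for
ties, so all-equal scores give exactly 0.5; the ROC step curve advances
diagonally through tied thresholds, making its trapezoidal integral equal
the rank AUC to machine precision (asserted at 1e-12 against an
independent implementation).  Class imbalance beyond 3:1 triggers a
warning but no resampling.

Saved models are joblib archives with a JSON sidecar carrying a format
version and a sha256 of the model file; loading verifies both and refuses
tampered or mismatched artifacts rather than reinterpreting them.

## Visualisation data products

All visual products are first computed as plain tables; rendering is an
optional thin matplotlib layer, so tests never compare pixels.

- **Logo matrices** give per-position letter frequencies over an aligned
  set (gaps excluded from denominators; all-gap columns flagged with zero
  information).  Information content is `log2|alphabet| − H(p)` bits, with
  no small-sample correction (n is user-controlled).  Default display is
  plain frequency stacks; information-scaled stacks are opt-in.
- **Alignment views** colour each natural residue by its cluster rank in a
  fixed, documented 20-colour qualitative palette; the reduced row reuses
  the same indices, so the reduced palette is a subset of the natural one
  by construction.
- **Mergence tables** record the natural→representative frequency flow
  (Sankey-style line widths proportional to frequency), and the heat-map
  table re-emits the feature matrix plus per-sequence top-n tuples with
  ties broken by column order.

## Synthetic benchmark generator

`SyntheticSpec` emulates a two-class protein benchmark with a planted
compositional signal: negatives are i.i.d. draws from a background residue
distribution (uniform by default); positives multiply the probabilities of
the residues in chosen clusters by an effect factor ≥ 1 and renormalise.
Defaults — 100 sequences per class, lengths 80–120, planted cluster FWY —
are sized like the small curated benchmarks this kind of tool is evaluated
on.  `effect=1` makes the classes exchangeable by construction, giving a
null for calibration.  The generator captures only *global composition*
differences: real benchmarks also differ in positional motifs, length
distributions, phylogenetic correlation between sequences, and label
noise, none of which are modelled.  Passing the planted-signal recovery
suite therefore shows the pipeline recovers compositional signal at
realistic sizes; it does not predict accuracy on any real dataset, and the
published accuracies of specific external benchmarks are not reproduced
here (their datasets and classifier settings are not part of this
package).

## Problem sizes and numerical choices

The test-bench runs window-enumeration agreement exhaustively over L ≤ 40,
K ≤ 4, g ≤ 3, λ ≤ 3; degenerate-equivalence checks on 100 random
sequences; and planted-signal recovery at effects {1, 2, 5} × 10 seeds ×
100 sequences per class with 5-fold SVM — sizes chosen as the smallest at
which the null band (AUC 0.45–0.55 at effect 1) and the strong-signal bound
(AUC ≥ 0.95 at effect 5) are stable across seeds.  Frequencies are
serialised with full double round-trip precision; human-readable report
text rounds to 4 decimals.  Determinism is byte-level: identical configs
(including seed) reproduce report JSON exactly.

## Known limitations

- No "pseudo" tier-correlation components beyond plain tuple composition;
  the feature space is exactly the R^K tuple frequencies.
- Alignment inputs must be pre-aligned; no aligner is invoked.
- Binary classification only; no hyperparameter search.
- The full-scale registry bundled here is a labelled synthetic stand-in,
  not a curated database of published alphabets (the curated subset covers
  the common ones).
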
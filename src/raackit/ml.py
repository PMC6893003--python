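"""Binary protein classification on reduced-alphabet features.

The evaluation protocol follows the five-step convention for sequence
predictors: benchmark dataset (positive/negative FASTA) -> feature
formulation (K-tuple reduced composition) -> classifier (SVM / KNN / RF)
-> cross-validation (stratified 5-fold by default, or leave-one-out) ->
report (pooled confusion counts, Sn/Sp/Acc/MCC, ROC curve, AUC).

Metrics are computed on predictions POOLED across folds — one Sn/Sp/Acc/MCC
value per run — with per-fold values additionally recorded.  The confusion
threshold is each classifier's native decision boundary (margin sign for
SVM, majority vote for KNN/RF); no ROC-optimised cut is applied.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import joblib
import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC

from .alphabets import ReductionScheme
from .features import FeatureMatrix, NoWindowsError, TupleSpec, extract_features
from .io import read_fasta
from .reduction import ProteinSequence

__all__ = [
    "LabeledDataset",
    "FoldPlan",
    "EvaluationReport",
    "build_dataset",
    "dataset_from_sequences",
    "make_folds",
    "cross_validate",
    "confusion_metrics",
    "roc_auc",
    "train_full",
    "save_model",
    "load_model",
    "CLASSIFIERS",
]

logger = logging.getLogger(__name__)

REPORT_SCHEMA_VERSION = 1
MODEL_FORMAT_VERSION = 1

#: Default hyperparameters per classifier (all overridable).
CLASSIFIERS = {
    "svm": {"C": 1.0, "gamma": "auto", "kernel": "rbf"},
    "knn": {"n_neighbors": 5},
    "rf": {"n_estimators": 100},
}


@dataclass
class LabeledDataset:
    """Feature matrix plus per-row labels in {+1, -1}."""

    features: FeatureMatrix
    labels: np.ndarray
    provenance: tuple[str, str] = ("", "")

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if len(self.labels) != len(self.features.row_ids):
            raise ValueError("label count does not match feature row count")
        if not set(np.unique(self.labels)) <= {-1, 1}:
            raise ValueError("labels must be +1 or -1")
        n_pos = int((self.labels == 1).sum())
        n_neg = int((self.labels == -1).sum())
        if n_pos == 0 or n_neg == 0:
            raise ValueError(
                f"both classes must be non-empty (got {n_pos} positive, "
                f"{n_neg} negative rows)"
            )
        ratio = max(n_pos, n_neg) / min(n_pos, n_neg)
        if ratio > 3:
            logger.warning(
                "class imbalance %.1f:1 exceeds 3:1 (%d pos / %d neg); "
                "no resampling is applied", ratio, n_pos, n_neg
            )

    @property
    def n_rows(self) -> int:
        return len(self.labels)


def dataset_from_sequences(
    pos: list[ProteinSequence],
    neg: list[ProteinSequence],
    scheme: ReductionScheme,
    spec: TupleSpec,
    unknown_policy: str = "mask",
    provenance: tuple[str, str] = ("", ""),
) -> LabeledDataset:
    """Label positives +1 and negatives -1; rows all-positives-then-negatives."""
    dup = {s.id for s in pos} & {s.id for s in neg}
    if dup:
        logger.warning(
            "duplicate ids across positive and negative sets (ids are not "
            "keys): %s", ", ".join(sorted(dup)[:5])
        )
    # extract per class so labels never depend on (possibly duplicate) ids
    try:
        mat_pos = extract_features(pos, scheme, spec, unknown_policy)
        mat_neg = extract_features(neg, scheme, spec, unknown_policy)
    except NoWindowsError as exc:
        raise ValueError(
            f"a class became empty after dropping sequences with no "
            f"windows: {exc}"
        ) from exc
    matrix = FeatureMatrix(
        column_names=mat_pos.column_names,
        values=np.vstack([mat_pos.values, mat_neg.values]),
        row_ids=mat_pos.row_ids + mat_neg.row_ids,
        spec=spec,
        scheme_key=scheme.key,
        window_counts=mat_pos.window_counts + mat_neg.window_counts,
        rejects=mat_pos.rejects + mat_neg.rejects,
    )
    labels = np.array([1] * len(mat_pos.row_ids) + [-1] * len(mat_neg.row_ids))
    return LabeledDataset(matrix, labels, provenance)


def build_dataset(
    pos_fasta,
    neg_fasta,
    scheme: ReductionScheme,
    spec: TupleSpec,
    unknown_policy: str = "mask",
) -> LabeledDataset:
    """Read positive/negative FASTA files and extract labelled features."""
    pos = read_fasta(pos_fasta)
    neg = read_fasta(neg_fasta)
    return dataset_from_sequences(
        pos, neg, scheme, spec, unknown_policy,
        provenance=(str(pos_fasta), str(neg_fasta)),
    )


@dataclass(frozen=True)
class FoldPlan:
    """Per-row fold assignment; stratified unless leave-one-out."""

    n_folds: int
    assignments: tuple[int, ...]
    seed: int
    loo: bool = False


def make_folds(
    labels,
    n_folds: int = 5,
    loo: bool = False,
    seed: int = 42,
) -> FoldPlan:
    """Stratified fold assignment, deterministic given ``seed``.

    Leave-one-out puts every row in its own fold.  For k-fold, ``n_folds``
    may not exceed the smaller class size (each training split must contain
    both classes).
    """
    labels = np.asarray(labels, dtype=int)
    n = len(labels)
    if loo:
        return FoldPlan(n, tuple(range(n)), seed, loo=True)
    if n_folds < 2:
        raise ValueError(f"n_folds must be >= 2, got {n_folds}")
    min_class = min(int((labels == 1).sum()), int((labels == -1).sum()))
    if n_folds > min_class:
        raise ValueError(
            f"n_folds={n_folds} exceeds the smaller class size "
            f"({min_class}); use leave-one-out (loo=True) instead"
        )
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    assignments = np.empty(n, dtype=int)
    for fold, (_, test_idx) in enumerate(skf.split(np.zeros((n, 1)), labels)):
        assignments[test_idx] = fold
    return FoldPlan(n_folds, tuple(int(a) for a in assignments), seed)


def _make_classifier(name: str, hyperparams: dict | None, seed: int):
    if name not in CLASSIFIERS:
        raise ValueError(
            f"unknown classifier {name!r}; supported: "
            f"{', '.join(sorted(CLASSIFIERS))}"
        )
    params = dict(CLASSIFIERS[name])
    if hyperparams:
        params.update(hyperparams)
    if name == "svm":
        return SVC(random_state=seed, **params)
    if name == "knn":
        return KNeighborsClassifier(**params)
    return RandomForestClassifier(random_state=seed, **params)


def _scores(clf, X: np.ndarray) -> np.ndarray:
    """Decision scores, larger = more positive-like."""
    if hasattr(clf, "decision_function"):
        return np.asarray(clf.decision_function(X), dtype=float)
    proba = clf.predict_proba(X)
    pos_col = list(clf.classes_).index(1)
    return np.asarray(proba[:, pos_col], dtype=float)


def confusion_metrics(tp: int, tn: int, fp: int, fn: int) -> dict[str, float]:
    """Sn, Sp, Acc and Matthews correlation coefficient from counts.

    MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN)), defined as 0
    when the denominator vanishes.
    """
    total = tp + tn + fp + fn
    sn = tp / (tp + fn) if tp + fn else 0.0
    sp = tn / (tn + fp) if tn + fp else 0.0
    acc = (tp + tn) / total if total else 0.0
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = (tp * tn - fp * fn) / np.sqrt(denom) if denom else 0.0
    return {"Sn": sn, "Sp": sp, "Acc": acc, "MCC": float(mcc)}


def roc_auc(scores, labels) -> tuple[np.ndarray, float]:
    """ROC step curve over unique thresholds and the rank (Mann-Whitney) AUC.

    AUC = P(score_pos > score_neg) + 0.5 * P(tie); equal scores give 0.5.
    The curve is the ordered (FPR, TPR) points from (0, 0) to (1, 1); its
    trapezoidal integral equals the rank AUC.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == -1).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present to compute ROC/AUC")
    # step curve: sweep unique scores descending, ties advance diagonally
    order = np.argsort(-scores, kind="stable")
    sorted_scores = scores[order]
    is_pos = labels[order] == 1
    points = [(0.0, 0.0)]
    tp = fp = 0
    i = 0
    n = len(scores)
    while i < n:
        j = i
        while j < n and sorted_scores[j] == sorted_scores[i]:
            j += 1
        tp += int(is_pos[i:j].sum())
        fp += (j - i) - int(is_pos[i:j].sum())
        points.append((fp / n_neg, tp / n_pos))
        i = j
    roc = np.array(points)
    # rank AUC with midranks for ties
    ranks = _midranks(scores)
    auc = (ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)
    return roc, float(auc)


def _midranks(x: np.ndarray) -> np.ndarray:
    """1-based ranks, ties receiving the average of their rank range."""
    order = np.argsort(x, kind="stable")
    ranks = np.empty(len(x), dtype=float)
    sx = x[order]
    i = 0
    while i < len(x):
        j = i
        while j < len(x) and sx[j] == sx[i]:
            j += 1
        ranks[order[i:j]] = (i + j + 1) / 2  # average of ranks i+1 .. j
        i = j
    return ranks


@dataclass
class EvaluationReport:
    """Pooled cross-validation results for one (scheme, spec, classifier) run."""

    TP: int
    TN: int
    FP: int
    FN: int
    Sn: float
    Sp: float
    Acc: float
    MCC: float
    roc: np.ndarray  # (n_points, 2) of (FPR, TPR)
    AUC: float
    classifier_name: str
    hyperparams: dict
    spec: TupleSpec
    scheme_key: tuple[str, int]
    seed: int
    n_folds: int
    per_fold: list[dict] = field(default_factory=list)
    schema_version: int = REPORT_SCHEMA_VERSION

    def to_dict(self) -> dict:
        d = {
            "schema_version": self.schema_version,
            "classifier": self.classifier_name,
            "hyperparams": self.hyperparams,
            "scheme": {"type": self.scheme_key[0], "size": self.scheme_key[1]},
            "tuple": dataclasses.asdict(self.spec),
            "seed": self.seed,
            "n_folds": self.n_folds,
            "confusion": {"TP": self.TP, "TN": self.TN,
                          "FP": self.FP, "FN": self.FN},
            "Sn": self.Sn, "Sp": self.Sp, "Acc": self.Acc, "MCC": self.MCC,
            "AUC": self.AUC,
            "roc": [[float(a), float(b)] for a, b in self.roc],
            "per_fold": self.per_fold,
        }
        return d

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True) + "\n"

    def summary(self) -> str:
        """Human-readable table, values rounded to 4 decimals."""
        type_id, size = self.scheme_key
        lines = [
            f"classifier : {self.classifier_name}",
            f"scheme     : {type_id} (size {size})",
            f"tuple      : K={self.spec.K} g={self.spec.g} lambda={self.spec.lam}",
            f"folds      : {self.n_folds}   seed: {self.seed}",
            f"confusion  : TP={self.TP} FN={self.FN} TN={self.TN} FP={self.FP}",
            f"Sn={self.Sn:.4f}  Sp={self.Sp:.4f}  "
            f"Acc={self.Acc:.4f}  MCC={self.MCC:.4f}  AUC={self.AUC:.4f}",
        ]
        return "\n".join(lines)


def cross_validate(
    dataset: LabeledDataset,
    fold_plan: FoldPlan,
    classifier: str = "svm",
    hyperparams: dict | None = None,
    seed: int | None = None,
) -> EvaluationReport:
    """Fit on each fold's complement, pool held-out predictions, and score.

    Every row is predicted exactly once; confusion counts, Sn/Sp/Acc/MCC and
    the ROC/AUC are computed from the pooled held-out predictions and
    decision scores.  ``seed`` defaults to the fold plan's seed and drives
    classifier-internal randomness.
    """
    X = dataset.features.values
    y = dataset.labels
    if len(fold_plan.assignments) != len(y):
        raise ValueError("fold plan size does not match dataset size")
    if seed is None:
        seed = fold_plan.seed
    assignments = np.asarray(fold_plan.assignments)
    pred = np.zeros(len(y), dtype=int)
    score = np.zeros(len(y), dtype=float)
    per_fold = []
    for fold in range(fold_plan.n_folds):
        test = assignments == fold
        train = ~test
        if len(np.unique(y[train])) < 2:
            raise ValueError(
                f"fold {fold}: training split contains a single class"
            )
        clf = _make_classifier(classifier, hyperparams, seed)
        clf.fit(X[train], y[train])
        pred[test] = clf.predict(X[test])
        score[test] = _scores(clf, X[test])
        fold_tp = int(((pred == 1) & (y == 1) & test).sum())
        fold_tn = int(((pred == -1) & (y == -1) & test).sum())
        fold_fp = int(((pred == 1) & (y == -1) & test).sum())
        fold_fn = int(((pred == -1) & (y == 1) & test).sum())
        per_fold.append(
            {"fold": fold, "n_test": int(test.sum()),
             **confusion_metrics(fold_tp, fold_tn, fold_fp, fold_fn)}
        )
    tp = int(((pred == 1) & (y == 1)).sum())
    tn = int(((pred == -1) & (y == -1)).sum())
    fp = int(((pred == 1) & (y == -1)).sum())
    fn = int(((pred == -1) & (y == 1)).sum())
    metrics = confusion_metrics(tp, tn, fp, fn)
    roc, auc = roc_auc(score, y)
    params = dict(CLASSIFIERS[classifier])
    if hyperparams:
        params.update(hyperparams)
    return EvaluationReport(
        TP=tp, TN=tn, FP=fp, FN=fn,
        Sn=metrics["Sn"], Sp=metrics["Sp"],
        Acc=metrics["Acc"], MCC=metrics["MCC"],
        roc=roc, AUC=auc,
        classifier_name=classifier, hyperparams=params,
        spec=dataset.features.spec, scheme_key=dataset.features.scheme_key,
        seed=seed, n_folds=fold_plan.n_folds, per_fold=per_fold,
    )


def train_full(
    dataset: LabeledDataset,
    classifier: str = "svm",
    hyperparams: dict | None = None,
    seed: int = 42,
):
    """Fit one classifier on the whole dataset (for export via save_model)."""
    clf = _make_classifier(classifier, hyperparams, seed)
    clf.fit(dataset.features.values, dataset.labels)
    return clf


def _file_sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def save_model(clf, path, metadata: dict | None = None) -> None:
    """Serialise a trained classifier plus a JSON metadata sidecar.

    The sidecar (``<path>.meta.json``) records the format version, a sha256
    of the model file, and caller metadata (scheme key, tuple parameters,
    classifier name, seed).  ``load_model`` verifies both.
    """
    path = Path(path)
    joblib.dump(clf, path)
    meta = {
        "format_version": MODEL_FORMAT_VERSION,
        "model_sha256": _file_sha256(path),
        **(metadata or {}),
    }
    path.with_suffix(path.suffix + ".meta.json").write_text(
        json.dumps(meta, indent=2, sort_keys=True) + "\n"
    )


def load_model(path):
    """Load a saved classifier, verifying format version and file hash.

    Returns ``(classifier, metadata)``.  A missing sidecar, a version
    mismatch or a tampered model file raises, never silently reinterprets.
    """
    path = Path(path)
    meta_path = path.with_suffix(path.suffix + ".meta.json")
    if not meta_path.exists():
        raise ValueError(f"missing metadata sidecar {meta_path}")
    meta = json.loads(meta_path.read_text())
    if meta.get("format_version") != MODEL_FORMAT_VERSION:
        raise ValueError(
            f"model format version {meta.get('format_version')!r} does not "
            f"match supported version {MODEL_FORMAT_VERSION}"
        )
    digest = _file_sha256(path)
    if digest != meta.get("model_sha256"):
        raise ValueError(
            f"model file hash mismatch (file {digest[:12]}..., "
            f"metadata {str(meta.get('model_sha256'))[:12]}...)"
        )
    return joblib.load(path), meta
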
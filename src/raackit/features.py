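"""K-tuple reduced amino-acid composition under three correlation parameters.

A tuple window of size K is slid along the sequence.  Two further integers
shape the enumeration:

- **g-gap** — successive window *start* positions differ by ``g + 1``;
  ``g = 0`` gives the usual overlapping windows (R1R2, R2R3, ...), ``g = 1``
  skips one start (R1R2, R3R4, ...).
- **λ-correlation** — adjacent residues *inside* a window are separated by λ
  skipped residues (index stride ``λ + 1``); ``λ = 0`` means contiguous.
  With K=2, λ=2 a CXXC-style motif is counted as the tuple CC.

A window therefore covers positions ``s, s+(λ+1), ..., s+(K-1)(λ+1)`` and
spans ``(K-1)(λ+1) + 1`` residues.  Each window's residues are mapped
through a reduction scheme and the resulting reduced K-tuples counted; the
normalised R^K-dimensional frequency vector is the sequence's feature row.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .alphabets import ReductionScheme
from .reduction import ProteinSequence, reduce_sequence

__all__ = [
    "TupleSpec",
    "FeatureMatrix",
    "NoWindowsError",
    "enumerate_windows",
    "tuple_labels",
    "ktuple_composition",
    "extract_features",
    "write_libsvm",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TupleSpec:
    """The (K, g, λ) triple governing window enumeration.

    Defaults K=2, g=0, λ=0 (overlapping dipeptides).
    """

    K: int = 2
    g: int = 0
    lam: int = 0

    def __post_init__(self) -> None:
        if self.K < 1:
            raise ValueError(f"K must be >= 1, got {self.K}")
        if self.g < 0:
            raise ValueError(f"g must be >= 0, got {self.g}")
        if self.lam < 0:
            raise ValueError(f"lambda must be >= 0, got {self.lam}")

    @property
    def span(self) -> int:
        """Number of sequence positions one window covers."""
        return (self.K - 1) * (self.lam + 1) + 1

    @property
    def step(self) -> int:
        """Distance between successive window start positions."""
        return self.g + 1


class NoWindowsError(ValueError):
    """Raised when a sequence yields no countable windows."""


def enumerate_windows(L: int, spec: TupleSpec) -> list[tuple[int, ...]]:
    """All K-long 1-based position tuples for a sequence of length ``L``.

    Window s covers ``(s, s+(λ+1), ..., s+(K-1)(λ+1))`` for
    ``s = 1, 1+(g+1), 1+2(g+1), ...`` while the last index stays <= L.
    Returns ``floor((L - span)/(g+1)) + 1`` windows when ``L >= span``,
    otherwise an empty list.
    """
    if L < 1:
        raise ValueError(f"sequence length must be >= 1, got {L}")
    span = spec.span
    if L < span:
        return []
    stride = spec.lam + 1
    offsets = range(0, spec.K * stride, stride)
    return [
        tuple(s + o for o in offsets)
        for s in range(1, L - span + 2, spec.step)
    ]


def tuple_labels(scheme: ReductionScheme, K: int) -> list[str]:
    """The R^K column labels: lexicographic product in cluster order.

    Order follows the scheme file's own cluster order, not the alphabet, so
    columns stay aligned with the scheme's presentation.
    """
    return [
        "".join(t) for t in itertools.product(scheme.representatives, repeat=K)
    ]


@dataclass
class FeatureMatrix:
    """Per-sequence normalised reduced K-tuple composition vectors.

    Rows follow input order; each row with ``window_count > 0`` lies on the
    simplex (sums to 1).  ``rejects`` lists (id, reason) for sequences that
    yielded no windows and were dropped.
    """

    column_names: list[str]
    values: np.ndarray  # shape (n_sequences, R**K)
    row_ids: list[str]
    spec: TupleSpec
    scheme_key: tuple[str, int]
    window_counts: list[int]
    rejects: list[tuple[str, str]] = field(default_factory=list)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.column_names)
        df.insert(0, "id", self.row_ids)
        return df

    def to_csv(self, path) -> None:
        """CSV with an ``id`` first column and full double precision."""
        self.to_dataframe().to_csv(path, index=False, float_format="%.17g")


def write_libsvm(matrix: FeatureMatrix, path, labels=None) -> None:
    """Sparse libsvm lines ``<label> <index>:<value> ...``, 1-based indices.

    Zero entries are omitted; ``labels`` defaults to 0 for every row.
    """
    if labels is None:
        labels = [0] * len(matrix.row_ids)
    if len(labels) != len(matrix.row_ids):
        raise ValueError("labels length does not match number of rows")
    with open(path, "w") as fh:
        for label, row in zip(labels, matrix.values):
            nz = np.nonzero(row)[0]
            feats = " ".join(f"{j + 1}:{row[j]:.17g}" for j in nz)
            fh.write(f"{int(label)} {feats}".rstrip() + "\n")


def ktuple_composition(
    seq: ProteinSequence,
    scheme: ReductionScheme,
    spec: TupleSpec,
    unknown_policy: str = "mask",
) -> tuple[np.ndarray, int]:
    """One feature row: the normalised reduced K-tuple composition of ``seq``.

    Windows touching a masked (non-standard) position are skipped; the
    denominator is the number of windows actually counted, so the row stays
    on the simplex.  Returns ``(vector, window_count)``.

    Raises
    ------
    NoWindowsError
        If no window could be counted, naming L, the window span, and how
        many windows were skipped due to masked positions.
    """
    reduced = reduce_sequence(seq, scheme, unknown_policy=unknown_policy)
    L = len(reduced)
    windows = enumerate_windows(L, spec) if L >= 1 else []
    rep_index = {rep: i for i, rep in enumerate(scheme.representatives)}
    R = scheme.size
    counts = np.zeros(R**spec.K, dtype=float)
    n_counted = 0
    n_masked_skips = 0
    for window in windows:
        idx = 0
        ok = True
        for pos in window:  # 1-based
            ch = reduced.residues[pos - 1]
            j = rep_index.get(ch)
            if j is None:  # masked position
                ok = False
                break
            idx = idx * R + j
        if ok:
            counts[idx] += 1.0
            n_counted += 1
        else:
            n_masked_skips += 1
    if n_counted == 0:
        raise NoWindowsError(
            f"sequence {seq.id!r}: no extractable windows "
            f"(L={L}, span={spec.span}, "
            f"{n_masked_skips} windows skipped at masked positions)"
        )
    return counts / n_counted, n_counted


def extract_features(
    seqs: list[ProteinSequence],
    scheme: ReductionScheme,
    spec: TupleSpec,
    unknown_policy: str = "mask",
) -> FeatureMatrix:
    """Feature matrix over a sequence set, rows in input order.

    Sequences yielding zero windows are dropped with a logged warning and
    recorded in ``rejects``; if every sequence is rejected an error is
    raised.
    """
    if not seqs:
        raise ValueError("no input sequences")
    columns = tuple_labels(scheme, spec.K)
    rows, ids, counts, rejects = [], [], [], []
    for seq in seqs:
        try:
            vec, n_windows = ktuple_composition(
                seq, scheme, spec, unknown_policy=unknown_policy
            )
        except NoWindowsError as exc:
            logger.warning("dropping sequence: %s", exc)
            rejects.append((seq.id, str(exc)))
            continue
        rows.append(vec)
        ids.append(seq.id)
        counts.append(n_windows)
    if not rows:
        raise NoWindowsError(
            f"all {len(seqs)} sequences were rejected (no extractable windows)"
        )
    return FeatureMatrix(
        column_names=columns,
        values=np.vstack(rows),
        row_ids=ids,
        spec=spec,
        scheme_key=scheme.key,
        window_counts=counts,
        rejects=rejects,
    )
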
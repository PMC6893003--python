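"""Data products behind the sequence, feature and logo visualisations.

Every visual product is first computed as a plain table (TSV-friendly
DataFrame or array), so tests never touch pixels; rendering to SVG/PNG via
matplotlib is optional and thin.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .alphabets import STANDARD_AA, ReductionScheme
from .features import FeatureMatrix
from .reduction import ProteinSequence, reduce_sequence

__all__ = [
    "PALETTE20",
    "LogoMatrix",
    "logo_matrix",
    "alignment_view",
    "feature_heatmap_table",
    "render_logo",
]

#: Fixed qualitative 20-colour palette, indexed by cluster rank.  A reduced
#: alphabet's colours are by construction a subset of the natural ones.
PALETTE20 = (
    "#1f77b4", "#ff7f0e", "#2ca02c", "#d62728", "#9467bd",
    "#8c564b", "#e377c2", "#7f7f7f", "#bcbd22", "#17becf",
    "#aec7e8", "#ffbb78", "#98df8a", "#ff9896", "#c5b0d5",
    "#c49c94", "#f7b6d2", "#c7c7c7", "#dbdb8d", "#9edae5",
)

GAP = "-"


@dataclass
class LogoMatrix:
    """Per-position letter frequencies of an alignment (one stack per column).

    ``freq[p, a]`` is the frequency of alphabet letter ``a`` at position
    ``p + 1`` among non-gap characters; rows with observations sum to 1.
    ``info[p]`` is the information content log2(|alphabet|) - H(freq[p]) in
    bits (0 at all-gap positions, which are listed in ``empty_positions``).
    """

    positions: int
    alphabet: tuple[str, ...]
    freq: np.ndarray  # (positions, len(alphabet))
    info: np.ndarray  # (positions,)
    n_seqs: int
    empty_positions: tuple[int, ...] = ()  # 1-based all-gap columns

    def to_frame(self) -> pd.DataFrame:
        """Long-form table: position, letter, frequency, info_bits."""
        rows = []
        for p in range(self.positions):
            for a, letter in enumerate(self.alphabet):
                if self.freq[p, a] > 0:
                    rows.append((p + 1, letter, self.freq[p, a],
                                 self.info[p]))
        return pd.DataFrame(
            rows, columns=["position", "letter", "frequency", "info_bits"]
        )


def _check_aligned(seqs: list) -> int:
    if len(seqs) < 2:
        raise ValueError("need at least 2 aligned sequences")
    W = len(seqs[0].residues)
    bad = [s.id for s in seqs if len(s.residues) != W]
    if bad:
        raise ValueError(
            f"sequences are not all the same length (expected {W}): "
            f"{', '.join(bad)}"
        )
    return W


def logo_matrix(
    seqs: list[ProteinSequence],
    scheme: ReductionScheme | None = None,
) -> LogoMatrix:
    """Per-position frequency (and information) matrix of an alignment.

    Input sequences must be pre-aligned (equal length; ``-`` as gap).  With
    ``scheme`` given, sequences are reduced first and the logo is over the
    scheme's representative letters; otherwise over the 20 natural letters.
    Gaps and masked residues are excluded from per-position denominators.
    """
    W = _check_aligned(seqs)
    if scheme is None:
        alphabet = tuple(STANDARD_AA)
        rows = [s.residues for s in seqs]
    else:
        alphabet = tuple(scheme.representatives)
        rows = []
        for s in seqs:
            # reduce around gap columns, then re-insert the gaps
            chars = []
            for ch in s.residues:
                if ch == GAP:
                    chars.append(GAP)
                else:
                    reduced = reduce_sequence(
                        ProteinSequence(s.id, ch), scheme, "mask"
                    )
                    chars.append(reduced.residues)
            rows.append("".join(chars))
    index = {a: i for i, a in enumerate(alphabet)}
    freq = np.zeros((W, len(alphabet)))
    for row in rows:
        for p, ch in enumerate(row):
            a = index.get(ch)
            if a is not None:
                freq[p, a] += 1.0
    totals = freq.sum(axis=1)
    empty = tuple(int(p + 1) for p in np.where(totals == 0)[0])
    nonzero = totals > 0
    freq[nonzero] /= totals[nonzero, None]
    # info = log2 |alphabet| - entropy, in bits
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(freq > 0, freq * np.log2(freq), 0.0)
    entropy = -plogp.sum(axis=1)
    info = np.where(nonzero, np.log2(len(alphabet)) - entropy, 0.0)
    return LogoMatrix(
        positions=W, alphabet=alphabet, freq=freq, info=info,
        n_seqs=len(seqs), empty_positions=empty,
    )


def alignment_view(
    seqs: list[ProteinSequence], scheme: ReductionScheme
) -> pd.DataFrame:
    """Paired natural/reduced alignment rows with per-cluster colour indices.

    One row per (sequence, position): natural letter, reduced letter, and
    the colour index of the residue's cluster.  Natural residues take the
    colour of their cluster, so the reduced row's palette is a subset of the
    natural row's by construction.  Gaps and masked residues get index -1.
    """
    _check_aligned(seqs)
    cluster_idx = scheme.mapping_index()
    rows = []
    for s in seqs:
        for p, ch in enumerate(s.residues, start=1):
            c = cluster_idx.get(ch, -1)
            reduced_ch = scheme.representatives[c] if c >= 0 else (
                GAP if ch == GAP else "X"
            )
            rows.append((s.id, p, ch, reduced_ch, c))
    return pd.DataFrame(
        rows, columns=["id", "position", "natural", "reduced", "color_index"]
    )


def feature_heatmap_table(
    matrix: FeatureMatrix, top_n: int = 5
) -> tuple[pd.DataFrame, dict[str, list[tuple[str, float]]]]:
    """Heat-map table plus per-sequence top-n tuple distribution.

    Returns the feature matrix as a DataFrame (unchanged) and, per row, the
    ``top_n`` highest-frequency tuple labels with frequencies; ties broken
    by column order (earlier column wins).
    """
    df = matrix.to_dataframe()
    tops: dict[str, list[tuple[str, float]]] = {}
    for rid, row in zip(matrix.row_ids, matrix.values):
        # stable sort on negated values keeps column order within ties
        order = np.argsort(-row, kind="stable")[:top_n]
        tops[rid] = [(matrix.column_names[j], float(row[j])) for j in order]
    return df, tops


def render_logo(logo: LogoMatrix, path, use_info: bool = False) -> None:
    """Minimal static stacked-bar logo rendering (matplotlib).

    Default display is frequency stacks; ``use_info=True`` scales stacks to
    the position's information content (WebLogo convention).
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(max(4, logo.positions * 0.4), 3))
    for p in range(logo.positions):
        bottom = 0.0
        scale = logo.info[p] if use_info else 1.0
        order = np.argsort(logo.freq[p])
        for a in order:
            h = logo.freq[p, a] * scale
            if h <= 0:
                continue
            color = PALETTE20[a % len(PALETTE20)]
            ax.bar(p + 1, h, bottom=bottom, color=color, width=0.85)
            if h > 0.08 * max(scale, 1e-9):
                ax.text(p + 1, bottom + h / 2, logo.alphabet[a],
                        ha="center", va="center", fontsize=8)
            bottom += h
    ax.set_xlabel("position")
    ax.set_ylabel("bits" if use_info else "frequency")
    ax.set_xlim(0.4, logo.positions + 0.6)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
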
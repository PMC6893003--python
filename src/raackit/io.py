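"""FASTA input/output, synthetic two-class dataset generation, run config.

The synthetic generator emulates binary protein classification benchmarks
(e.g. secretory vs non-secretory sets): negatives are i.i.d. draws from a
background residue distribution; positives share that background but with
the residues of chosen clusters enriched by a multiplicative factor.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .alphabets import STANDARD_AA
from .reduction import ProteinSequence, ReducedSequence

__all__ = [
    "read_fasta",
    "write_fasta",
    "write_reduced_fasta",
    "SyntheticSpec",
    "generate_synthetic",
    "write_synthetic",
    "RunConfig",
]

logger = logging.getLogger(__name__)


def read_fasta(path) -> list[ProteinSequence]:
    """Read protein FASTA records in file order.

    Record ids are the first whitespace-delimited header token; ``*`` (stop)
    is stripped; residues upper-cased; blank lines tolerated; duplicate ids
    are warned about but accepted (ids are not keys).
    """
    path = Path(path)
    records = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta-pearson"):
        residues = str(rec.seq).replace("*", "").strip()
        if not residues:
            raise ValueError(
                f"{path}: record {rec.id!r} has an empty sequence"
            )
        if rec.id in seen:
            logger.warning("%s: duplicate record id %r", path, rec.id)
        seen.add(rec.id)
        desc = rec.description
        if desc.startswith(rec.id):
            desc = desc[len(rec.id):].strip()
        records.append(ProteinSequence(rec.id, residues, desc))
    if not records:
        raise ValueError(f"{path}: no FASTA records found")
    return records


def _wrap(s: str, width: int = 60) -> str:
    return "\n".join(s[i:i + width] for i in range(0, len(s), width))


def write_fasta(seqs: list[ProteinSequence], path, wrap: int = 60) -> None:
    """Write standard FASTA, 60-column wrapped."""
    with open(path, "w") as fh:
        for seq in seqs:
            header = seq.id if not seq.description else f"{seq.id} {seq.description}"
            fh.write(f">{header}\n{_wrap(seq.residues, wrap)}\n")


def write_reduced_fasta(seqs: list[ReducedSequence], path, wrap: int = 60) -> None:
    """Write reduced sequences with ``>{id} | scheme={type} size={R}`` headers."""
    with open(path, "w") as fh:
        for seq in seqs:
            type_id, size = seq.scheme_key
            fh.write(
                f">{seq.id} | scheme={type_id} size={size}\n"
                f"{_wrap(seq.residues, wrap)}\n"
            )


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of a planted-signal two-class protein set.

    ``effect`` multiplies the background probability of every residue in
    ``planted_clusters`` for the positive class (then renormalises);
    ``effect = 1`` makes positives and negatives exchangeable.  Defaults
    follow the study conditions used throughout the test-bench: 100
    sequences per class, lengths 80-120, uniform background, a
    three-residue aromatic planted cluster.
    """

    n_pos: int = 100
    n_neg: int = 100
    length_range: tuple[int, int] = (80, 120)
    background: tuple[float, ...] = tuple([1.0 / 20] * 20)
    planted_clusters: tuple[str, ...] = ("FWY",)
    effect: float = 2.0
    seed: int = 42

    def __post_init__(self) -> None:
        bg = np.asarray(self.background, dtype=float)
        if bg.shape != (20,) or not np.isclose(bg.sum(), 1.0):
            raise ValueError("background must be a 20-dim probability vector")
        if self.effect < 1:
            raise ValueError(f"effect must be >= 1, got {self.effect}")
        bad = set("".join(self.planted_clusters)) - set(STANDARD_AA)
        if bad:
            raise ValueError(
                f"planted cluster letters not standard residues: "
                f"{''.join(sorted(bad))}"
            )
        lo, hi = self.length_range
        if not (1 <= lo <= hi):
            raise ValueError(f"invalid length_range {self.length_range}")

    def class_probabilities(self) -> tuple[np.ndarray, np.ndarray]:
        """(positive, negative) residue probability vectors over STANDARD_AA."""
        neg = np.asarray(self.background, dtype=float)
        pos = neg.copy()
        planted = set("".join(self.planted_clusters))
        for i, aa in enumerate(STANDARD_AA):
            if aa in planted:
                pos[i] *= self.effect
        pos /= pos.sum()
        return pos, neg


def generate_synthetic(
    spec: SyntheticSpec,
) -> tuple[list[ProteinSequence], list[ProteinSequence]]:
    """Draw (positives, negatives) deterministically from ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    pos_p, neg_p = spec.class_probabilities()
    letters = np.array(list(STANDARD_AA))
    lo, hi = spec.length_range

    def draw(n: int, p: np.ndarray, prefix: str) -> list[ProteinSequence]:
        out = []
        for i in range(1, n + 1):
            L = int(rng.integers(lo, hi + 1))
            residues = "".join(rng.choice(letters, size=L, p=p))
            out.append(ProteinSequence(f"{prefix}{i}", residues))
        return out

    return draw(spec.n_pos, pos_p, "pos_"), draw(spec.n_neg, neg_p, "neg_")


def write_synthetic(spec: SyntheticSpec, pos_path, neg_path) -> None:
    """Generate and write the two FASTA files (byte-identical per seed)."""
    pos, neg = generate_synthetic(spec)
    write_fasta(pos, pos_path)
    write_fasta(neg, neg_path)


@dataclass
class RunConfig:
    """Fully serialisable record of one run's inputs.

    Echoed as JSON into the run's output directory; re-running from the
    echoed config reproduces all deterministic outputs byte-identically.
    """

    table: str | None = None  # scheme table path; None = bundled curated table
    type_id: str = "t1"
    size: int = 8
    K: int = 2
    g: int = 0
    lam: int = 0
    unknown_policy: str = "mask"
    classifier: str = "svm"
    hyperparams: dict = field(default_factory=dict)
    folds: int = 5
    loo: bool = False
    seed: int = 42
    output_dir: str = "."
    verbose: bool = False

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True) + "\n"

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        return cls(**json.loads(text))

    def config_hash(self) -> str:
        """sha256 of the canonical JSON form (logged with every run)."""
        return hashlib.sha256(self.to_json().encode()).hexdigest()[:16]
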
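"""Rewrite natural protein sequences over a reduced alphabet.

Positions are 1-based in all human-facing output (error messages, tables);
internally arrays are 0-based.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .alphabets import STANDARD_AA, ReductionScheme, scheme_mapping

__all__ = [
    "AMBIGUOUS_AA",
    "ProteinSequence",
    "ReducedSequence",
    "reduce_sequence",
    "mergence_table",
    "composition_distribution",
    "translate_ambiguous",
]

#: Tolerated non-standard codes: B (D/N), Z (E/Q), X (any), U (Sec), O (Pyl).
AMBIGUOUS_AA = "BZXUO"
#: '-' is tolerated as the alignment gap character (pre-aligned inputs).
_ALLOWED = frozenset(STANDARD_AA + AMBIGUOUS_AA + "-")

#: Conventional substitutions for ambiguous codes (opt-in, never silent).
_AMBIGUOUS_TRANSLATION = {"B": "D", "Z": "E", "U": "C", "O": "K"}


@dataclass(frozen=True)
class ProteinSequence:
    """A FASTA record: identifier, residue string, optional description.

    Residues are upper-cased at construction; ``*`` (stop) must be stripped
    by the reader.  Characters outside the 20 standard letters plus
    ``{B, Z, X, U, O}`` are rejected.
    """

    id: str
    residues: str
    description: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "residues", self.residues.upper())
        if len(self.residues) == 0:
            raise ValueError(f"sequence {self.id!r} is empty")
        bad = sorted(set(self.residues) - _ALLOWED)
        if bad:
            raise ValueError(
                f"sequence {self.id!r} contains unsupported characters: "
                f"{''.join(bad)}"
            )

    def __len__(self) -> int:
        return len(self.residues)


def translate_ambiguous(seq: ProteinSequence) -> ProteinSequence:
    """Apply the conventional B->D, Z->E, U->C, O->K substitutions.

    X remains non-standard.  Opt-in only: silently translating would alter
    compositions invisibly.
    """
    table = str.maketrans(_AMBIGUOUS_TRANSLATION)
    return ProteinSequence(seq.id, seq.residues.translate(table), seq.description)


@dataclass(frozen=True)
class ReducedSequence:
    """A sequence rewritten over a scheme's representative letters.

    ``mask[i]`` is True where the source residue was non-standard (the
    reduced string holds ``X`` there under the mask policy).  Under the drop
    policy ``source_positions`` records, 1-based, where each kept residue sat
    in the source.
    """

    id: str
    residues: str
    scheme_key: tuple[str, int]
    mask: tuple[bool, ...] = field(default=())
    source_positions: tuple[int, ...] = field(default=())

    def __len__(self) -> int:
        return len(self.residues)


def reduce_sequence(
    seq: ProteinSequence,
    scheme: ReductionScheme,
    unknown_policy: str = "mask",
) -> ReducedSequence:
    """Map each residue to its cluster representative.

    Non-standard residues are handled per ``unknown_policy``:

    - ``"mask"`` (default): placeholder ``X`` with the mask flag set;
    - ``"drop"``: removed, with 1-based source positions kept for bookkeeping;
    - ``"error"``: reject, naming the first offending position and character.
    """
    if unknown_policy not in ("mask", "drop", "error"):
        raise ValueError(
            f"unknown_policy must be 'mask', 'drop' or 'error', "
            f"got {unknown_policy!r}"
        )
    mapping = scheme_mapping(scheme)
    out: list[str] = []
    mask: list[bool] = []
    kept: list[int] = []
    for pos, aa in enumerate(seq.residues, start=1):
        rep = mapping.get(aa)
        if rep is not None:
            out.append(rep)
            mask.append(False)
            kept.append(pos)
        elif unknown_policy == "mask":
            out.append("X")
            mask.append(True)
            kept.append(pos)
        elif unknown_policy == "drop":
            continue
        else:
            raise ValueError(
                f"sequence {seq.id!r}: non-standard residue {aa!r} at "
                f"position {pos} (unknown_policy='error')"
            )
    if not out:
        raise ValueError(
            f"sequence {seq.id!r} is empty after dropping non-standard residues"
        )
    return ReducedSequence(
        id=seq.id,
        residues="".join(out),
        scheme_key=scheme.key,
        mask=tuple(mask),
        source_positions=tuple(kept) if unknown_policy == "drop" else (),
    )


def mergence_table(
    seqs: list[ProteinSequence], scheme: ReductionScheme
) -> pd.DataFrame:
    """Natural -> representative residue flow underlying the mergence view.

    One row per natural residue observed in ``seqs``:
    ``(natural, representative, count, frequency)``, frequencies normalised
    over all counted (standard) residues, so the column sums to 1.  Line
    widths of the Sankey-style rendering are proportional to ``frequency``.
    """
    mapping = scheme_mapping(scheme)
    counts: dict[str, int] = {}
    for seq in seqs:
        for aa in seq.residues:
            if aa in mapping:
                counts[aa] = counts.get(aa, 0) + 1
    total = sum(counts.values())
    if total == 0:
        raise ValueError("no standard residues found in input sequences")
    rows = [
        (aa, mapping[aa], counts[aa], counts[aa] / total)
        for aa in STANDARD_AA
        if aa in counts
    ]
    return pd.DataFrame(
        rows, columns=["natural", "representative", "count", "frequency"]
    )


def composition_distribution(
    seqs: list[ProteinSequence], scheme: ReductionScheme
) -> tuple[pd.Series, pd.Series]:
    """Paired natural (20-bin) and reduced (R-bin) composition vectors.

    Both sum to 1; reduced bin r is exactly the sum of the natural bins of
    cluster r.  Non-standard residues are excluded from the denominators.
    """
    table = mergence_table(seqs, scheme)
    natural = pd.Series(0.0, index=list(STANDARD_AA), name="natural")
    natural.update(table.set_index("natural")["frequency"])
    reduced = pd.Series(0.0, index=list(scheme.representatives), name="reduced")
    grouped = table.groupby("representative")["frequency"].sum()
    reduced.update(grouped)
    return natural, reduced
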
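"""Reduced amino-acid alphabet schemes and the flat-file scheme registry.

A *reduction scheme* partitions the 20 standard amino acids into R clusters
(2 <= R <= 20) of physico-chemically or evolutionarily similar residues; a
protein sequence is rewritten over one representative letter per cluster.
Schemes are organised into *types* (families derived by one clustering rule
at several cluster sizes) and stored in a plain TSV registry:

    type<TAB>size<TAB>clusters<TAB>source

where the ``clusters`` column joins cluster strings with ``-``, e.g.
``ARNDQEGHKPST-CILMFWYV`` for a two-letter alphabet.  ``#`` lines are
comments.  The ``source`` column is free text (citation / clustering rule).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Iterator

import numpy as np

__all__ = [
    "STANDARD_AA",
    "ReductionScheme",
    "SchemeRegistry",
    "SchemeError",
    "SchemeParseError",
    "SchemeValidationError",
    "parse_scheme_table",
    "filter_schemes",
    "scheme_mapping",
    "load_curated_registry",
    "identity_scheme",
    "synthetic_registry_text",
]

#: The 20 standard one-letter amino acid codes, alphabetical.
STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"
_STANDARD_SET = frozenset(STANDARD_AA)


class SchemeError(ValueError):
    """Base class for scheme table problems."""


class SchemeParseError(SchemeError):
    """A table line that cannot be split into the mandatory columns."""

    def __init__(self, message: str, line_number: int | None = None):
        super().__init__(message)
        self.line_number = line_number


class SchemeValidationError(SchemeError):
    """A parsed scheme whose clusters are not a partition of the 20 residues."""

    def __init__(self, message: str, missing: str = "", duplicated: str = "",
                 line_number: int | None = None):
        super().__init__(message)
        self.missing = missing
        self.duplicated = duplicated
        self.line_number = line_number


@dataclass(frozen=True)
class ReductionScheme:
    """One named partition of the 20 standard amino acids into R clusters.

    Parameters
    ----------
    type_id : str
        Label of the alphabet family, e.g. ``"t1"`` or ``"type 11"``.
    size : int
        Number of clusters R, ``2 <= R <= 20`` (20 is the identity alphabet).
    clusters : tuple of str
        Ordered, disjoint, exhaustive partition of the 20 standard residues.
    representatives : tuple of str
        One representative letter per cluster; by convention the first letter
        of each cluster string as written in the table.
    source : str
        Free-text citation / clustering-rule description.
    """

    type_id: str
    size: int
    clusters: tuple[str, ...]
    representatives: tuple[str, ...]
    source: str = ""

    def __post_init__(self) -> None:
        pooled = "".join(self.clusters)
        counts: dict[str, int] = {}
        for ch in pooled:
            counts[ch] = counts.get(ch, 0) + 1
        missing = "".join(a for a in STANDARD_AA if a not in counts)
        duplicated = "".join(sorted(c for c, n in counts.items() if n > 1))
        foreign = "".join(sorted(set(pooled) - _STANDARD_SET))
        if missing or duplicated or foreign:
            parts = []
            if missing:
                parts.append(f"missing residues: {missing}")
            if duplicated:
                parts.append(f"duplicated residues: {duplicated}")
            if foreign:
                parts.append(f"non-standard letters: {foreign}")
            raise SchemeValidationError(
                f"clusters of scheme ({self.type_id!r}, size {self.size}) are not a "
                f"partition of the 20 standard residues ({'; '.join(parts)})",
                missing=missing,
                duplicated=duplicated,
            )
        if self.size != len(self.clusters):
            raise SchemeValidationError(
                f"declared size {self.size} != number of clusters "
                f"{len(self.clusters)} for type {self.type_id!r}"
            )
        if any(c == "" for c in self.clusters):
            raise SchemeValidationError("empty cluster in scheme")
        if len(set(self.representatives)) != len(self.representatives):
            raise SchemeValidationError("representatives are not pairwise distinct")
        for rep, cluster in zip(self.representatives, self.clusters):
            if rep not in cluster:
                raise SchemeValidationError(
                    f"representative {rep!r} is not a member of cluster {cluster!r}"
                )

    @classmethod
    def from_clusters(cls, type_id: str, clusters: Iterable[str],
                      source: str = "") -> "ReductionScheme":
        """Build a scheme taking each cluster's first letter as representative."""
        cl = tuple(c.upper() for c in clusters)
        reps = tuple(c[0] for c in cl if c)
        return cls(type_id=type_id, size=len(cl), clusters=cl,
                   representatives=reps, source=source)

    @property
    def key(self) -> tuple[str, int]:
        return (self.type_id, self.size)

    def cluster_of(self, residue: str) -> int:
        """Index of the cluster containing ``residue`` (KeyError if non-standard)."""
        return self.mapping_index()[residue]

    def mapping_index(self) -> dict[str, int]:
        """Residue -> cluster-index map (cached on first use)."""
        idx = getattr(self, "_idx", None)
        if idx is None:
            idx = {a: i for i, c in enumerate(self.clusters) for a in c}
            object.__setattr__(self, "_idx", idx)
        return idx

    def to_table_line(self) -> str:
        return "\t".join(
            [self.type_id, str(self.size), "-".join(self.clusters), self.source]
        )


def scheme_mapping(scheme: ReductionScheme) -> dict[str, str]:
    """Materialise the partition as a 20-entry residue -> representative map.

    Applying the map twice equals applying it once: representatives map to
    themselves.
    """
    return {
        a: scheme.representatives[i]
        for a, i in scheme.mapping_index().items()
    }


_TRAILING_INT = re.compile(r"(\d+)\s*$")


def _type_sort_key(type_id: str) -> tuple[str, float, str]:
    """Sort types numerically on a trailing integer ('type 2' < 'type 11')."""
    m = _TRAILING_INT.search(type_id)
    if m:
        return (type_id[: m.start()].strip().lower(), int(m.group(1)), type_id)
    return (type_id.strip().lower(), float("inf"), type_id)


@dataclass
class SchemeRegistry:
    """Collection of :class:`ReductionScheme` keyed by ``(type_id, size)``."""

    schemes: dict[tuple[str, int], ReductionScheme] = field(default_factory=dict)
    #: (line_number, message) pairs for rows rejected during lenient parsing.
    rejects: list[tuple[int, str]] = field(default_factory=list)

    def add(self, scheme: ReductionScheme) -> None:
        if scheme.key in self.schemes:
            raise SchemeError(f"duplicate scheme key {scheme.key}")
        self.schemes[scheme.key] = scheme

    def get(self, type_id: str, size: int) -> ReductionScheme:
        try:
            return self.schemes[(type_id, int(size))]
        except KeyError:
            raise KeyError(
                f"no scheme with type {type_id!r} and size {size}; "
                f"available types: {', '.join(self.type_ids()) or '(none)'}"
            ) from None

    def type_ids(self) -> list[str]:
        return sorted({t for t, _ in self.schemes}, key=_type_sort_key)

    def __len__(self) -> int:
        return len(self.schemes)

    def __iter__(self) -> Iterator[ReductionScheme]:
        for key in sorted(self.schemes, key=lambda k: (_type_sort_key(k[0]), k[1])):
            yield self.schemes[key]

    def serialize(self) -> str:
        """Canonical scheme-TSV text (round-trips through parse_scheme_table)."""
        lines = ["type\tsize\tclusters\tsource"]
        lines.extend(s.to_table_line() for s in self)
        return "\n".join(lines) + "\n"


def parse_scheme_table(table_text: str, strict: bool = True) -> SchemeRegistry:
    """Parse scheme-TSV text into a :class:`SchemeRegistry`.

    Format: header ``type	size	clusters	source`` (header optional but
    conventional), one scheme per line, clusters joined by ``-``, ``#`` lines
    ignored, input upper-cased before validation.

    With ``strict=True`` (default) the first malformed or invalid row raises
    :class:`SchemeParseError` / :class:`SchemeValidationError` naming the line;
    with ``strict=False`` bad rows are collected in ``registry.rejects``.
    """
    if not table_text or not table_text.strip():
        raise SchemeParseError("scheme table text is empty")
    registry = SchemeRegistry()
    seen_data = False
    for lineno, raw in enumerate(table_text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        cols = line.split("\t")
        if not seen_data and cols[0].strip().lower() == "type":
            seen_data = True
            continue  # header
        seen_data = True
        try:
            if len(cols) < 3:
                raise SchemeParseError(
                    f"line {lineno}: expected at least 3 tab-separated columns "
                    f"(type, size, clusters), got {len(cols)}",
                    line_number=lineno,
                )
            type_id = cols[0].strip()
            try:
                size = int(cols[1])
            except ValueError:
                raise SchemeParseError(
                    f"line {lineno}: size column {cols[1]!r} is not an integer",
                    line_number=lineno,
                ) from None
            clusters = tuple(
                c for c in cols[2].strip().upper().split("-") if c != ""
            )
            source = cols[3].strip() if len(cols) > 3 else ""
            scheme = ReductionScheme.from_clusters(type_id, clusters, source)
            if scheme.size != size:
                raise SchemeValidationError(
                    f"line {lineno}: declared size {size} != "
                    f"{scheme.size} parsed clusters",
                    line_number=lineno,
                )
            registry.add(scheme)
        except SchemeError as exc:
            if isinstance(exc, SchemeValidationError) and exc.line_number is None:
                exc.line_number = lineno
            if strict:
                if not str(exc).startswith(f"line {lineno}"):
                    exc.args = (f"line {lineno}: {exc}",) + exc.args[1:]
                raise
            registry.rejects.append((lineno, str(exc)))
    if not registry.schemes and strict:
        raise SchemeParseError("scheme table contains no data rows")
    return registry


def filter_schemes(
    registry: SchemeRegistry,
    type_id: str | None = None,
    size: int | None = None,
    keyword: str | None = None,
) -> list[ReductionScheme]:
    """All schemes matching every provided criterion, in canonical order.

    Criteria are conjunctive; ``keyword`` is a case-insensitive substring
    match against the scheme's ``source`` text and ``type_id``.  An empty
    result is not an error.
    """
    out = []
    kw = keyword.lower() if keyword is not None else None
    for scheme in registry:
        if type_id is not None and scheme.type_id != type_id:
            continue
        if size is not None and scheme.size != int(size):
            continue
        if kw is not None and kw not in scheme.source.lower() \
                and kw not in scheme.type_id.lower():
            continue
        out.append(scheme)
    return out


def identity_scheme() -> ReductionScheme:
    """The size-20 identity alphabet (each residue is its own cluster)."""
    return ReductionScheme.from_clusters(
        "t0", tuple(STANDARD_AA), source="identity alphabet"
    )


def load_curated_registry() -> SchemeRegistry:
    """Load the bundled curated table of published reduced alphabets."""
    text = (
        resources.files("raackit").joinpath("data/curated_schemes.tsv").read_text()
    )
    return parse_scheme_table(text)


def synthetic_registry_text(
    n_types: int = 74, n_schemes: int = 673, seed: int = 20190814
) -> str:
    """Deterministically generate a SYNTHETIC full-scale scheme table.

    This is a synthetic stand-in emulating the scale of a curated
    reduced-alphabet database — ``n_types`` alphabet families comprising
    ``n_schemes`` schemes in total, every one a valid partition of the 20
    standard residues.  Cluster memberships are random (seeded), so the
    schemes carry no biological meaning; they exercise registry-scale
    parsing, filtering and validation only.

    Scheme counts per type are balanced (sizes cycle through 2..20), and the
    output is byte-identical for a given ``(n_types, n_schemes, seed)``.
    """
    if n_schemes < n_types:
        raise ValueError("need at least one scheme per type")
    if n_schemes > n_types * 19:
        raise ValueError("at most 19 distinct sizes (2..20) per type")
    rng = np.random.default_rng(seed)
    base, extra = divmod(n_schemes, n_types)
    lines = ["type\tsize\tclusters\tsource"]
    all_sizes = list(range(2, 21))
    for t in range(1, n_types + 1):
        n_here = base + (1 if t <= extra else 0)
        start = (t * 7) % len(all_sizes)  # vary which sizes each type covers
        sizes = [all_sizes[(start + j) % len(all_sizes)] for j in range(n_here)]
        for size in sorted(sizes):
            letters = list(STANDARD_AA)
            rng.shuffle(letters)
            # size clusters: random split points over the shuffled alphabet
            cuts = np.sort(rng.choice(np.arange(1, 20), size=size - 1,
                                      replace=False))
            bounds = [0, *cuts.tolist(), 20]
            clusters = [
                "".join(letters[bounds[i]:bounds[i + 1]]) for i in range(size)
            ]
            lines.append(
                f"t{t}\t{size}\t{'-'.join(clusters)}\tsynthetic stand-in scheme"
            )
    return "\n".join(lines) + "\n"
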
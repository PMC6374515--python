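"""Domain-architecture data model.

A protein is an ordered N->C list of domain annotations drawn from a small
controlled vocabulary (Sema, PSI, IPT, FNIII, TSP1, Ig, ...). The optional
transmembrane (TM) annotation splits the architecture into an extracellular
(ecto) and an intracellular (endo) segment; everything in a protein without
a TM is treated as extracellular. Coordinates, when present, are 1-based
inclusive residue indices and must be non-overlapping and increasing.

All downstream classification works from token order alone, so records
without coordinates (the packaged fixture) are first-class citizens.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

from .errors import StructureError, VocabularyError
from .taxa import check_species

#: Controlled vocabulary of domain kinds.
DOMAIN_KINDS = frozenset(
    {
        "SEMA", "PSI", "PSI_LIKE", "IPT", "FN3", "TSP1", "IG", "SEA",
        "TM", "SIGNAL", "GPI", "RASGAP", "RBD", "TYRKIN", "UNKNOWN",
    }
)

#: Spelling variants accepted by :func:`parse_architecture` (case-insensitive).
TOKEN_ALIASES: dict[str, str] = {
    "SEMA": "SEMA",
    "PSI": "PSI",
    "PSI_LIKE": "PSI_LIKE",
    "PSILIKE": "PSI_LIKE",
    "IPT": "IPT",
    "FN3": "FN3",
    "FNIII": "FN3",
    "TSP1": "TSP1",
    "TSP_1": "TSP1",
    "IG": "IG",
    "SEA": "SEA",
    "TM": "TM",
    "SIGNAL": "SIGNAL",
    "GPI": "GPI",
    "RASGAP": "RASGAP",
    "RAS_GAP": "RASGAP",
    "RBD": "RBD",
    "TYRKIN": "TYRKIN",
    "UNKNOWN": "UNKNOWN",
}

TOPOLOGIES = frozenset({"secreted", "transmembrane", "gpi_anchored", "unknown"})


def normalize_kind(token: str) -> str:
    """Map a spelling variant to its vocabulary kind, or raise."""
    kind = TOKEN_ALIASES.get(token.strip().upper().replace("-", "_"))
    if kind is None:
        raise VocabularyError(f"unknown domain token: {token!r}")
    return kind


@dataclass(frozen=True)
class DomainAnnotation:
    """One annotated domain.

    ``certainty`` distinguishes confident annotations from tentative ones
    (e.g. FNIII repeats inferred from spacing only); ``truncated`` flags a
    domain interrupted by missing sequence.
    """

    kind: str
    start: int | None = None
    end: int | None = None
    certainty: str = "high"
    truncated: bool = False
    source_name: str | None = None  # original profile name for UNKNOWN kinds

    def __post_init__(self):
        if self.kind not in DOMAIN_KINDS:
            raise VocabularyError(f"unknown domain kind: {self.kind!r}")
        if self.certainty not in ("high", "low"):
            raise VocabularyError(f"certainty must be 'high' or 'low', got {self.certainty!r}")
        if (self.start is None) != (self.end is None):
            raise StructureError("start and end must be given together")
        if self.start is not None:
            if self.start < 1:
                raise StructureError(f"start must be >= 1, got {self.start}")
            if self.end < self.start:
                raise StructureError(f"end ({self.end}) < start ({self.start})")


def _check_positions(domains: Sequence[DomainAnnotation]) -> None:
    positioned = [d for d in domains if d.start is not None]
    for a, b in zip(positioned, positioned[1:]):
        if b.start <= a.end:
            raise StructureError(
                f"overlapping domains: {a.kind} {a.start}-{a.end} and {b.kind} {b.start}-{b.end}"
            )


@dataclass(frozen=True)
class ArchitectureString:
    """A validated N->C domain-token sequence split at the TM marker.

    ``ecto`` precedes ``tm`` precedes ``endo``. At most one TM is allowed;
    architectures without TM have everything in ``ecto``.
    """

    domains: tuple[DomainAnnotation, ...]

    def __post_init__(self):
        if not self.domains:
            raise StructureError("empty architecture")
        _check_positions(self.domains)
        if sum(1 for d in self.domains if d.kind == "TM") > 1:
            raise StructureError("more than one TM annotation")

    @property
    def tokens(self) -> tuple[str, ...]:
        return tuple(d.kind for d in self.domains)

    @property
    def has_tm(self) -> bool:
        return "TM" in self.tokens

    def _tm_index(self) -> int:
        return self.tokens.index("TM")

    @property
    def ecto(self) -> tuple[DomainAnnotation, ...]:
        if not self.has_tm:
            return self.domains
        return self.domains[: self._tm_index()]

    @property
    def endo(self) -> tuple[DomainAnnotation, ...]:
        if not self.has_tm:
            return ()
        return self.domains[self._tm_index() + 1:]

    def count(self, kind: str, segment: str = "all") -> int:
        """Number of domains of ``kind`` in 'ecto', 'endo' or 'all'."""
        if segment == "all":
            part: Iterable[DomainAnnotation] = self.domains
        elif segment == "ecto":
            part = self.ecto
        elif segment == "endo":
            part = self.endo
        else:
            raise ValueError(f"segment must be ecto/endo/all, got {segment!r}")
        return sum(1 for d in part if d.kind == kind)

    def counts(self, segment: str = "all") -> Counter:
        part = {"all": self.domains, "ecto": self.ecto, "endo": self.endo}[segment]
        return Counter(d.kind for d in part)

    def has_tandem(self, kind: str, n: int = 2) -> bool:
        """True if >= n consecutive domains of ``kind`` occur."""
        run = best = 0
        for t in self.tokens:
            run = run + 1 if t == kind else 0
            best = max(best, run)
        return best >= n

    def __str__(self) -> str:
        return "-".join(self.tokens)


def parse_architecture(tokens) -> ArchitectureString:
    """Build a validated :class:`ArchitectureString`.

    ``tokens`` may be a hyphen-separated string ("Sema-PSI-IPT-...-TM"), an
    iterable of token strings, or an iterable of :class:`DomainAnnotation`.
    Idempotent on its own output.
    """
    if isinstance(tokens, ArchitectureString):
        return tokens
    if isinstance(tokens, str):
        tokens = tokens.split("-")
    items = list(tokens)
    if not items:
        raise StructureError("empty architecture")
    domains = []
    for item in items:
        if isinstance(item, DomainAnnotation):
            domains.append(item)
        else:
            domains.append(DomainAnnotation(kind=normalize_kind(item)))
    # input order is the N->C order; positioned domains must already increase
    return ArchitectureString(domains=tuple(domains))


@dataclass(frozen=True)
class ProteinRecord:
    """One surveyed protein: identity, membrane topology, and architecture."""

    protein_id: str
    species: str
    clade: str
    topology: str
    architecture: ArchitectureString
    truncated: bool = False
    sequence: str | None = None

    def __post_init__(self):
        check_species(self.species)
        if self.topology not in TOPOLOGIES:
            raise VocabularyError(f"unknown topology: {self.topology!r}")
        if self.topology == "transmembrane" and not self.architecture.has_tm:
            raise StructureError(
                f"{self.protein_id}: transmembrane topology but no TM annotation"
            )

    @property
    def ecto(self) -> tuple[DomainAnnotation, ...]:
        return self.architecture.ecto

    @property
    def endo(self) -> tuple[DomainAnnotation, ...]:
        return self.architecture.endo

    def with_id(self, protein_id: str) -> "ProteinRecord":
        return replace(self, protein_id=protein_id)
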
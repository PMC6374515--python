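"""The fourteen study taxa: acronyms, clades, and clade groupings.

Acronyms are the five-letter species codes used throughout (gene-tree leaf
labels, fixture tables, species-tree tips). Each species stands for one
clade of the reference phylogeny, except the two choanoflagellates which
share Choanoflagellida.
"""

from __future__ import annotations

from .errors import UnknownSpeciesError

#: acronym -> (full species name, clade)
SPECIES: dict[str, tuple[str, str]] = {
    "Mbrev": ("Monosiga brevicollis", "Choanoflagellida"),
    "Srose": ("Salpingoeca rosetta", "Choanoflagellida"),
    "Aquee": ("Amphimedon queenslandica", "Porifera"),
    "Mleid": ("Mnemiopsis leidyi", "Ctenophora"),
    "Tadha": ("Trichoplax adhaerens", "Placozoa"),
    "Nvect": ("Nematostella vectensis", "Cnidaria"),
    "Ctele": ("Capitella teleta", "Annelida"),
    "Acali": ("Aplysia californica", "Mollusca"),
    "Celeg": ("Caenorhabditis elegans", "Nematoda"),
    "Smari": ("Strigamia maritima", "Myriapoda"),
    "Dmela": ("Drosophila melanogaster", "Insecta"),
    "Aplan": ("Acanthaster planci", "Echinodermata"),
    "Bbelc": ("Branchiostoma belcheri", "Cephalochordata"),
    "Hsapi": ("Homo sapiens", "Vertebrata"),
}

CLADES = frozenset(clade for _, clade in SPECIES.values())

PROTOSTOMIA = frozenset({"Annelida", "Mollusca", "Nematoda", "Myriapoda", "Insecta"})
DEUTEROSTOMIA = frozenset({"Echinodermata", "Cephalochordata", "Vertebrata"})
NON_BILATERIA = frozenset(
    {"Choanoflagellida", "Porifera", "Ctenophora", "Placozoa", "Cnidaria"}
)


def clade_of(acronym: str) -> str:
    """Return the clade a species acronym belongs to.

    Raises :class:`UnknownSpeciesError` for acronyms outside the study set.
    """
    try:
        return SPECIES[acronym][1]
    except KeyError:
        raise UnknownSpeciesError(f"unknown species acronym: {acronym!r}") from None


def check_species(acronym: str) -> str:
    """Validate an acronym, returning it unchanged."""
    clade_of(acronym)
    return acronym
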
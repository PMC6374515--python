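"""Packaged survey inventory: 131 Sema-domain proteins across 14 species.

The inventory transcribes, at domain-token level, the published domain
cartoons and species survey text for plexins, semaphorins, and Met / Met-LP
receptor tyrosine kinases from choanoflagellates to human. Coordinates are
deliberately absent: the classifier works from token order alone.

The compact table below is the single source of truth; the packaged TSV
(``data/sema_inventory.tsv``, same schema as any domain table) is generated
from it and a test keeps the two in sync. Counts that the survey gives only
as ranges ("five to seven FNIII domains") are pinned to one representative
value per protein and noted inline.
"""

from __future__ import annotations

from functools import lru_cache
from pathlib import Path

from .arch import ProteinRecord, parse_architecture
from .errors import UnknownSpeciesError
from .io import read_domain_table
from .taxa import SPECIES, clade_of

_DATA_DIR = Path(__file__).parent / "data"
FIXTURE_TSV = _DATA_DIR / "sema_inventory.tsv"

# canonical architectures
_PLEXIN_ECTO = "SEMA-PSI-IPT-PSI-IPT-PSI-IPT-IPT-IPT-IPT"
PLEXIN_FULL = _PLEXIN_ECTO + "-TM-RASGAP"
PLEXIN_TRUNC = _PLEXIN_ECTO + "-TM"  # short intracellular part, no conserved domain
MET = "SEMA-PSI-IPT-IPT-IPT-IPT-TM-TYRKIN"  # truncated plexin-like ectodomain
MET_LP = _PLEXIN_ECTO + "-TM-TYRKIN"  # complete plexin ectodomain


def _sema_fn(n_fn3: int, sea: bool = True) -> str:
    stalk = "-".join(["FN3"] * n_fn3)
    return f"SEMA-PSI-{stalk}" + ("-SEA" if sea else "") + "-TM"


def _sema5(n_tsp1: int) -> str:
    return "SEMA-PSI-" + "-".join(["TSP1"] * n_tsp1) + "-TM"


# per-species inventory: (protein_id, topology, architecture, record_truncated)
_TM = "transmembrane"
_SEC = "secreted"
_GPI = "gpi_anchored"

INVENTORY: dict[str, list[tuple[str, str, str, bool]]] = {
    # Choanoflagellida: one plexin and one Sema-FN semaphorin each
    "Mbrev": [
        ("Plexin-1", _TM, PLEXIN_FULL, False),
        ("Sema-FN1", _TM, _sema_fn(6), False),  # 5-7 FNIII range
    ],
    "Srose": [
        ("Plexin-1", _TM, PLEXIN_FULL, False),
        ("Sema-FN1", _TM, _sema_fn(7), False),  # 5-7 FNIII range
    ],
    # Porifera: six plexins (four intracellularly truncated), four semaphorins
    "Aquee": [
        ("Plexin-1", _TM, PLEXIN_FULL, False),
        ("Plexin-A1", _TM, PLEXIN_TRUNC, True),
        ("Plexin-A2", _TM, PLEXIN_TRUNC, True),
        ("Plexin-A3", _TM, PLEXIN_TRUNC, True),
        ("Plexin-A4", _TM, PLEXIN_TRUNC, True),
        ("Plexin-A5", _TM, PLEXIN_FULL, False),
        ("Sema-FN1", _TM, _sema_fn(5, sea=False), False),  # 5 confidently detected FNIII
        ("Sema1A", _TM, "SEMA-PSI-TM", False),
        ("Sema1B", _TM, "SEMA-PSI-TM", False),
        ("Sema1C", _TM, "SEMA-PSI-TM", False),
    ],
    # Ctenophora: four plexins, three secreted Sema1-type, six Sema-IG
    "Mleid": [
        ("Plexin-1", _TM, PLEXIN_FULL, False),
        ("Plexin-2", _TM, PLEXIN_FULL, False),
        ("Plexin-3", _TM, PLEXIN_FULL, False),
        ("Plexin-4", _TM, PLEXIN_FULL, False),
        ("Sema1A", _SEC, "SEMA-PSI", False),
        ("Sema1B", _SEC, "SEMA-PSI", False),
        ("Sema1C", _SEC, "SEMA-PSI", False),
        ("Sema-IG1", _TM, "SEMA-PSI-IG-IG-TM", False),
        ("Sema-IG2", _TM, "SEMA-PSI-IG-IG-TM", False),
        ("Sema-IG3", _TM, "SEMA-PSI-IG-IG-TM", False),
        ("Sema-IG4", _TM, "SEMA-PSI-IG-IG-TM", False),
        ("Sema-IG5", _TM, "SEMA-PSI-IG-IG-TM", False),
        ("Sema-IG6", _TM, "SEMA-PSI-IG-IG-TM", False),
    ],
    # Placozoa: two plexins (predicted deletions), Sema-FN with one FNIII,
    # Sema5 with seven TSP1
    "Tadha": [
        ("Plexin-A1", _TM, PLEXIN_FULL, True),
        ("Plexin-A2", _TM, PLEXIN_FULL, True),
        ("Sema-FN1", _TM, _sema_fn(1, sea=False), False),
        ("Sema5A", _TM, _sema5(7), False),
    ],
    # Cnidaria
    "Nvect": [
        ("Plexin-1", _TM, PLEXIN_FULL, False),
        ("Sema5A", _TM, _sema5(5), False),
    ],
    # Annelida
    "Ctele": [
        ("Plexin-1", _TM, PLEXIN_FULL, False),
        ("Plexin-2", _TM, PLEXIN_FULL, False),
        ("Sema1A", _TM, "SEMA-PSI-TM", False),
        ("Sema2A", _SEC, "SEMA-PSI-IG", False),
        ("Sema5A", _TM, _sema5(5), False),
        ("Met", _TM, MET, False),
        ("Met-LP1", _TM, MET_LP, False),
    ],
    # Mollusca
    "Acali": [
        ("Plexin-1", _TM, PLEXIN_FULL, False),
        ("Plexin-2", _TM, PLEXIN_FULL, False),
        ("Sema1A", _TM, "SEMA-PSI-TM", False),
        ("Sema2A", _SEC, "SEMA-PSI-IG", False),
        ("Sema5A", _TM, _sema5(5), False),
        ("Met", _TM, MET, False),
        ("Met-LP1", _TM, MET_LP, False),
    ],
    # Nematoda (reference set)
    "Celeg": [
        ("Plexin-1", _TM, PLEXIN_FULL, False),
        ("Plexin-2", _TM, PLEXIN_FULL, False),
        ("Sema1A", _TM, "SEMA-PSI-TM", False),
        ("Sema1B", _TM, "SEMA-PSI-TM", False),
        ("Sema2A", _SEC, "SEMA-PSI-IG", False),
    ],
    # Myriapoda
    "Smari": [
        ("Plexin-1", _TM, PLEXIN_FULL, False),
        ("Plexin-2", _TM, PLEXIN_FULL, False),
        ("Sema1A", _TM, "SEMA-PSI-TM", False),
        ("Sema1B", _TM, "SEMA-PSI-TM", False),
        ("Sema1C", _TM, "SEMA-PSI-TM", False),
        ("Sema2A", _SEC, "SEMA-PSI-IG", False),
        ("Sema5A", _TM, _sema5(5), False),
    ],
    # Insecta (reference set)
    "Dmela": [
        ("Plexin-A", _TM, PLEXIN_FULL, False),
        ("Plexin-B", _TM, PLEXIN_FULL, False),
        ("Sema1A", _TM, "SEMA-PSI-TM", False),
        ("Sema1B", _TM, "SEMA-PSI-TM", False),
        ("Sema2A", _SEC, "SEMA-PSI-IG", False),
        ("Sema2B", _SEC, "SEMA-PSI-IG", False),
        ("Sema5C", _TM, _sema5(5), False),
    ],
    # Echinodermata: family expansion; Sema-SI/-SP are new secreted classes
    "Aplan": [
        ("Plexin-A1", _TM, PLEXIN_FULL, False),
        ("Plexin-A2", _TM, PLEXIN_FULL, False),
        ("Plexin-A3", _TM, "SEMA-PSI-IPT-TM", True),  # short fragment
        ("Plexin-B1", _TM, PLEXIN_FULL, False),
        ("Plexin-B2", _TM, PLEXIN_FULL, False),
        ("Plexin-B3", _TM, PLEXIN_FULL, False),
        ("Plexin-B4", _TM, PLEXIN_FULL, False),
        ("Plexin-B5", _TM, PLEXIN_FULL, False),
        ("Plexin-B6", _TM, PLEXIN_FULL, False),
        ("Plexin-B7", _TM, PLEXIN_FULL, False),
        ("Plexin-B8", _TM, PLEXIN_FULL, False),
        ("Met", _TM, MET, False),
        ("Met-LP1", _TM, MET_LP, False),
        ("Met-LP2", _TM, MET_LP, False),
        ("Met-LP3", _TM, MET_LP, False),
        ("Met-LP4", _TM, MET_LP, False),
        ("Sema5A", _TM, _sema5(5), False),
        ("Sema6A", _TM, "SEMA-PSI-TM", False),
        ("Sema-SI1", _SEC, "SEMA-PSI_LIKE", False),  # lacks the Ig domain
        ("Sema-SI2", _SEC, "SEMA-PSI_LIKE-IG", False),
        ("Sema-SI3", _SEC, "SEMA-PSI_LIKE-IG", False),
        ("Sema-SI4", _SEC, "SEMA-PSI_LIKE-IG", False),
        ("Sema-SP1", _SEC, "SEMA-PSI", False),
        ("Sema-SP2", _SEC, "SEMA-PSI", False),
        ("Sema-SP3", _SEC, "SEMA-PSI", False),
        ("Sema-SP4", _SEC, "SEMA-PSI", False),
        ("Sema-SP5", _SEC, "SEMA-PSI", False),
        ("Sema-SP6", _SEC, "SEMA-PSI", False),
    ],
    # Cephalochordata
    "Bbelc": [
        ("Plexin-1", _TM, PLEXIN_FULL, False),
        ("Plexin-2", _TM, PLEXIN_FULL, False),
        ("Met", _TM, MET, False),
        ("Sema5A", _TM, _sema5(5), False),
        ("Sema6A", _TM, "SEMA-PSI-TM", False),
        ("Sema6B", _TM, "SEMA-PSI-TM", False),
    ],
    # Vertebrata (reference set, genenames)
    "Hsapi": [
        ("Plexin-A1", _TM, PLEXIN_FULL, False),
        ("Plexin-A2", _TM, PLEXIN_FULL, False),
        ("Plexin-A3", _TM, PLEXIN_FULL, False),
        ("Plexin-A4", _TM, PLEXIN_FULL, False),
        ("Plexin-B1", _TM, PLEXIN_FULL, False),
        ("Plexin-B2", _TM, PLEXIN_FULL, False),
        ("Plexin-B3", _TM, PLEXIN_FULL, False),
        # Plexin-C1 lacks one PSI and two IPT domains
        ("Plexin-C1", _TM, "SEMA-PSI-IPT-PSI-IPT-IPT-IPT-TM-RASGAP", False),
        ("Plexin-D1", _TM, PLEXIN_FULL, False),
        ("Met", _TM, MET, False),
        ("Ron", _TM, MET, False),
        ("Sema3A", _SEC, "SEMA-PSI-IG", False),
        ("Sema3B", _SEC, "SEMA-PSI-IG", False),
        ("Sema3C", _SEC, "SEMA-PSI-IG", False),
        ("Sema3D", _SEC, "SEMA-PSI-IG", False),
        ("Sema3E", _SEC, "SEMA-PSI-IG", False),
        ("Sema3F", _SEC, "SEMA-PSI-IG", False),
        ("Sema3G", _SEC, "SEMA-PSI-IG", False),
        ("Sema4A", _TM, "SEMA-PSI-IG-TM", False),
        ("Sema4B", _TM, "SEMA-PSI-IG-TM", False),
        ("Sema4C", _TM, "SEMA-PSI-IG-TM", False),
        ("Sema4D", _TM, "SEMA-PSI-IG-TM", False),
        ("Sema4F", _TM, "SEMA-PSI-IG-TM", False),
        ("Sema4G", _TM, "SEMA-PSI-IG-TM", False),
        ("Sema5A", _TM, _sema5(7), False),
        ("Sema5B", _TM, _sema5(7), False),
        ("Sema6A", _TM, "SEMA-PSI-TM", False),
        ("Sema6B", _TM, "SEMA-PSI-TM", False),
        ("Sema6C", _TM, "SEMA-PSI-TM", False),
        ("Sema6D", _TM, "SEMA-PSI-TM", False),
        ("Sema7A", _GPI, "SEMA-PSI-IG", False),
    ],
}


def inventory_records(species: str | None = None) -> list[ProteinRecord]:
    """Expand the compact inventory table into protein records."""
    if species is not None and species not in INVENTORY:
        raise UnknownSpeciesError(f"no fixture inventory for {species!r}")
    acronyms = [species] if species else list(SPECIES)
    records = []
    for acr in acronyms:
        for pid, topology, arch, truncated in INVENTORY[acr]:
            records.append(
                ProteinRecord(
                    protein_id=pid,
                    species=acr,
                    clade=clade_of(acr),
                    topology=topology,
                    architecture=parse_architecture(arch),
                    truncated=truncated,
                )
            )
    return records


@lru_cache(maxsize=1)
def _packaged_records() -> tuple[ProteinRecord, ...]:
    return tuple(read_domain_table(FIXTURE_TSV))


def load_fixture(species: str | None = None) -> list[ProteinRecord]:
    """Load the packaged survey inventory from the shipped TSV.

    With ``species`` given (five-letter acronym) only that species'
    proteins are returned; otherwise all 131 records.
    """
    if species is not None and species not in INVENTORY:
        raise UnknownSpeciesError(f"no fixture inventory for {species!r}")
    records = list(_packaged_records())
    if species is not None:
        records = [r for r in records if r.species == species]
    return records
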
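"""Family and class assignment for Sema-domain proteins.

The decision table encodes the structural definitions of the survey:

* family level — an intracellular tyrosine kinase plus a complete plexin
  ectodomain (>=2 PSI) is a Met-LP RTK; a tyrosine kinase behind the
  truncated Sema+PSI+IPT ectodomain is a Met RTK; IPT repeats without a
  kinase make a plexin (full-length iff the intracellular Ras-GAP domain is
  present); no IPT and no kinase is a semaphorin.
* semaphorin class level — TSP1 repeats define class 5 in every clade;
  FNIII repeats define the Sema-FN class; a degenerate PSI ("PSI-like")
  marks the echinoderm Sema-SI class; tandem Ig domains in Ctenophora mark
  Sema-IG; a single Ig otherwise splits by lineage and topology into
  class 2 (secreted, Protostomia) or the vertebrate classes 3/4/7; bare
  Sema+PSI architectures split by lineage into Sema-SP (secreted,
  Echinodermata), class 1 (Protostomia and non-bilaterians, any topology)
  and class 6 (transmembrane Deuterostomia).

Every fired rule is recorded in ``rationale`` so a classification is
auditable after the fact.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .arch import ProteinRecord
from .errors import ClassificationError
from .taxa import DEUTEROSTOMIA, NON_BILATERIA, PROTOSTOMIA

FAMILIES = ("PLEXIN", "SEMAPHORIN", "MET", "MET_LP", "UNCLASSIFIED")
SEMA_CLASSES = (
    "SEMA_FN", "SEMA_IG", "SEMA_SP", "SEMA_SI",
    "SEMA1", "SEMA2", "SEMA3", "SEMA4", "SEMA5", "SEMA6", "SEMA7",
)

#: class token -> protein-name stem used by tree-based naming
CLASS_STEMS = {
    "SEMA_FN": "Sema-FN",
    "SEMA_IG": "Sema-IG",
    "SEMA_SP": "Sema-SP",
    "SEMA_SI": "Sema-SI",
    "SEMA1": "Sema1",
    "SEMA2": "Sema2",
    "SEMA3": "Sema3",
    "SEMA4": "Sema4",
    "SEMA5": "Sema5",
    "SEMA6": "Sema6",
    "SEMA7": "Sema7",
}


@dataclass(frozen=True)
class Classification:
    """Outcome of the decision table for one protein."""

    family: str
    semaphorin_class: str | None = None
    plexin_intracellular: str | None = None
    rationale: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ClassificationError(f"unknown family {self.family!r}")
        if self.semaphorin_class is not None and self.family != "SEMAPHORIN":
            raise ClassificationError("semaphorin_class set on a non-semaphorin")
        if self.plexin_intracellular is not None and self.family != "PLEXIN":
            raise ClassificationError("plexin_intracellular set on a non-plexin")
        if self.family != "UNCLASSIFIED" and not self.rationale:
            raise ClassificationError("classified records need a rationale")

    @property
    def stem(self) -> str:
        """Protein-name stem ('Plexin', 'Met', 'Met-LP', or the class stem)."""
        if self.family == "PLEXIN":
            return "Plexin"
        if self.family == "MET":
            return "Met"
        if self.family == "MET_LP":
            return "Met-LP"
        if self.family == "SEMAPHORIN" and self.semaphorin_class:
            return CLASS_STEMS[self.semaphorin_class]
        return "Unclassified"


def classify_family(record: ProteinRecord) -> Classification:
    """Assign PLEXIN / SEMAPHORIN / MET / MET_LP from the architecture.

    Requires at least one Sema domain (the survey's inclusion criterion).
    Semaphorin records are handed on to :func:`classify_semaphorin` by
    :func:`classify_record`; this function stops at family level.
    """
    arch = record.architecture
    if arch.count("SEMA") < 1:
        raise ClassificationError(
            f"{record.protein_id}: no Sema domain; record is outside the survey"
        )
    n_psi_ecto = arch.count("PSI", "ecto")
    n_ipt_ecto = arch.count("IPT", "ecto")
    has_tyrkin = arch.count("TYRKIN", "endo") > 0
    fired: list[str] = []

    if has_tyrkin and n_psi_ecto >= 2:
        fired.append("endo TYRKIN + >=2 ecto PSI (complete plexin ectodomain) -> MET_LP")
        return Classification(family="MET_LP", rationale=tuple(fired))
    if has_tyrkin and n_psi_ecto == 1 and n_ipt_ecto >= 1:
        fired.append("endo TYRKIN + 1 ecto PSI + >=1 IPT (truncated ectodomain) -> MET")
        return Classification(family="MET", rationale=tuple(fired))
    if has_tyrkin:
        return Classification(
            family="UNCLASSIFIED",
            rationale=("endo TYRKIN without IPT repeats fits no RTK rule",),
        )
    if n_ipt_ecto >= 1:
        fired.append(">=1 ecto IPT, no TYRKIN -> PLEXIN")
        if arch.count("RASGAP", "endo") > 0:
            fired.append("endo RASGAP -> full-length intracellular domain")
            intra = "full"
        else:
            fired.append("no endo RASGAP -> truncated intracellular domain")
            intra = "truncated"
        return Classification(
            family="PLEXIN", plexin_intracellular=intra, rationale=tuple(fired)
        )
    fired.append("no IPT, no TYRKIN -> SEMAPHORIN")
    return Classification(family="SEMAPHORIN", rationale=tuple(fired))


def classify_semaphorin(record: ProteinRecord) -> Classification:
    """Assign the semaphorin class (precondition: family is SEMAPHORIN)."""
    base = classify_family(record)
    if base.family != "SEMAPHORIN":
        raise ClassificationError(
            f"{record.protein_id}: classify_semaphorin needs a semaphorin, got {base.family}"
        )
    arch = record.architecture
    fired = list(base.rationale)
    tested: list[str] = []

    def done(cls: str, why: str) -> Classification:
        fired.append(why)
        return Classification(
            family="SEMAPHORIN", semaphorin_class=cls, rationale=tuple(fired)
        )

    clade, topo = record.clade, record.topology
    has_ig = arch.count("IG", "ecto") > 0

    if arch.count("TSP1", "ecto") >= 1:
        return done("SEMA5", ">=1 TSP1 repeat -> class 5")
    tested.append("TSP1")
    if arch.count("FN3", "ecto") >= 1:
        return done("SEMA_FN", ">=1 FNIII domain -> Sema-FN")
    tested.append("FN3")
    if arch.count("PSI_LIKE", "ecto") >= 1:
        return done("SEMA_SI", "atypical PSI-like domain -> Sema-SI")
    tested.append("PSI_LIKE")
    if arch.has_tandem("IG", 2) and clade == "Ctenophora":
        return done("SEMA_IG", "tandem Ig domains in Ctenophora -> Sema-IG")
    tested.append("tandem IG x Ctenophora")
    if has_ig and topo == "secreted" and clade in PROTOSTOMIA:
        return done("SEMA2", "Ig + secreted + Protostomia -> class 2")
    tested.append("IG x secreted x Protostomia")
    if has_ig and clade == "Vertebrata":
        if topo == "secreted":
            return done("SEMA3", "Ig + secreted + Vertebrata -> class 3")
        if topo == "transmembrane":
            return done("SEMA4", "Ig + transmembrane + Vertebrata -> class 4")
        if topo == "gpi_anchored":
            return done("SEMA7", "Ig + GPI anchor + Vertebrata -> class 7")
    tested.append("IG x Vertebrata")
    if not has_ig:
        if clade == "Echinodermata" and topo == "secreted":
            return done("SEMA_SP", "bare Sema+PSI, secreted, Echinodermata -> Sema-SP")
        tested.append("bare x Echinodermata x secreted")
        if clade in PROTOSTOMIA or clade in NON_BILATERIA:
            return done("SEMA1", "bare Sema+PSI in Protostomia/non-bilateria -> class 1")
        tested.append("bare x Protostomia/non-bilateria")
        if clade in DEUTEROSTOMIA and topo == "transmembrane":
            return done("SEMA6", "bare Sema+PSI, transmembrane, Deuterostomia -> class 6")
        tested.append("bare x Deuterostomia x transmembrane")
    return Classification(
        family="UNCLASSIFIED",
        rationale=tuple(f"tested: {t}" for t in tested) or ("no rule fired",),
    )


def classify_record(record: ProteinRecord) -> Classification:
    """Full classification: family plus, for semaphorins, the class."""
    base = classify_family(record)
    if base.family == "SEMAPHORIN":
        return classify_semaphorin(record)
    return base


def classify_all(records) -> pd.DataFrame:
    """Classify a batch of records into a tidy per-protein table.

    Columns: protein_id, species, clade, family, semaphorin_class,
    plexin_intracellular, rationale. Deterministic and independent of
    record order (rows come back in input order).
    """
    rows = []
    for rec in records:
        c = classify_record(rec)
        rows.append(
            {
                "protein_id": rec.protein_id,
                "species": rec.species,
                "clade": rec.clade,
                "family": c.family,
                "semaphorin_class": c.semaphorin_class,
                "plexin_intracellular": c.plexin_intracellular,
                "rationale": "; ".join(c.rationale),
            }
        )
    columns = [
        "protein_id", "species", "clade", "family",
        "semaphorin_class", "plexin_intracellular", "rationale",
    ]
    return pd.DataFrame(rows, columns=columns)


def summarize_counts(table: pd.DataFrame) -> pd.DataFrame:
    """Per-species family counts (wide), mirroring the survey's captions."""
    if table.empty:
        return pd.DataFrame(columns=list(FAMILIES)).rename_axis("species")
    counts = (
        table.pivot_table(
            index="species", columns="family", aggfunc="size", fill_value=0
        )
        .reindex(columns=list(FAMILIES), fill_value=0)
        .rename_axis("species")
    )
    return counts


def summarize_classes(table: pd.DataFrame) -> pd.DataFrame:
    """Per-species semaphorin class counts (wide)."""
    semas = table[table["family"] == "SEMAPHORIN"]
    if semas.empty:
        return pd.DataFrame(columns=list(SEMA_CLASSES)).rename_axis("species")
    return (
        semas.pivot_table(
            index="species", columns="semaphorin_class", aggfunc="size", fill_value=0
        )
        .reindex(columns=list(SEMA_CLASSES), fill_value=0)
        .rename_axis("species")
    )
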
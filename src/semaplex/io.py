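"""Readers and writers for the package's tabular and sequence formats.

Domain tables are plain UTF-8 TSV with a header row and one row per domain
annotation; rows belonging to the same ``protein_id`` are grouped into one
:class:`~semaplex.arch.ProteinRecord` regardless of row order in the file.
hmmscan ``--domtblout`` output is read with a configurable profile-name
alias table so that Pfam naming drift across releases stays a config edit,
not a code change. Alignments are aligned FASTA via Biopython.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable

import yaml
from Bio import AlignIO

from .arch import ArchitectureString, DomainAnnotation, ProteinRecord, normalize_kind
from .errors import TableFormatError

logger = logging.getLogger(__name__)

DOMAIN_TABLE_COLUMNS = (
    "protein_id", "species", "clade", "topology",
    "domain_kind", "start", "end", "certainty", "truncated",
)

_DATA_DIR = Path(__file__).parent / "data"

#: default hmmscan profile-name -> vocabulary aliases (editable config ships
#: alongside in data/hmm_aliases.yaml; pass a path to override).
DEFAULT_HMM_ALIASES = {
    "Sema": "SEMA",
    "PSI": "PSI",
    "TIG": "IPT",
    "IPT": "IPT",
    "fn3": "FN3",
    "FN3": "FN3",
    "TSP_1": "TSP1",
    "I-set": "IG",
    "Ig_2": "IG",
    "ig": "IG",
    "SEA": "SEA",
    "RasGAP": "RASGAP",
    "Pkinase_Tyr": "TYRKIN",
}


def _parse_bool(text: str) -> bool:
    return text.strip().lower() in ("1", "true", "yes", "y")


def read_domain_table(path) -> list[ProteinRecord]:
    """Read a domain-annotation TSV into protein records.

    One record per distinct ``protein_id``, with domains ordered by start
    coordinate (file row order is used for coordinate-free rows). A file
    with only a header yields an empty list (logged as a warning).
    """
    path = Path(path)
    with path.open(encoding="utf-8") as fh:
        header_line = fh.readline()
        if not header_line:
            raise TableFormatError("empty file (no header)")
        header = header_line.rstrip("\n").split("\t")
        missing = [c for c in DOMAIN_TABLE_COLUMNS if c not in header]
        if missing:
            raise TableFormatError(f"missing mandatory column(s): {', '.join(missing)}")
        idx = {c: header.index(c) for c in DOMAIN_TABLE_COLUMNS}

        # ids may repeat across species (every genome has a "Plexin-1"), so
        # the grouping key is (protein_id, species)
        proteins: dict[tuple[str, str], dict] = {}
        order: list[tuple[str, str]] = []
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < len(header):
                raise TableFormatError("too few fields", line=lineno)
            row = {c: fields[idx[c]] for c in DOMAIN_TABLE_COLUMNS}
            start = end = None
            try:
                if row["start"].strip():
                    start = int(row["start"])
                if row["end"].strip():
                    end = int(row["end"])
            except ValueError:
                raise TableFormatError(
                    f"unparseable coordinate: start={row['start']!r} end={row['end']!r}",
                    line=lineno,
                ) from None
            ann = DomainAnnotation(
                kind=normalize_kind(row["domain_kind"]),
                start=start,
                end=end,
                certainty=row["certainty"].strip() or "high",
                truncated=_parse_bool(row["truncated"]),
            )
            pid = (row["protein_id"], row["species"])
            if pid not in proteins:
                proteins[pid] = {
                    "species": row["species"],
                    "clade": row["clade"],
                    "topology": row["topology"],
                    "record_truncated": False,
                    "domains": [],
                }
                order.append(pid)
            proteins[pid]["domains"].append((start if start is not None else 0, len(proteins[pid]["domains"]), ann))
            proteins[pid]["record_truncated"] |= ann.truncated

    if not proteins:
        logger.warning("domain table %s contains no data rows", path)
        return []

    records = []
    for pid, _species in order:
        meta = proteins[(pid, _species)]
        domains = [a for *_, a in sorted(meta["domains"], key=lambda t: (t[0], t[1]))]
        records.append(
            ProteinRecord(
                protein_id=pid,
                species=meta["species"],
                clade=meta["clade"],
                topology=meta["topology"],
                architecture=ArchitectureString(domains=tuple(domains)),
                truncated=meta["record_truncated"],
            )
        )
    return records


def write_domain_table(records: Iterable[ProteinRecord], path) -> None:
    """Write protein records to a domain-annotation TSV (round-trips with
    :func:`read_domain_table` up to row grouping)."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write("\t".join(DOMAIN_TABLE_COLUMNS) + "\n")
        for rec in records:
            for d in rec.architecture.domains:
                fh.write(
                    "\t".join(
                        (
                            rec.protein_id,
                            rec.species,
                            rec.clade,
                            rec.topology,
                            d.kind,
                            "" if d.start is None else str(d.start),
                            "" if d.end is None else str(d.end),
                            d.certainty,
                            str(d.truncated or rec.truncated),
                        )
                    )
                    + "\n"
                )


def load_hmm_aliases(path=None) -> dict[str, str]:
    """Load the profile-name alias table (YAML mapping), defaulting to the
    packaged config."""
    if path is None:
        path = _DATA_DIR / "hmm_aliases.yaml"
    with open(path, encoding="utf-8") as fh:
        aliases = yaml.safe_load(fh)
    if not isinstance(aliases, dict):
        raise TableFormatError(f"alias config {path} is not a mapping")
    return {str(k): str(v) for k, v in aliases.items()}


def read_hmmscan_domtbl(path, aliases: dict[str, str] | None = None) -> dict[str, list[DomainAnnotation]]:
    """Parse hmmscan per-domain tabular output (``--domtblout``).

    Returns ``{query_id: [DomainAnnotation, ...]}`` using alignment ("ali")
    coordinates, columns 18-19 of the 23-column dialect. Profiles missing
    from the alias table become UNKNOWN annotations that keep the original
    profile name in ``source_name``.
    """
    if aliases is None:
        aliases = load_hmm_aliases()
    result: dict[str, list[DomainAnnotation]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 23:
                raise TableFormatError(
                    f"expected >=23 whitespace-separated fields, got {len(fields)}",
                    line=lineno,
                )
            target, query = fields[0], fields[3]
            try:
                ali_from, ali_to = int(fields[17]), int(fields[18])
            except ValueError:
                raise TableFormatError("unparseable ali coords", line=lineno) from None
            kind = aliases.get(target)
            ann = DomainAnnotation(
                kind=kind or "UNKNOWN",
                start=ali_from,
                end=ali_to,
                source_name=None if kind else target,
            )
            result.setdefault(query, []).append(ann)
    for anns in result.values():
        anns.sort(key=lambda a: a.start)
    return result


def read_alignment(path):
    """Read an aligned FASTA file into a Biopython MultipleSeqAlignment."""
    return AlignIO.read(str(path), "fasta")
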
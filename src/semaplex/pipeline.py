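"""End-to-end pipeline: classify -> name -> reconcile -> conserve.

``run_pipeline`` drives the four analysis stages from a single config,
writes one TSV per stage plus a per-species summary table, and records a
manifest marking which stages ran, were skipped (no input), or failed.
Outputs are byte-reproducible for a fixed config and seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from . import classify as _classify
from .conservation import Alignment, load_matrix, windowed_similarity
from .errors import NamingError, ParameterError, SemaplexError
from .io import read_domain_table
from .naming import assign_names
from .reconcile import assign_ancestral_genes
from .trees import SpeciesTree, default_species_tree, read_gene_tree

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Inputs and knobs for one pipeline run."""

    domains: Path | None = None  # domain-annotation TSV
    gene_trees: list[Path] = field(default_factory=list)  # Newick files
    alignments: list[Path] = field(default_factory=list)  # aligned FASTA
    species_tree: Path | None = None  # override packaged topology
    swap_porifera_ctenophora: bool = False
    window: int = 50
    matrix: str = "BLOSUM62"
    delimiter: str = "_"
    out_dir: Path = Path("semaplex_out")
    seed: int = 0

    def __post_init__(self):
        if self.window < 1:
            raise ParameterError(f"window must be >= 1, got {self.window}")

    def resolve_species_tree(self) -> SpeciesTree:
        if self.species_tree is not None:
            return SpeciesTree.from_newick(Path(self.species_tree))
        return default_species_tree(self.swap_porifera_ctenophora)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all configured stages; returns the manifest dict.

    Raises :class:`SemaplexError` after writing the manifest if any stage
    failed (partial outputs are retained).
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"stages": {}, "seed": config.seed}
    sp = config.resolve_species_tree()
    failures: list[str] = []
    classifications = None

    def stage(name: str, fn, enabled: bool) -> None:
        nonlocal failures
        if not enabled:
            manifest["stages"][name] = {"status": "skipped"}
            return
        try:
            outputs = fn()
            manifest["stages"][name] = {"status": "ok", "outputs": outputs}
        except Exception as exc:
            logger.exception("stage %s failed", name)
            manifest["stages"][name] = {"status": "failed", "error": str(exc)}
            failures.append(name)

    def do_classify() -> list[str]:
        nonlocal classifications
        records = read_domain_table(config.domains)
        table = _classify.classify_all(records)
        classifications = {
            (r.species, r.protein_id): _classify.classify_record(r) for r in records
        }
        table.to_csv(out / "classification.tsv", sep="\t", index=False)
        _classify.summarize_counts(table).to_csv(out / "summary_counts.tsv", sep="\t")
        _classify.summarize_classes(table).to_csv(out / "summary_classes.tsv", sep="\t")
        for _, row in table.iterrows():
            logger.info("classified %s/%s: %s", row.species, row.protein_id, row.rationale)
        return ["classification.tsv", "summary_counts.tsv", "summary_classes.tsv"]

    def do_trees() -> list[str]:
        outputs = []
        for i, path in enumerate(config.gene_trees, start=1):
            tree = read_gene_tree(Path(path), delimiter=config.delimiter, species_tree=sp)
            labeling = assign_ancestral_genes(tree, sp)
            tag = f"tree{i}"
            with open(out / f"{tag}_labeling.tsv", "w", encoding="utf-8") as fh:
                fh.write("species\tprotein_id\tgene_number\n")
                for (species, pid), gene in sorted(labeling.leaf_gene.items()):
                    fh.write(f"{species}\t{pid}\t{gene}\n")
            with open(out / f"{tag}_events.tsv", "w", encoding="utf-8") as fh:
                fh.write("new_gene\tparent_gene\tspecies_branch\tclade\n")
                for ev in labeling.events:
                    logger.info(
                        "duplication: gene %d -> gene %d on %s",
                        ev.parent_gene, ev.new_gene, ev.species_branch.label,
                    )
                    fh.write(
                        f"{ev.new_gene}\t{ev.parent_gene}\t"
                        f"{ev.species_branch.label}\t{ev.species_branch.clade}\n"
                    )
            outputs += [f"{tag}_labeling.tsv", f"{tag}_events.tsv"]
            if classifications is not None:
                try:
                    names = assign_names(tree, classifications)
                except NamingError as exc:
                    # naming needs every tree leaf in the classified set;
                    # trees over other identifiers still get reconciled
                    logger.warning("skipping names for %s: %s", path, exc)
                else:
                    with open(out / f"{tag}_names.tsv", "w", encoding="utf-8") as fh:
                        fh.write("species\tprotein_id\tname\n")
                        for (species, pid), name in sorted(names.items()):
                            fh.write(f"{species}\t{pid}\t{name}\n")
                    outputs.append(f"{tag}_names.tsv")
        return outputs

    def do_conserve() -> list[str]:
        matrix = load_matrix(config.matrix)
        outputs = []
        for i, path in enumerate(config.alignments, start=1):
            aln = Alignment.from_fasta(Path(path))
            profile = windowed_similarity(
                aln, window=config.window, matrix=matrix, matrix_id=str(config.matrix)
            )
            name = f"alignment{i}_profile.tsv"
            profile.to_tsv(out / name)
            outputs.append(name)
        return outputs

    stage("classify", do_classify, config.domains is not None)
    stage("reconcile", do_trees, bool(config.gene_trees))
    stage("conserve", do_conserve, bool(config.alignments))

    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    if failures:
        raise SemaplexError(f"pipeline stage(s) failed: {', '.join(failures)}")
    return manifest
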
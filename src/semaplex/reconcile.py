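"""Minimal ancestral-gene labeling of a gene tree on a species tree.

The procedure mirrors how a curator reads a published gene-family tree:

* a gene-tree node implies a duplication only when at least two of its
  child subtrees contain copies from the same species — a *soft polytomy*
  by itself forces nothing;
* the lineage at the root is ancestral "gene 1" and is carried toward the
  tips until a duplication is met;
* at a duplication node exactly one child subtree keeps the parent's gene
  number — the one whose species span reaches the most basal species-tree
  divergence (ties broken by child input order). Every other child whose
  species overlap forced the duplication is the start of a new ancestral
  gene and receives the next unused number; children uninvolved in any
  overlap simply inherit the parent gene;
* copies of a single species that form a monophyletic clade share one gene
  number: duplication nodes whose subtree is all one species mint nothing
  (those are within-species expansions, e.g. a five-copy "-A1..-A5" array);
* each minted gene is placed on the species tree at the stem of the
  smallest clade containing every species that carries it (a single-species
  gene maps to that species' terminal stem).

Gene numbers form 1..n with no gaps and ``n = 1 + number of events``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import dendropy

from .trees import GeneTree, SpeciesTree, default_species_tree

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SpeciesBranch:
    """A species-tree branch: the stem above the named node."""

    label: str
    clade: str

    def __str__(self) -> str:
        return self.label


@dataclass(frozen=True)
class DuplicationEvent:
    parent_gene: int
    new_gene: int
    species_branch: SpeciesBranch
    species: frozenset[str]
    gene_tree_node: object = None  # dendropy node where the event was read


@dataclass(frozen=True)
class AncestralGeneLabeling:
    """Per-leaf gene numbers plus the duplication events explaining them."""

    leaf_gene: dict  # (species, protein_id) -> gene number
    events: tuple[DuplicationEvent, ...]

    @property
    def n_genes(self) -> int:
        return 1 + len(self.events)

    def genes_of_species(self, acronym: str) -> list[int]:
        return sorted(g for (sp, _), g in self.leaf_gene.items() if sp == acronym)


def _species_sets(root: dendropy.Node) -> dict[int, frozenset[str]]:
    """Species set of every subtree, by node id (postorder fill)."""
    out: dict[int, frozenset[str]] = {}
    for node in root.postorder_iter():
        if node.is_leaf():
            out[id(node)] = frozenset({node.species})
        else:
            acc: set[str] = set()
            for child in node.child_nodes():
                acc |= out[id(child)]
            out[id(node)] = frozenset(acc)
    return out


def find_duplication_nodes(tree: GeneTree) -> set[dendropy.Node]:
    """Internal nodes where >=2 child subtrees share at least one species.

    This is the conservative, soft-polytomy-safe criterion: discordance
    between gene-tree and species-tree topology alone never creates a
    duplication here, only same-species co-occurrence across children does.
    """
    sets = _species_sets(tree.root)
    dups: set[dendropy.Node] = set()
    for node in tree.tree.preorder_internal_node_iter():
        seen: set[str] = set()
        for child in node.child_nodes():
            child_set = sets[id(child)]
            if seen & child_set:
                dups.add(node)
                break
            seen |= child_set
    return dups


def place_gene(species: frozenset[str], sp: SpeciesTree) -> SpeciesBranch:
    """Species-tree stem branch of the smallest clade holding ``species``."""
    from .errors import UnknownSpeciesError
    from .taxa import clade_of

    node = sp.lca(species)
    if node is sp.root and species != sp.species:
        logger.warning(
            "gene spans %s with no common species-tree clade below the root; "
            "placing on the root stem", sorted(species),
        )
    label = sp.label(node)
    clade = label
    if node.is_leaf():
        try:
            clade = clade_of(label)
        except UnknownSpeciesError:
            pass
    return SpeciesBranch(label=label, clade=clade)


def place_event(event_node: dendropy.Node, new_gene_species: frozenset[str],
                sp: SpeciesTree) -> SpeciesBranch:
    """Placement of a duplication event read at ``event_node``: the stem of
    the smallest species-tree clade containing the new gene's species."""
    return place_gene(frozenset(new_gene_species), sp)


def assign_ancestral_genes(tree: GeneTree, sp: SpeciesTree | None = None) -> AncestralGeneLabeling:
    """Greedy pre-order ancestral-gene labeling (see module docstring)."""
    if sp is None:
        sp = default_species_tree()
    sets = _species_sets(tree.root)
    leaf_gene: dict[tuple[str, str], int] = {}
    events: list[DuplicationEvent] = []
    counter = [1]

    def assign_subtree(node: dendropy.Node, gene: int) -> None:
        for leaf in ([node] if node.is_leaf() else node.leaf_iter()):
            leaf_gene[(leaf.species, leaf.protein_id)] = gene

    def is_duplication(node: dendropy.Node) -> bool:
        seen: set[str] = set()
        for child in node.child_nodes():
            if seen & sets[id(child)]:
                return True
            seen |= sets[id(child)]
        return False

    def visit(node: dendropy.Node, gene: int) -> None:
        if node.is_leaf():
            leaf_gene[(node.species, node.protein_id)] = gene
            return
        if len(sets[id(node)]) == 1:
            # within-species monophyletic expansion: one gene for the clade
            assign_subtree(node, gene)
            return
        children = node.child_nodes()
        if not is_duplication(node):
            for child in children:
                visit(child, gene)
            return
        # children involved in a same-species overlap
        child_sets = [sets[id(c)] for c in children]
        involved = []
        for i, cs in enumerate(child_sets):
            others = set().union(*(s for j, s in enumerate(child_sets) if j != i))
            if cs & others:
                involved.append(i)
        # keeper: most basal species-tree span, then input order
        keeper = min(involved, key=lambda i: (sp.lca_depth(child_sets[i]), i))
        plan: list[tuple[dendropy.Node, int]] = []
        for i, child in enumerate(children):
            if i in involved and i != keeper:
                counter[0] += 1
                new_gene = counter[0]
                events.append(
                    DuplicationEvent(
                        parent_gene=gene,
                        new_gene=new_gene,
                        species_branch=place_gene(child_sets[i], sp),
                        species=child_sets[i],
                        gene_tree_node=node,
                    )
                )
                plan.append((child, new_gene))
            else:
                plan.append((child, gene))
        for child, g in plan:
            visit(child, g)

    visit(tree.root, 1)
    return AncestralGeneLabeling(leaf_gene=leaf_gene, events=tuple(events))
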
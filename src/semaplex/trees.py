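"""Rooted species and gene trees.

Both are thin wrappers around :mod:`dendropy` trees. Gene trees may contain
polytomies (kept as-is, never arbitrarily resolved) and carry optional
posterior-probability support on internal nodes; leaves encode
``(species acronym, protein id)`` through a configurable label delimiter.

The packaged species-tree topology follows the widely accepted backbone
for the fourteen study taxa, with Porifera branching before Ctenophora by
default; because that ordering is debated, a flag swaps the two lineages.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable

import dendropy

from .errors import TreeError, UnknownSpeciesError
from .taxa import SPECIES, clade_of

_DATA_DIR = Path(__file__).parent / "data"
SPECIES_TREE_NWK = _DATA_DIR / "species_tree.nwk"

DEFAULT_DELIMITER = "_"


def _read_newick(source: str | Path) -> dendropy.Tree:
    try:
        if isinstance(source, Path) or (isinstance(source, str) and "\n" not in source and not source.rstrip().endswith(";") ):
            tree = dendropy.Tree.get(
                path=str(source), schema="newick",
                preserve_underscores=True, rooting="force-rooted",
            )
        else:
            tree = dendropy.Tree.get(
                data=str(source), schema="newick",
                preserve_underscores=True, rooting="force-rooted",
            )
    except Exception as exc:  # dendropy raises several parse error types
        raise TreeError(f"could not parse Newick from {source!r}: {exc}") from exc
    return tree


class SpeciesTree:
    """Rooted reference topology over species acronyms.

    Internal nodes carry clade labels from the packaged Newick; terminal
    branches are identified by their species acronym. Depth is counted in
    edges from the root (root = 0).
    """

    def __init__(self, tree: dendropy.Tree):
        self._tree = tree
        self._leaf: dict[str, dendropy.Node] = {}
        for leaf in tree.leaf_node_iter():
            label = leaf.taxon.label if leaf.taxon else leaf.label
            if label in self._leaf:
                raise TreeError(f"duplicate species acronym in species tree: {label}")
            self._leaf[label] = leaf
        self._depth: dict[int, int] = {}
        for node in tree.preorder_node_iter():
            self._depth[id(node)] = 0 if node.parent_node is None else self._depth[id(node.parent_node)] + 1

    @classmethod
    def default(cls, swap_porifera_ctenophora: bool = False) -> "SpeciesTree":
        """The packaged reference topology (optionally with the Porifera /
        Ctenophora branching order exchanged)."""
        tree = _read_newick(SPECIES_TREE_NWK)
        sp = cls(tree)
        if swap_porifera_ctenophora:
            a, m = sp._leaf["Aquee"], sp._leaf["Mleid"]
            a.taxon, m.taxon = m.taxon, a.taxon
            sp = cls(tree)
        return sp

    @classmethod
    def from_newick(cls, source: str | Path) -> "SpeciesTree":
        return cls(_read_newick(source))

    @property
    def species(self) -> frozenset[str]:
        return frozenset(self._leaf)

    @property
    def root(self) -> dendropy.Node:
        return self._tree.seed_node

    def __contains__(self, acronym: str) -> bool:
        return acronym in self._leaf

    def leaf(self, acronym: str) -> dendropy.Node:
        try:
            return self._leaf[acronym]
        except KeyError:
            raise UnknownSpeciesError(f"species {acronym!r} not in species tree") from None

    def depth(self, node: dendropy.Node) -> int:
        return self._depth[id(node)]

    def label(self, node: dendropy.Node) -> str:
        """Branch/node identifier: acronym for leaves, clade label otherwise."""
        if node.is_leaf():
            return node.taxon.label if node.taxon else node.label
        if node.label:
            return node.label
        leaves = sorted(self.label(l) for l in node.leaf_iter())
        return "+".join(leaves)

    def lca(self, acronyms: Iterable[str]) -> dendropy.Node:
        """Most recent common ancestor of a non-empty set of species."""
        acronyms = list(acronyms)
        if not acronyms:
            raise TreeError("lca of an empty species set")
        nodes = [self.leaf(a) for a in set(acronyms)]
        lca = nodes[0]
        for node in nodes[1:]:
            ancestors = []
            cursor = lca
            while cursor is not None:
                ancestors.append(cursor)
                cursor = cursor.parent_node
            ids = {id(n) for n in ancestors}
            cursor = node
            while cursor is not None and id(cursor) not in ids:
                cursor = cursor.parent_node
            if cursor is None:  # pragma: no cover - single-rooted tree
                raise TreeError("species share no ancestor")
            lca = cursor
        return lca

    def lca_depth(self, acronyms: Iterable[str]) -> int:
        return self.depth(self.lca(acronyms))

    def as_newick(self) -> str:
        return self._tree.as_string(schema="newick", suppress_rooting=True).strip()


def default_species_tree(swap_porifera_ctenophora: bool = False) -> SpeciesTree:
    return SpeciesTree.default(swap_porifera_ctenophora=swap_porifera_ctenophora)


class GeneTree:
    """Rooted, polytomy-tolerant gene tree with species-tagged leaves.

    Each leaf node gains ``species`` and ``protein_id`` attributes; internal
    nodes gain ``support`` (float or None) parsed from their Newick label.
    """

    def __init__(self, tree: dendropy.Tree, delimiter: str = DEFAULT_DELIMITER,
                 species_tree: SpeciesTree | None = None):
        self._tree = tree
        self.delimiter = delimiter
        known = species_tree.species if species_tree is not None else frozenset(SPECIES)
        for leaf in tree.leaf_node_iter():
            label = leaf.taxon.label if leaf.taxon else leaf.label
            if label is None or delimiter not in label:
                raise TreeError(
                    f"leaf label {label!r} lacks the {delimiter!r} species delimiter"
                )
            species, protein_id = label.split(delimiter, 1)
            if species not in known:
                raise TreeError(f"leaf {label!r}: species {species!r} not in species tree")
            leaf.species = species
            leaf.protein_id = protein_id
        for node in tree.preorder_internal_node_iter():
            support = None
            if node.label:
                try:
                    support = float(node.label)
                except ValueError:
                    support = None
            node.support = support

    @property
    def tree(self) -> dendropy.Tree:
        return self._tree

    @property
    def root(self) -> dendropy.Node:
        return self._tree.seed_node

    def leaves(self) -> list[dendropy.Node]:
        return list(self._tree.leaf_node_iter())

    def leaf_ids(self) -> list[tuple[str, str]]:
        return [(l.species, l.protein_id) for l in self.leaves()]

    def __len__(self) -> int:
        return sum(1 for _ in self._tree.leaf_node_iter())

    def as_newick(self) -> str:
        return self._tree.as_string(schema="newick", suppress_rooting=True).strip()


def read_gene_tree(source: str | Path, delimiter: str = DEFAULT_DELIMITER,
                   species_tree: SpeciesTree | None = None) -> GeneTree:
    """Parse a rooted Newick gene tree (file path or Newick string).

    Polytomies are preserved; internal-node labels that parse as floats
    become support values. Leaf labels must be
    ``<acronym><delimiter><protein_id>`` with a known species acronym.
    """
    return GeneTree(_read_newick(source), delimiter=delimiter, species_tree=species_tree)
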
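"""Tree-guided protein naming.

Within each species and family (or semaphorin class), the most basally
branching copy gets suffix 1, the next 2, and so on; copies that form a
within-species monophyletic clade (i.e. duplicated inside that species)
share a letter and are numbered A1..Ak in clade pre-order (the next clade
takes B, etc.). Numbered semaphorin classes (Sema1..Sema7) conventionally
use plain letter suffixes instead (Sema1A, Sema1B, ...), so for those stems
every copy gets the next letter in basal order.

"More basal" is operationalized as smaller leaf depth (edges from the gene
tree root), with pre-order position breaking ties — a deterministic proxy
for reading a published tree from base to tips.
"""

from __future__ import annotations

import re
import string

import dendropy

from .classify import Classification
from .errors import NamingError
from .trees import GeneTree

_LETTER_STYLE = re.compile(r"^Sema[1-7]$")


def _letters(i: int) -> str:
    """0 -> A, 1 -> B, ... 26 -> AA (excel-style, just in case)."""
    out = ""
    i += 1
    while i:
        i, rem = divmod(i - 1, 26)
        out = string.ascii_uppercase[rem] + out
    return out


def assign_names(tree: GeneTree, classifications: dict) -> dict[tuple[str, str], str]:
    """Name every leaf of ``tree``.

    ``classifications`` maps ``(species, protein_id)`` to a
    :class:`~semaplex.classify.Classification`; every leaf must be covered
    and classified (raises :class:`NamingError` otherwise). Returns
    ``(species, protein_id) -> name``.
    """
    depth: dict[int, int] = {}
    preorder: dict[int, int] = {}
    for i, node in enumerate(tree.tree.preorder_node_iter()):
        preorder[id(node)] = i
        depth[id(node)] = 0 if node.parent_node is None else depth[id(node.parent_node)] + 1

    leaves = tree.leaves()
    stems: dict[tuple[str, str], str] = {}
    for leaf in leaves:
        key = (leaf.species, leaf.protein_id)
        cls = classifications.get(key)
        if cls is None:
            raise NamingError(f"leaf {key} has no classification")
        if isinstance(cls, Classification):
            if cls.family == "UNCLASSIFIED":
                raise NamingError(f"leaf {key} is unclassified")
            stems[key] = cls.stem
        else:
            stems[key] = str(cls)

    def leaf_stem(leaf: dendropy.Node) -> str:
        return stems[(leaf.species, leaf.protein_id)]

    # maximal within-species, same-stem monophyletic clades (>= 2 leaves)
    homogeneous: dict[int, tuple[str, str] | None] = {}
    for node in tree.tree.postorder_node_iter():
        if node.is_leaf():
            homogeneous[id(node)] = (node.species, leaf_stem(node))
        else:
            tags = {homogeneous[id(c)] for c in node.child_nodes()}
            homogeneous[id(node)] = tags.pop() if len(tags) == 1 and None not in tags else None

    clade_roots: list[dendropy.Node] = []
    in_clade: set[int] = set()
    for node in tree.tree.preorder_internal_node_iter():
        if homogeneous[id(node)] is not None and id(node) not in in_clade:
            clade_roots.append(node)
            for sub in node.preorder_iter():
                in_clade.add(id(sub))

    names: dict[tuple[str, str], str] = {}
    # group leaves / clades per (species, stem)
    groups: dict[tuple[str, str], dict] = {}

    def group(species: str, stem: str) -> dict:
        return groups.setdefault((species, stem), {"singles": [], "clades": []})

    for leaf in leaves:
        if id(leaf) not in in_clade:
            group(leaf.species, leaf_stem(leaf))["singles"].append(leaf)
    for root in clade_roots:
        species, stem = homogeneous[id(root)]
        group(species, stem)["clades"].append(root)

    for (species, stem), parts in groups.items():
        basal = lambda n: (depth[id(n)], preorder[id(n)])  # noqa: E731
        items = sorted(
            [("single", n) for n in parts["singles"]]
            + [("clade", n) for n in parts["clades"]],
            key=lambda t: basal(t[1]),
        )
        sep = "-" if "-" not in stem and not _LETTER_STYLE.match(stem) else ""
        if _LETTER_STYLE.match(stem):
            # flat letter suffixes in basal order, clades expanded pre-order
            i = 0
            for kind, node in items:
                members = [node] if kind == "single" else sorted(
                    node.leaf_iter(), key=lambda l: preorder[id(l)]
                )
                for leaf in members:
                    names[(leaf.species, leaf.protein_id)] = f"{stem}{_letters(i)}"
                    i += 1
        else:
            num = 0
            letter = 0
            for kind, node in items:
                if kind == "single":
                    num += 1
                    names[(node.species, node.protein_id)] = f"{stem}{sep}{num}"
                else:
                    tag = _letters(letter)
                    letter += 1
                    for k, leaf in enumerate(
                        sorted(node.leaf_iter(), key=lambda l: preorder[id(l)]), start=1
                    ):
                        names[(leaf.species, leaf.protein_id)] = f"{stem}{sep}{tag}{k}"

    return names
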
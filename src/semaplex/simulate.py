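"""Synthetic data with known ground truth for every pipeline stage.

``simulate_gene_family`` evolves one ancestral gene down the species tree:
the number of duplication events on each species-tree branch (including
the root stem) is Poisson with mean ``dup_rate``, and each event splits one
gene lineage (chosen uniformly among those crossing the branch) into the
continuing parent copy and a new copy inherited by all descendant species.
No losses are simulated. Ground truth follows the curator convention used
by the analysis: an event on an internal branch (or the root stem) founds a
new ancestral gene and is recorded in ``true_events``; an event on a
terminal branch only expands a within-species clade, whose copies share
their parent's gene number (recorded separately), so
``true n_genes = 1 + len(true_events)`` always.

``simulate_architecture`` emits a domain architecture satisfying a given
family/class definition, with stalk-domain counts drawn from the ranges the
survey reports (5-7 FNIII for Sema-FN, 5-7 TSP1 for class 5).

``simulate_alignment`` draws alignment columns with a controlled
per-column conservation level: each row matches the column consensus with
probability ``level`` and is an independent uniform residue otherwise.

All generators are deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .arch import ProteinRecord, parse_architecture
from .conservation import Alignment
from .errors import ParameterError, VocabularyError
from .trees import GeneTree, SpeciesTree, default_species_tree, read_gene_tree

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class SimulatedFamily:
    """A simulated gene family and its ground truth."""

    gene_tree: GeneTree
    true_events: tuple[tuple[str, int], ...]  # (species-tree branch label, new gene)
    within_species_events: tuple[tuple[str, int], ...]  # (branch label, parent gene)
    true_labeling: dict  # (species, protein_id) -> gene number
    seed: int

    @property
    def n_genes(self) -> int:
        return 1 + len(self.true_events)

    @property
    def n_events_total(self) -> int:
        return len(self.true_events) + len(self.within_species_events)


class _Slot:
    """A position in the growing gene tree waiting for a subtree."""

    __slots__ = ("gene", "container", "index")

    def __init__(self, gene: int, container: list, index: int):
        self.gene = gene
        self.container = container
        self.index = index

    def fill(self, value) -> None:
        self.container[self.index] = value


def _to_newick(node) -> str:
    if isinstance(node, str):
        return node
    return "(" + ",".join(_to_newick(c) for c in node) + ")"


def simulate_gene_family(sp: SpeciesTree | None = None, dup_rate: float = 0.3,
                         seed: int = 0) -> SimulatedFamily:
    """Simulate one loss-free gene family on the species tree."""
    if dup_rate < 0:
        raise ParameterError(f"dup_rate must be >= 0, got {dup_rate}")
    if sp is None:
        sp = default_species_tree()
    rng = np.random.default_rng(seed)

    counter = [1]
    true_events: list[tuple[str, int]] = []
    within_events: list[tuple[str, int]] = []
    labeling: dict[tuple[str, str], int] = {}
    copy_index: dict[str, int] = {}

    def process(sp_node, entering: list[_Slot]) -> None:
        branch = sp.label(sp_node)
        terminal = sp_node.is_leaf()
        active = list(entering)
        n_events = rng.poisson(dup_rate)
        for _ in range(n_events):
            i = int(rng.integers(len(active)))
            lin = active[i]
            pair: list = [None, None]
            lin.fill(pair)
            keep = _Slot(lin.gene, pair, 0)
            if terminal:
                new_gene = lin.gene  # within-species copy, no new ancestral gene
                within_events.append((branch, lin.gene))
            else:
                counter[0] += 1
                new_gene = counter[0]
                true_events.append((branch, new_gene))
            new = _Slot(new_gene, pair, 1)
            active[i] = keep
            active.append(new)
        if terminal:
            for lin in active:
                copy_index[branch] = copy_index.get(branch, 0) + 1
                pid = f"P{copy_index[branch]}"
                labeling[(branch, pid)] = lin.gene
                lin.fill(f"{branch}_{pid}")
        else:
            children = sp_node.child_nodes()
            per_child: list[list[_Slot]] = [[] for _ in children]
            for lin in active:
                spec: list = [None] * len(children)
                lin.fill(spec)
                for k in range(len(children)):
                    per_child[k].append(_Slot(lin.gene, spec, k))
            for child, slots in zip(children, per_child):
                process(child, slots)

    holder: list = [None]
    process(sp.root, [_Slot(1, holder, 0)])
    newick = _to_newick(holder[0]) + ";"
    gene_tree = read_gene_tree(newick, species_tree=sp)
    return SimulatedFamily(
        gene_tree=gene_tree,
        true_events=tuple(true_events),
        within_species_events=tuple(within_events),
        true_labeling=labeling,
        seed=seed,
    )


# representative species per simulated class (clade constraints matter for
# the lineage-conditional semaphorin rules)
_CLASS_SPECIES = {
    "PLEXIN": "Mbrev",
    "MET": "Ctele",
    "MET_LP": "Ctele",
    "SEMA_FN": "Mbrev",
    "SEMA_IG": "Mleid",
    "SEMA_SP": "Aplan",
    "SEMA_SI": "Aplan",
    "SEMA1": "Ctele",
    "SEMA2": "Ctele",
    "SEMA3": "Hsapi",
    "SEMA4": "Hsapi",
    "SEMA5": "Tadha",
    "SEMA6": "Bbelc",
    "SEMA7": "Hsapi",
}

SIMULATABLE_CLASSES = tuple(_CLASS_SPECIES)


def simulate_architecture(class_token: str, seed: int = 0) -> ProteinRecord:
    """Emit a protein record whose architecture satisfies ``class_token``.

    ``class_token`` is a family (PLEXIN, MET, MET_LP) or a semaphorin class
    token; the emitted record round-trips through the classifier.
    """
    if class_token not in _CLASS_SPECIES:
        raise VocabularyError(f"unknown class token: {class_token!r}")
    rng = np.random.default_rng(seed)
    species = _CLASS_SPECIES[class_token]
    topology = "transmembrane"
    if class_token == "PLEXIN":
        arch = "SEMA-PSI-IPT-PSI-IPT-PSI-IPT-IPT-IPT-IPT-TM-RASGAP"
    elif class_token == "MET":
        arch = "SEMA-PSI-IPT-IPT-IPT-IPT-TM-TYRKIN"
    elif class_token == "MET_LP":
        arch = "SEMA-PSI-IPT-PSI-IPT-PSI-IPT-IPT-IPT-IPT-TM-TYRKIN"
    elif class_token == "SEMA_FN":
        n = int(rng.integers(5, 8))
        arch = "SEMA-PSI-" + "-".join(["FN3"] * n) + "-SEA-TM"
    elif class_token == "SEMA5":
        n = int(rng.integers(5, 8))
        arch = "SEMA-PSI-" + "-".join(["TSP1"] * n) + "-TM"
    elif class_token == "SEMA_IG":
        arch = "SEMA-PSI-IG-IG-TM"
    elif class_token == "SEMA_SP":
        arch, topology = "SEMA-PSI", "secreted"
    elif class_token == "SEMA_SI":
        arch, topology = "SEMA-PSI_LIKE-IG", "secreted"
    elif class_token == "SEMA1":
        arch = "SEMA-PSI-TM"
    elif class_token == "SEMA2":
        arch, topology = "SEMA-PSI-IG", "secreted"
    elif class_token == "SEMA3":
        arch, topology = "SEMA-PSI-IG", "secreted"
    elif class_token == "SEMA4":
        arch = "SEMA-PSI-IG-TM"
    elif class_token == "SEMA6":
        arch = "SEMA-PSI-TM"
    else:  # SEMA7
        arch, topology = "SEMA-PSI-IG", "gpi_anchored"
    from .taxa import clade_of

    return ProteinRecord(
        protein_id=f"sim_{class_token}_{seed}",
        species=species,
        clade=clade_of(species),
        topology=topology,
        architecture=parse_architecture(arch),
    )


def simulate_alignment(levels, n_rows: int = 4, seed: int = 0) -> Alignment:
    """Alignment with a controlled per-column conservation profile.

    ``levels`` is a sequence of per-column probabilities in [0, 1]: each
    row carries the column's consensus residue with that probability and an
    independent uniform residue otherwise (level 1.0 makes the column
    identical across rows).
    """
    levels = list(levels)
    if n_rows < 2:
        raise ParameterError(f"n_rows must be >= 2, got {n_rows}")
    if any(not (0.0 <= l <= 1.0) for l in levels):
        raise ParameterError("conservation levels must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    aa = np.array(list(AMINO_ACIDS))
    cols = []
    for level in levels:
        consensus = rng.choice(aa)
        residues = np.where(
            rng.random(n_rows) < level, consensus, rng.choice(aa, size=n_rows)
        )
        cols.append(residues)
    matrix = np.array(cols).T  # rows x columns
    rows = tuple("".join(r) for r in matrix)
    ids = tuple(f"seq{i + 1}" for i in range(n_rows))
    return Alignment(ids=ids, rows=rows)
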
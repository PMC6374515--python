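"""Duplication inference tests, including an independent brute-force
LCA-reconciliation oracle.

The oracle maps every gene-tree node to the species-tree LCA of its leaf
species; a node is an LCA-duplication iff its mapping equals that of one
of its children. On gene trees generated by duplication histories on the
species tree this coincides exactly with the same-species-overlap
criterion; on arbitrary (discordant) topologies the overlap criterion is a
subset — LCA reconciliation additionally charges duplications for
topological conflict, which the curator-style reading deliberately does
not.
"""

import random

from semaplex.reconcile import (
    assign_ancestral_genes,
    find_duplication_nodes,
    place_gene,
)
from semaplex.simulate import simulate_gene_family
from semaplex.trees import SpeciesTree, read_gene_tree

# ---------------------------------------------------------------- oracle


def lca_duplication_nodes(gene_tree, sp):
    """Brute-force LCA-mapping duplications (independent of the package's
    overlap-based detector)."""
    mapping = {}
    for node in gene_tree.root.postorder_iter():
        if node.is_leaf():
            mapping[id(node)] = sp.lca([node.species])
        else:
            species = {l.species for l in node.leaf_iter()}
            mapping[id(node)] = sp.lca(species)
    dups = set()
    for node in gene_tree.tree.preorder_internal_node_iter():
        if any(mapping[id(c)] is mapping[id(node)] for c in node.child_nodes()):
            dups.add(node)
    return dups


def random_binary_gene_tree(rng, species_pool, n_leaves):
    """Arbitrary random binary topology with species drawn with replacement."""
    leaves = [
        f"{rng.choice(species_pool)}_L{i}" for i in range(n_leaves)
    ]
    nodes = list(leaves)
    while len(nodes) > 1:
        i = rng.randrange(len(nodes))
        a = nodes.pop(i)
        j = rng.randrange(len(nodes))
        b = nodes.pop(j)
        nodes.append(f"({a},{b})")
    return nodes[0] + ";"


SMALL_SP = "((Mbrev,Aquee)AB,(Tadha,Hsapi)CD)Root;"


# ---------------------------------------------------------------- tests


class TestFindDuplicationNodes:
    def test_cherry_of_two_species_is_speciation(self, species_tree):
        tree = read_gene_tree("(Aquee_x,Mleid_y);", species_tree=species_tree)
        assert find_duplication_nodes(tree) == set()

    def test_same_species_across_children_forces_duplication(self, species_tree, toy_newick):
        tree = read_gene_tree(toy_newick, species_tree=species_tree)
        dups = find_duplication_nodes(tree)
        # the inter-species polytomy AND the five-copy within-species
        # expansion are both duplication nodes under the overlap criterion
        assert len(dups) == 2
        assert any(len(node.child_nodes()) == 3 for node in dups)
        assert any(
            {l.species for l in node.leaf_iter()} == {"Aquee"} for node in dups
        )

    def test_soft_polytomy_alone_forces_nothing(self, species_tree):
        tree = read_gene_tree(
            "(Aquee_a,Mleid_b,Tadha_c,Nvect_d);", species_tree=species_tree
        )
        assert find_duplication_nodes(tree) == set()

    def test_overlap_criterion_is_subset_of_lca_reconciliation(self):
        """On arbitrary random topologies every overlap-duplication is an
        LCA-duplication (the converse fails for discordant trees)."""
        sp = SpeciesTree.from_newick(SMALL_SP)
        rng = random.Random(2024)
        pool = sorted(sp.species)
        strict_subset_seen = False
        for _ in range(300):
            nwk = random_binary_gene_tree(rng, pool, rng.randint(2, 8))
            tree = read_gene_tree(nwk, species_tree=sp)
            ours = find_duplication_nodes(tree)
            oracle = lca_duplication_nodes(tree, sp)
            assert ours <= oracle
            strict_subset_seen |= ours < oracle
        assert strict_subset_seen  # discordance-only duplications exist

    def test_agrees_with_lca_oracle_on_duplication_generated_trees(self):
        sp = SpeciesTree.from_newick(SMALL_SP)
        for seed in range(200):
            fam = simulate_gene_family(sp, dup_rate=0.4, seed=seed)
            assert find_duplication_nodes(fam.gene_tree) == lca_duplication_nodes(
                fam.gene_tree, sp
            )


class TestAssignAncestralGenes:
    def test_worked_example_gene_two(self, species_tree, toy_newick):
        """Two basal singletons keep gene 1; the five-copy sponge clade is
        gene 2, born after the divergence of Porifera."""
        tree = read_gene_tree(toy_newick, species_tree=species_tree)
        lab = assign_ancestral_genes(tree, species_tree)
        assert lab.leaf_gene[("Aquee", "Plexin1")] == 1
        assert lab.leaf_gene[("Mleid", "Plexin1")] == 1
        gene2 = [k for k, g in lab.leaf_gene.items() if g == 2]
        assert sorted(gene2) == [("Aquee", f"PlexinA{i}") for i in range(1, 6)]
        assert len(lab.events) == 1
        (ev,) = lab.events
        assert (ev.parent_gene, ev.new_gene) == (1, 2)
        assert ev.species_branch.clade == "Porifera"
        assert lab.n_genes == 2

    def test_one_leaf_per_species_is_one_gene(self, species_tree):
        tree = read_gene_tree(
            "((Mbrev_P1,Srose_P1),(Aquee_P1,(Tadha_P1,Hsapi_P1)));",
            species_tree=species_tree,
        )
        lab = assign_ancestral_genes(tree, species_tree)
        assert set(lab.leaf_gene.values()) == {1}
        assert lab.events == ()

    def test_within_species_clade_shares_one_gene(self, species_tree):
        tree = read_gene_tree(
            "((Aquee_a,Aquee_b),Mleid_c);", species_tree=species_tree
        )
        lab = assign_ancestral_genes(tree, species_tree)
        assert set(lab.leaf_gene.values()) == {1}

    def test_non_monophyletic_copies_mint_new_genes(self, species_tree):
        tree = read_gene_tree(
            "((Aquee_a,Mleid_x),(Aquee_b,Mleid_y));", species_tree=species_tree
        )
        lab = assign_ancestral_genes(tree, species_tree)
        assert lab.n_genes == 2
        # both members of the new gene sit in one child subtree
        genes = {lab.leaf_gene[("Aquee", "a")], lab.leaf_gene[("Aquee", "b")]}
        assert genes == {1, 2}

    def test_gene_numbers_contiguous(self, species_tree):
        for seed in range(30):
            fam = simulate_gene_family(species_tree, dup_rate=0.25, seed=seed)
            lab = assign_ancestral_genes(fam.gene_tree, species_tree)
            genes = set(lab.leaf_gene.values())
            assert genes == set(range(1, lab.n_genes + 1))
            assert lab.n_genes == 1 + len(lab.events)

    def test_relabeling_invariance(self, species_tree, toy_newick):
        lab1 = assign_ancestral_genes(
            read_gene_tree(toy_newick, species_tree=species_tree), species_tree
        )
        renamed = toy_newick.replace("Plexin", "Prot")
        lab2 = assign_ancestral_genes(
            read_gene_tree(renamed, species_tree=species_tree), species_tree
        )
        remap = {k: (k[0], k[1].replace("Prot", "Plexin")) for k in lab2.leaf_gene}
        assert {remap[k]: g for k, g in lab2.leaf_gene.items()} == lab1.leaf_gene

    def test_adding_leaves_never_decreases_gene_count(self, species_tree):
        """Grow random trees one leaf at a time; the minimal ancestral-gene
        count is monotone."""
        rng = random.Random(11)
        pool = sorted(species_tree.species)
        for _ in range(15):
            leaves = [f"{rng.choice(pool)}_L0", f"{rng.choice(pool)}_L1"]
            tree_struct = f"({leaves[0]},{leaves[1]})"
            prev = 0
            for i in range(2, 10):
                nwk = tree_struct + ";"
                lab = assign_ancestral_genes(
                    read_gene_tree(nwk, species_tree=species_tree), species_tree
                )
                assert lab.n_genes >= prev
                prev = lab.n_genes
                # attach a new leaf next to a random existing leaf
                target = rng.choice(leaves)
                new = f"{rng.choice(pool)}_L{i}"
                tree_struct = tree_struct.replace(target, f"({target},{new})", 1)
                leaves.append(new)


class TestPlaceGene:
    def test_single_species_gene_maps_to_terminal_stem(self, species_tree):
        branch = place_gene(frozenset({"Aquee"}), species_tree)
        assert (branch.label, branch.clade) == ("Aquee", "Porifera")

    def test_two_clade_gene_maps_to_their_ancestor(self, species_tree):
        branch = place_gene(frozenset({"Tadha", "Nvect"}), species_tree)
        assert branch.label == "Parahoxozoa"

    def test_all_species_gene_maps_to_root_stem(self, species_tree):
        branch = place_gene(frozenset(species_tree.species), species_tree)
        assert branch.label == "Choanozoa"

    def test_rootward_gene_subset_warns(self, species_tree, caplog):
        with caplog.at_level("WARNING"):
            branch = place_gene(frozenset({"Mbrev", "Hsapi"}), species_tree)
        assert branch.label == "Choanozoa"
        assert "root stem" in caplog.text
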
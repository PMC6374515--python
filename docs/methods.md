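# Methods

## Scope and data model

The package operationalizes a comparative genomic survey of Sema-domain
proteins. The unit of analysis is a protein record: a species (one of 14
study taxa, each standing for a clade from Choanoflagellida to
Vertebrata), a membrane topology (secreted / transmembrane / GPI-anchored,
as predicted upstream by signal-peptide and TM predictors — we consume
those calls, we do not make them), and an ordered N→C list of domain
annotations over a fixed vocabulary. Coordinates are 1-based inclusive and
optional; every downstream decision works from token order alone, so
token-level records (like the packaged inventory) are fully supported. The
single TM token splits ecto- from endodomain; a record without TM is
treated as entirely extracellular.

`PSI_LIKE` is deliberately a separate token from `PSI`: the degenerate
PSI variant (missing some of the up-to-eight conserved cysteines) is
class-defining for the echinoderm Sema-SI semaphorins and must not count
as a PSI when discriminating Met from Met-LP architectures.

Truncation (missing sequence, conventionally drawn as asterisks and
written as poly-glycine runs in sequence files) is a per-record flag plus
optional per-domain flags. Truncated records are still classified — a
recognizable fragment such as a Sema+PSI+IPT stub is informative and is
assigned a family like any other record.

## Classifier

The decision table is ordered, and order carries meaning:

1. kinase + ≥2 ecto PSI → MET_LP. The Met vs Met-LP contrast is encoded
   as PSI count (1 vs ≥2) rather than ectodomain length: the complete
   plexin ectodomain has three PSI-IPT units, the Met ectodomain exactly
   one PSI before its IPT stack. This is robust to the IPT-count noise
   that truncated records show.
2. kinase + exactly 1 PSI + ≥1 IPT → MET.
3. ≥1 ecto IPT, no kinase → PLEXIN; `full` iff endo RASGAP present.
4. otherwise SEMAPHORIN, then by class:
   TSP1 presence outranks everything (TSP1 repeats are class-5-defining
   in every clade, non-bilaterian and bilaterian alike); then FNIII →
   Sema-FN; then PSI-like → Sema-SI (so the Ig-less Sema-SI member cannot
   leak into Sema-SP); then tandem (adjacent) Ig ×2 in Ctenophora →
   Sema-IG; then single-Ig rules (secreted Protostomia → Sema2;
   Vertebrata by topology → Sema3/4/7); finally the bare Sema+PSI rules
   (secreted Echinodermata → Sema-SP; Protostomia or non-bilaterians →
   Sema1 regardless of topology — the ctenophore class-1-like semaphorins
   are secreted while the sponge ones are transmembrane, so topology is
   not discriminative there; transmembrane Deuterostomia → Sema6).

A kinase-bearing record without IPT repeats fits no rule and is returned
UNCLASSIFIED rather than forced. Every classification carries the ordered
list of fired rules as its rationale.

The Sema1/Sema6 split is purely lineage-conditional (identical
architectures on either side of the protostome/deuterostome divide); this
is intrinsic to the naming tradition, not a limitation of the encoding.

## Packaged inventory

`data/sema_inventory.tsv` transcribes the survey's published per-species
inventories (131 records) at token level. Where only ranges or qualitative
counts are published, one representative value is pinned: choanoflagellate
Sema-FN with 6 (M. brevicollis) and 7 (S. rosetta) FNIII domains from the
stated 5–7 range; sponge Sema-FN with the 5 confidently detected FNIII
(up to 9 are suspected from spacing — we record the conservative count,
all high-certainty); 5 TSP1 repeats for "multiple TSP1" class-5 members
without a printed count (7 where printed: placozoan Sema5A, human
Sema5A/5B); human Plexin-C1 with one PSI and two IPT fewer than canonical.
The compact per-protein table in `fixtures.py` is the source of truth; the
TSV is generated from it and a test keeps both in sync. Whether the four
intracellularly truncated sponge plexins retain their TM segment is not
documented; the inventory assumes they do.

## Species tree

The packaged topology is the widely accepted backbone for the 14 taxa:
(Choanoflagellida,(Porifera,(Ctenophora,(Placozoa,(Cnidaria,(Protostomia,
Deuterostomia)))))), with Lophotrochozoa/Ecdysozoa and
Echinodermata/Chordata subsplits. Because the Porifera/Ctenophora order is
debated, `default_species_tree(swap_porifera_ctenophora=True)` exchanges
the two lineages; internal clade labels are positional conveniences and
keep their names under the swap. Branches are identified by the node they
subtend: species acronym for terminal stems, clade label for internal
stems; the branch above the root is the root stem.

## Duplication inference

A gene-tree internal node is a duplication node iff at least two of its
child subtrees contain leaves of the same species. Polytomies are soft:
an unresolved multifurcation whose children are species-disjoint implies
no event. This is the conservative, curator-style criterion; classical
LCA-mapping reconciliation additionally infers duplications from pure
topological discordance between gene tree and species tree. On gene trees
that actually arose by duplications along the species tree the two
criteria provably coincide (a property the test suite verifies against an
independently implemented brute-force LCA oracle over hundreds of
simulated trees); on arbitrary topologies the overlap criterion is a
strict subset, which is intentional — support for the discordant parts of
published trees is typically too weak to hang events on.

Labeling is greedy pre-order. The root lineage is gene 1. At an
inter-species duplication node, children uninvolved in any same-species
overlap inherit the parent's number; among involved children, the one
whose species set has the most basal species-tree LCA (smallest depth)
keeps the parent number — ties broken by child input order, making the
procedure deterministic — and each other involved child founds a new gene,
numbered at node-visit time in child order. A subtree containing only one
species receives a single number for all its copies regardless of its
internal structure (within-species expansions such as a five-copy -A1..A5
array are one ancestral gene). Each event is placed on the species-tree
stem of the smallest clade containing every species carrying the new
gene; single-species genes map to that species' terminal stem. Gene
numbers are contiguous 1..n and n = 1 + number of events.

The published narrative's clause about groups "comprising two copies of
the same taxon" is ambiguous for clades mixing one taxon's pair with
other taxa; the rules above reproduce the fully worked example (the
sponge gene-2 expansion) and make no stronger claim.

## Naming

Names are derived per species and per family/class stem from the gene
tree: singleton copies get numeric suffixes in order of increasing leaf
depth from the root (pre-order breaks ties) — a deterministic proxy for
"branches most basally"; each within-species monophyletic clade of ≥2
same-stem leaves takes the next unused letter with members numbered in
clade pre-order (Plexin-A1..A5). Numbered semaphorin classes use the
field's letter convention instead (Sema1A, 1B, ...). Hyphenation follows
the stem: `Plexin-1` / `Met-1` but `Met-LP1` / `Sema-FN1`. Whether
letter order among multiple within-species clades should follow figure
layout is unknowable from a tree; divergence depth is used.

## Conservation profile

Column score = mean substitution-matrix score over all unordered residue
pairs; any pair touching a gap (`-`) or mask (`X`) contributes 0 and
remains in the denominator, bounding the score and making results
bit-reproducible. Window score at start j (1-based) = mean of column
scores over j..j+W−1; a length-L alignment yields L−W+1 windows. Defaults:
W = 50 aa, BLOSUM62; any matrix readable by Biopython's flat-file reader
can be substituted. Plotting against window centers is left to the
presentation layer. The exact gap normalization of the original plotcon
implementation is not replicated — this contract is declared, not
reverse-engineered. Poly-glycine runs ≥ 15 aa are masked to `X` before
scoring (`mask_missing`); genuine short glycine runs are untouched. The
15-aa default is comfortably above natural glycine-rich linkers while
catching annotation-convention stretches.

## Synthetic data

`simulate_gene_family` draws, per species-tree branch (terminal branches
and the root stem included), a Poisson(dup_rate) number of duplication
events; each event picks one gene lineage crossing the branch uniformly
at random and splits it into the continuing parent copy (kept as first
child, so ties resolve toward the original lineage) and a new copy
inherited by all descendant species. No losses are modeled — the
analysis procedure itself does not model losses, and a loss_rate hook is
reserved but unimplemented. Ground truth mirrors the labeling convention:
internal-branch (and root-stem) events found new ancestral genes
(`true_events`); terminal-branch events only expand within-species clades
and share the parent's number (`within_species_events`), so the true gene
count is 1 + |true_events| and loss-free recovery by
`assign_ancestral_genes` is exact — which the tests require in 100% of
families. The default dup_rate 0.3/branch yields families of roughly
20–100 leaves (median ~45) on the 27-branch study tree, bracketing the
surveyed family sizes.

`simulate_architecture` emits one record per class token with stalk
counts drawn from the published ranges (FNIII and TSP1 uniform on 5..7),
choosing a clade-appropriate representative species so the
lineage-conditional rules are exercised; its closure under the classifier
is a tested invariant. `simulate_alignment` draws each column's residues
identical to a random consensus with the requested probability, else
uniform — it emulates a target conservation profile only, not indels,
rate heterogeneity among sites, or phylogenetic correlation, so passing
profile tests says nothing about alignment quality on real data.

All generators take an integer seed and are fully deterministic given it.

## What the tests do and do not show

The inventory reproduction tests show that the decision table encodes the
published structural definitions faithfully on the published
architectures — not that the classifier would survive noisy automated
domain scans (low-certainty and UNKNOWN annotations pass through but carry
no rules). Duplication-inference tests show equivalence with LCA
reconciliation in the concordant regime and exact recovery under the
simulator's assumptions (no loss, no discordance); real published trees
with gene losses or weakly supported conflicts need curatorial judgment
that this package makes explicit but cannot replace. The conservation
module is checked against hand-computed matrix arithmetic, not against
the original plotcon binary.

## Problem sizes and numerics

Default experiment sizes — 500 oracle-comparison trees (≤8 leaves on a
4-taxon tree), 200 recovery families on the full tree, alignments of a
few hundred columns — were chosen so the whole suite and the acceptance
script run in seconds while keeping the binomial uncertainty of the
reported percentages well below a percentage point. Window convolution
uses an explicit uniform kernel (numpy `convolve`, "valid" mode); column
scoring counts residue multiplicities, so cost is O(L·a²) in alphabet
size a, independent of row count beyond the counting pass.
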
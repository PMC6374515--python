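# semaplex

Toolkit for comparative surveys of **Sema-domain protein families** —
plexins, semaphorins, and Met / Met-LP receptor tyrosine kinases — across
eukaryote genomes, from unicellular choanoflagellates to human.

It is written for molecular evolution researchers who curate
domain-annotated protein inventories and published gene trees and want the
bookkeeping steps of such a survey to be explicit, reproducible code:

* **Architecture model & classifier** — proteins are ordered N→C token
  lists over a controlled domain vocabulary (SEMA, PSI, IPT, FN3, TSP1,
  IG, SEA, TM, RASGAP, TYRKIN, ...), split by the TM marker into ecto- and
  endodomain. A decision table assigns each record a family and, for
  semaphorins, a class:
  - endo TYRKIN + ≥2 ecto PSI (complete plexin ectodomain) → **Met-LP**;
  - endo TYRKIN + exactly 1 PSI + ≥1 IPT → **Met**;
  - ≥1 ecto IPT, no kinase → **plexin** (full-length iff endo RASGAP);
  - otherwise → **semaphorin**, with class rules ordered
    TSP1 → Sema5, FNIII → Sema-FN, PSI-like → Sema-SI, tandem Ig
    (Ctenophora) → Sema-IG, single Ig by lineage/topology → Sema2/3/4/7,
    bare Sema+PSI by lineage/topology → Sema-SP/Sema1/Sema6.
* **Packaged inventory** — a 131-protein, 14-species domain-annotation
  table transcribed from the survey's figure inventories
  (`semaplex/data/sema_inventory.tsv`), usable as test bed and template.
* **Ancestral-gene / duplication inference** — rooted, polytomy-tolerant
  gene trees (Newick, `Acronym_ProteinId` leaves) are read against a
  packaged reference species tree. A node is a duplication node iff two of
  its child subtrees share a species (a soft polytomy alone forces
  nothing). A greedy pre-order labeling carries "gene 1" from the root
  until duplications force new gene numbers; within-species monophyletic
  expansions share one number; every event is placed on the species-tree
  stem of the smallest clade containing the new gene. The minimal
  ancestral-gene count is `1 + #events`.
* **Tree-based naming** — per species and family, basally branching copies
  get suffixes `-1, -2, ...`; within-species clades get `-A1..-Ak`;
  numbered semaphorin classes use letter suffixes (`Sema1A`...).
* **Conservation profiles** — plotcon-style sliding-window mean pairwise
  similarity (default window 50 aa, BLOSUM62), with poly-glycine
  missing-sequence masking.
* **Synthetic data** — gene-family simulation with Poisson duplications on
  species-tree branches and recorded ground truth, class-consistent
  architecture generation, and alignments with controlled per-column
  conservation.

## Worked example

```python
import semaplex as sx

# classify the packaged sponge inventory
table = sx.classify_all(sx.load_fixture("Aquee"))
print(sx.summarize_counts(table).to_string())

# infer ancestral genes on a small plexin subtree
sp = sx.default_species_tree()
toy = ("((Aquee_Plexin1,Mleid_Plexin1,(Aquee_PlexinA1,Aquee_PlexinA2,"
       "Aquee_PlexinA3,Aquee_PlexinA4,Aquee_PlexinA5)));")
lab = sx.assign_ancestral_genes(sx.read_gene_tree(toy, species_tree=sp), sp)
print("ancestral genes:", lab.n_genes)
for ev in lab.events:
    print(f"gene {ev.parent_gene} -> gene {ev.new_gene} on branch "
          f"{ev.species_branch.label} ({ev.species_branch.clade})")
```

prints

```
family   PLEXIN  SEMAPHORIN  MET  MET_LP  UNCLASSIFIED
species
Aquee         6           4    0       0             0
ancestral genes: 2
gene 1 -> gene 2 on branch Aquee (Porifera)
```

i.e. the sponge carries six plexins and four semaphorins; on the subtree,
the two basally branching copies (sponge Plexin-1 and comb-jelly Plexin-1)
descend from ancestral gene 1, while the five-copy sponge expansion is
explained by a single duplication after the divergence of Porifera,
founding gene 2.

A CLI wraps the same operations
(`semaplex classify|name|reconcile|conserve|simulate|report`), e.g.:

```bash
semaplex classify --out survey/
semaplex reconcile --tree plexins.nwk --out recon/
semaplex conserve --alignment plexin_aln.fasta --window 50 --out cons/
```

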
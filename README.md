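# gh2arch

Domain-architecture classification and catalytic-domain phylogenetics
for family-2 glycoside hydrolases (GH2).

GH2 enzymes — β-galactosidases, β-glucuronidases, β-mannosidases —
share a catalytic TIM-barrel module (Pfam `Glyco_hydro_2_C`, "GH2C")
behind two N-terminal β-sandwiches, but differ sharply in what follows
the catalytic module. Those C-terminal differences sort the family into
five domain-architecture (DA) types and track function and evolution:
canonical β-galactosidases carry the small-subunit module
`Bgal_Small_N` (type 3), bicistronic β-galactosidases split the same
layout across two loci (type 2, LacL + LacM), β-glucuronidase-like
enzymes end at the catalytic module (type 1), and the divergent types 4
and 5 carry unannotated extensions, with the BIG1-bearing corner of
type 5 holding the high-transglycosylation β-galactosidases of
biotechnological interest (galactooligosaccharide synthesis).

`gh2arch` is for computational biologists who want that analysis as a
tested, seedable pipeline instead of a one-off. It takes protein
sequences (FASTA) plus Pfam-style envelope annotations (TSV or HMMER
`domtblout`) and provides:

* **Encoding** — binary DA vectors over a repeat-aware domain
  vocabulary (slot *(d, k)* = "≥ k tandem copies of domain *d*").
* **Classification** — admission filter (single GH2C, model coverage
  ≥ 0.70, no hybrid catalytic module) and the five-way DA-type rules,
  with subtypes, audit-friendly evidence trails, and bicistronic
  resolution from a partner-locus table.
* **C-terminal analysis** — extension extraction, BIG1 tagging
  (identity > 40% and reference coverage > 60%, both strict), and
  `Ct_<band>_<index>` clustering by length band + single-linkage
  identity.
* **Phylogeny** — in-house global affine aligner and progressive MSA,
  p-distances with Kimura protein correction, Saitou–Nei neighbor
  joining, column bootstrap, condensation of edges below 50% support
  into polytomies, and DA-vs-tree concordance (monophyly, purity,
  nesting).
* **Conservation** — active-site anchors mapped through the alignment,
  per-column conservation banded at >50% / 100%.
* **Synthetic data** — a generator that emits the exact input formats
  with full ground truth (true tree, planted DA types, bicistronic
  partners, planted conserved columns, pre-noise annotations), so the
  whole pipeline is testable offline.

## Worked example

Simulate a 30-taxon dataset, classify it, cluster the C-terminal
extensions, and build the bootstrap NJ tree of the catalytic modules:

```sh
$ gh2arch simulate --workdir demo --seed 42 --n-taxa 30
simulated 30 taxa into demo
$ gh2arch classify --workdir demo
da_type counts: {"1": 8, "2": 2, "3": 6, "4": 6, "5": 8}
$ gh2arch cluster-ct --workdir demo
14 extensions in 3 clusters
$ gh2arch tree --workdir demo --seed 42 --replicates 100
tree over 30 GH2C modules written
$ head -4 demo/concordance.tsv
label	monophyletic	clade_size	purity
1	1	8	1.000
2	1	2	1.000
3	0	8	0.750
```

Reading the output: all 30 planted architectures were recovered (8
type-1, 2 bicistronic type-2, 6 canonical type-3, 6 type-4, 8 type-5);
the 14 type-4/5 sequences with unannotated C-terminal extensions fell
into 3 length/similarity clusters. The concordance table shows type 1
and type 2 each forming clades, while type 3 is *not* monophyletic
(`purity 0.750`): its smallest containing clade holds 8 leaves, the 6
type-3 leaves plus the 2 bicistronic ones nested inside — exactly the
planted scenario in which bicistronic β-galactosidases emerge from
within the canonical clade by gene disruption. Stage outputs
(`classification.tsv`, `ct_clusters.tsv`, `gh2c_tree.nwk`,
`gh2c_tree_condensed.nwk`, `da_vectors.tsv`, `conservation.tsv`) are
plain TSV/Newick; every stage writes a manifest with its configuration
hash and seed, and identical seeds give byte-identical outputs.

The same pipeline runs on real data by placing your own
`sequences.fasta` and `domains.tsv` (columns: seq_id, domain,
env_start, env_end, model_coverage; or a HMMER domtblout) in the work
directory, with an optional `partners.tsv` for bicistronic resolution
and `big1_refs.fasta` for BIG1 tagging.

## Documentation

`docs/methods.md` describes the models, rules, thresholds and numerical
choices in detail, including what the synthetic generator does and does
not emulate.
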
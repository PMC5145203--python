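# Methods

## The problem

Family-2 glycoside hydrolases (GH2; CAZy classification) share a
catalytic (β/α)₈ TIM-barrel module — Pfam `Glyco_hydro_2_C`, abbreviated
GH2C — preceded by two β-sandwich modules (`Glyco_hydro_2_N` /
`Glyco_hydro_2`, here GH2N and GH2d). What differs across the family is
the C-terminal region, and that difference tracks function: canonical
β-galactosidases carry the small-subunit module `Bgal_Small_N` linked by
the β-sandwich DUF4981; bicistronic β-galactosidases split the same
layout across two loci (LacL + LacM); β-glucuronidase-like enzymes have
nothing after GH2C; and a divergent group — including the industrially
important high-transglycosylation β-galactosidases — carries DUF4982
followed by Ig-like modules (BIG1) and long unannotated extensions.

`gh2arch` implements that comparative analysis as a reproducible
pipeline: architecture encoding, rule-based classification into five
domain-architecture (DA) types, C-terminal extension analysis, a
catalytic-module phylogeny with bootstrap supports, DA-vs-tree
concordance, and active-site conservation profiling.

## Architecture encoding

A protein's architecture is the N→C ordered list of identified domains
after overlap resolution. Pfam envelopes occasionally overlap; when two
hits overlap by more than half the shorter span they are treated as
competing models for the same region and the hit with higher model
coverage wins (ties: longer span, then lexicographic name). Smaller
overlaps are kept — adjacent envelopes commonly abut or nick each other.

The dataset-wide vocabulary has one slot per (domain, ordinal): slot
(d, k) means "at least k tandem copies of d". Slots are ordered by each
domain's median relative midpoint position across the dataset, so the
vector layout reads roughly N-terminal to C-terminal. A presence/absence
vector cannot encode arbitrary per-protein domain order; order lives in
the `Architecture`, the vector encodes presence and repeat count. The
vocabulary is deterministic and invariant to input order (property-
tested), and `decode ∘ encode` is the identity on occurrence multisets.

## Classification

Admission filter: exactly one GH2C hit, model coverage ≥ 0.70
(boundary inclusive — "at least" is read literally), and no additional
catalytic module (a configurable blacklist captures hybrid enzymes).
Raising the floor can only shrink the admitted set (property-tested).

Core layout: `canonical` (GH2N, GH2d, GH2C in order) or `gh2d_like_gap`
— GH2d unannotated but the GH2N→GH2C gap has a length within 0.7–1.3×
the reference GH2d length, read as an unannotated equivalent domain.
The reference length is the dataset median GH2d span (falling back to
300 residues); the window bounds are configuration, since "similar
length" has no canonical quantification.

Decision order for the C-terminal region (first match wins):

1. `Bgal_Small_N` anywhere downstream of GH2C → **type 3**; subtypes:
   `3-appended` if decoration modules (LamG3, NPCBM, F5/F8, …) are also
   present, `3-canonical` if DUF4981 present and the core canonical,
   else `3-replaced`.
2. DUF4982 immediately after GH2C with further modules or an extension
   ≥ 60 residues → **type 5**.
3. A bare unannotated tail ≥ 60 residues → **type 4**.
4. Otherwise the call is deferred as `1or2`.

Bgal_Small_N outranks DUF4982 because it is the defining signature of
the canonical type. The 60-residue floor is the smallest reported
type-4 extension. N-terminal decorations (RicinB, YSIRK) are recorded
as flags and never change the type.

Deferred `1or2` calls resolve to **type 2** only with positive evidence
— a recorded small-subunit (LacM) partner locus, or a GH2C subcluster
tagged bicistronic — and default to **type 1** otherwise, mirroring the
fact that the two types are indistinguishable from the architecture of
the GH2C-bearing gene alone.

## C-terminal extensions

Extensions are the residues downstream of the last identified domain
(≥ 60 to count). A region is tagged BIG1-like when a global alignment
against a reference BIG1 module exceeds 40% identity with over 60%
coverage of the reference — both bounds strict. Identity and coverage
are defined against the reference (matches / aligned reference
positions; aligned reference positions / reference length), since the
rule compares candidate regions to reference exemplars. Lowering either
bound can only add tags (property-tested).

Extensions are grouped `Ct_<band>_<index>`: first into length bands
(defaults 60–300 and 301–1100 residues), then single-linkage clusters
on pairwise global-alignment identity at a 0.30 default threshold.
Single linkage on a thresholded identity graph gives the same
connected-component behaviour as cutting a tree of the extension
alignment, while being simpler and deterministic; the output equals
brute-force connected components (tested for small inputs). Labels are
deterministic: bands in order, clusters by smallest member id.

## Alignment

The pairwise stage is global affine-gap alignment (Gotoh's three-state
DP) under BLOSUM62 with gap open −11 / extend −1, the community default
for global protein alignment. The first gapped position costs the open
penalty, each further one the extend penalty. Traceback uses pointer
matrices recorded during the forward pass, with a fixed tie order
(substitution, then gap in the first input, then gap in the second), so
output is deterministic. Scores equal a brute-force enumeration over
all alignments for short inputs (tested exhaustively).

The multiple aligner is guide-tree progressive: WPGMA on 3-mer
distances for the guide tree, then leaf-to-root profile–profile merges
using the same affine DP on expected-score column profiles (gap mass
scores zero). Degapping any output row always reproduces the input
sequence (asserted at run time). Aligned FASTA import/export and PHYLIP
export allow swapping in an external aligner or cross-checking the
downstream stages with external tree software; parity with any specific
aligner is explicitly not promised.

## Phylogeny

Distances: p-distance (pairwise or complete gap deletion) with optional
Poisson (−ln(1−p)) or Kimura protein (−ln(1−p−0.2p²), the default)
corrections. A p at or beyond the correction's domain is flagged
saturated, not silently truncated; saturated pairs abort tree building
(or drop the affected bootstrap replicate, logged).

Tree building is Saitou–Nei neighbor joining with the standard Q
criterion. Ties take the lowest (row-major) index pair; negative branch
estimates clamp to zero, logged. NJ reconstructs any additive matrix
exactly (tested on random trees, 4–12 taxa) and agrees with an
independent implementation on noisy matrices.

Bootstrap: columns resampled with replacement, NJ per replicate, and
each internal edge of the full-data tree supported by the fraction of
replicate trees containing the same bipartition. Supports are exactly
reproducible given the seed. Supports of well-separated splits are
insensitive to input row order; splits involved in exact distance ties
are not, because the deterministic tie-break consumes indices — an
inherent property of any indexed tie-breaking rule.

Condensation contracts internal edges with support strictly below the
threshold (default 0.50; an edge at exactly the threshold survives)
into polytomies, discarding the contracted edge's length. Condensation
is idempotent and never adds edges.

Concordance treats monophyly in the unrooted sense: a label is
monophyletic iff some split separates exactly its leaf set (singletons
by convention). For each label the report gives the smallest split side
containing it and the label's purity inside it; the nesting matrix
marks labels strictly inside another label's smallest containing clade.
This is what turns "canonical β-galactosidases cluster together, with
bicistronic enzymes emerging inside them" into a computable statement.

Representative selection subclusters a distance matrix by single
linkage at a height cut, takes each subcluster's smallest member, and
fills the remaining quota by seeded uniform sampling — deterministic
given the seed, with every subcluster represented.

## Conservation profiling

Active-site residues are anchors: 1-based ungapped positions on a
reference row, each carrying its expected residue as an off-by-one
guard (a mismatch is a hard error). Anchors map through the alignment
to columns; each column's conservation is the percentage of rows
carrying the consensus residue — the column's modal residue by default,
with identity-to-reference available — banded as exactly 100%, strictly
above 50%, or below. Gaps never match and count in the denominator by
default (configurable), so sparsely populated columns read as poorly
conserved. When a sequence subset is supplied (e.g. the BIG1-tagged
set) each anchor also reports within-subset and rest conservation.
Documented presets ship for the Bacillus circulans active-site positions
(Lys 409, Glu 447 acid/base, Tyr 449, Asp 481, Tyr 511, Glu 532
nucleophile, Trp 570) and the Thermotoga maritima acceptor platform
(Trp 959); they are data, not hard-coded behaviour.

## The synthetic generator

The generator emits the exact formats the readers consume, plus ground
truth recorded before any corruption, so every stage of the pipeline is
testable without a database download.

Scenario: a rooted backbone `(type1, (type4, (type5, type3)))` mirrors
the evolutionary model the pipeline should recover — a core-only
ancestor, with clades gaining C-terminal modules: type 3 gains
DUF4981 + Bgal_Small_N (with replaced and decorated per-leaf variants),
type 4 a bare 200-residue extension, type 5 DUF4982 + a BIG1-like
module + a 250-residue tail (30% of type-5 leaves are BIG1-free). The
bicistronic subclade is grafted onto a branch *inside* the type-3
clade, making type 3 paraphyletic with respect to type 2; its leaves
emit two records each (core-only large subunit plus a standalone
small-subunit partner, mapped in a partner table).

Defaults: 60 taxa — 15/5/13/12/15 across types 1/2/3/4/5 — with module
lengths GH2N 180, GH2d 300, GH2C 320, DUF4981 100, DUF4982 110,
Bgal_Small_N 220, BIG1 90 residues. Sequences evolve by independent-site
substitution (uniform among the 19 alternatives) at 0.1 subs/site per
unit branch. Branch lengths are 0.3 + Exp(0.25) within clades and 0.8 on
backbone edges. The floor keeps every internal edge long enough (≥ 0.03
expected subs/site) to be resolvable from a 320-column alignment, and
the overall depth keeps pairwise p-distances inside the Kimura
correction's domain (p < 0.834) — a recoverable-by-design benchmark
rather than a coin flip. Four planted GH2C columns (positions 40, 110,
200, 260) are held invariant within the type-5 clade to give the
conservation stage known targets.

Noise knobs, applied after the truth snapshot: per-hit annotation
dropout, model-coverage jitter (clipped to [0,1]), hybrid-catalytic
contaminant records, and duplicated-GH2C records. The audit helper
compares calls against truth and attributes each miss to the dropped
annotations that caused it.

What the generator does *not* emulate: indels (alignment difficulty is
deliberately out of scope — the aligner is validated against oracles
instead), site-rate heterogeneity, an empirical exchangeability matrix,
compositional bias, and real Pfam HMM score distributions. Passing
recovery tests therefore demonstrates the correctness of the pipeline's
logic under its stated model, not robustness to every pathology of real
survey data.

## Statistical notes

Classifier agreement under 5% dropout is estimated by pooling ~57
admitted sequences per seed over 5 seeds (~290 trials): the per-seed
value is a small-n binomial draw (sd ≈ 0.03) that straddles the 0.90
bound by chance, while the pooled estimate (mean ≈ 0.94, sd ≈ 0.014)
tests the claim with adequate power. Tree-stage checks run 5 seeds at
100 bootstrap replicates each; the problem sizes (60 taxa, 320 columns)
keep the full default suite under half a minute while leaving all
recovery margins wide.

## Known limitations

* Tree inference is distance-NJ, not maximum likelihood; the package
  exports alignments (aligned FASTA/PHYLIP) for external ML
  verification, and its claims are topology-level.
* The type-5 C-terminal letter grammar is configurable but defaults to
  the two robust splits (BIG1-bearing vs BIG1-free, plus module
  decorations); finer subgroup labels depend on unpublished cutoffs.
* The vocabulary's "typical position" slot ordering is a heuristic; two
  proteins with the same domains in different orders receive the same
  vector (order is preserved in the architecture, not the vector).
* Bicistronic resolution requires external evidence (partner table or
  subcluster tags); without it every `1or2` call defaults to type 1.
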
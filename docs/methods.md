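# Methods

## Scope and model

`glub1typer` models agarose-gel PCR genotyping of the wheat *Glu-B1* locus
as three composable stages: (1) virtual allele-specific PCR on a template
sequence, (2) gel resolution of the predicted products into bands, and
(3) consistency-set inference from band patterns to allele calls. The
marker content — 23 primer sets (PS1–PS14 for *Glu-1Bx*, PS15–PS23 for
*Glu-1By*) and the allele registry — is packaged data, not code, so
corrections to published content are data patches.

## Virtual PCR

Primer annealing is sequence-determined only. A primer binds a template
window when

* internal mismatches ≤ `max_internal_mismatches` (default 1), and
* the 3′-terminal `three_prime_exact_len` bases (default 3) match exactly.

The exact-3′ rule is the operative model of allele-specific PCR: extension
from a 3′-mismatched primer is treated as completely blocked, which is how
the panel's SNP markers (e.g. the ZSBy8/By18-SNP forward primers that
differ only at their terminal base) separate alleles. A tolerated internal
mismatch is remembered and later downgrades the band to *weak*, which
reproduces the reported weak products of the By8-negative and 45-bp-indel
markers on *Glu-1By15*/*By20*. `N` in a template never pairs by default
(conservative for calling); a wildcard mode exists for draft sequences.

Products are enumerated for every upstream/downstream site pairing within
`max_product_bp` (default 3000), in both template orientations, so an
amplicon list is invariant under reverse-complementing the template.
Coordinates are 0-based half-open on the plus strand; `length = end −
start` counts both primer footprints. The "principal product" used for
size comparisons is the shortest product, i.e. the most efficiently
amplified, dominant gel band. There is no thermodynamics: annealing
temperatures in the panel are bench metadata and never consulted; Tm, ΔG,
dimers and amplification efficiency are out of scope.

## Gel model

Two sizes co-migrate when `|a − b| < max(f · mean(a,b), floor)` with
`f = 0.05, floor = 10 bp` at 1% agarose and `f = 0.02, floor = 5 bp` at
3%. These four numbers are the model's only free parameters and were
calibrated once against the panel's published gel-percentage column: every
marker must be resolvable at its listed percentage, the 15/18 bp
coding-region indel markers (run at 3%) must *fail* at 1% for their
~500 bp products, and every ≥43 bp promoter indel must already be visible
at 1%. Co-migrating products merge (single linkage over sorted sizes) into
a band at the rounded mean size; a band is *strong* if any merged product
was a perfect primer match. Migration distances, ladders and densitometry
are not modelled; intensity is a two-level ordinal because the source data
never quantify "weak".

## Decision engine

Expected outcomes live in a data matrix (allele × primer set). Three
scoring modes cover the panel: *presence* (dominant markers), *size*
(co-dominant indel markers, classes named by product length or indel
state) and *count* (the multi-band ZSBy9 marker: three bands for
*Glu-1By16*, one for *By15*/*By20*, two otherwise). An observed band
pattern matches a size class by nearest-class assignment with a 10%
sanity bound; band intensity participates in matching only for the three
markers where weak bands are documented (PS16, PS18, PS19) to avoid
leaning on an unquantified signal.

Inference intersects: the call is the set of alleles whose expected row is
consistent with *every* observed marker. Markers not observed are ignored;
observed markers inconsistent with all alleles are counted as conflicts;
an empty intersection is an explicit `no_call`. This representation makes
the two irreducible ambiguity classes — {*Bx14*^(+), *Bx20*} and {*By15*,
*By20*}, whose rows are identical by construction — fall out naturally,
and gives monotone refinement (more markers never widen a call).
*Glu-1By8** (no public sequence) is called purely by elimination: PS15
negative, PS16 positive-strong, PS17/PS23 negative, no 45 bp deletion.
The decision table covers the nine Bx and seven By alleles with published
marker outcomes; registry-only alleles (*Bx14**, *Bx17**, *Bx23*,
*Bx23**, *By15**) appear in the sequence-comparison tools instead.

Product sizes printed in the source tables and figures are used verbatim
in the size classes (520/563/705/748, 365/419, 457, 501, 254, 527, 543,
558 bp; 45 bp smaller for *By9*, 108 bp smaller for *Bx17*, 45 bp larger
for *Bx6*). Sizes the source never states (the 18 bp indel markers, the
junction markers, the ~900 bp 45-bp-indel markers, the ZSBy9 band ladder)
are fixture-defined constants chosen in the working range of the assay:
PS7/PS14 full = 518/del = 500, PS3 = 448, PS4 = 600, PS18
full/del45/larger = 898/853/988, PS19 = 533/488/623, PS22 bands at
300/500/700 (one band at 400 for *By15*/*By20*).

## Fixture design

Fixtures are layout-driven, not mutated copies of real accessions: a
haplotype is a concatenation of blocks — primer footprints carrying the
allele's discriminant bases, indel feature blocks, and seeded random
spacers sized so each marker hits its target product length. Block
presence is derived from the allele's expected-outcome row, and every
built template is self-checked (full panel run → gel → outcome comparison)
before use, so fixture soundness is enforced at construction. Spacer
content depends only on locus and seed, so two alleles' fixtures differ
exactly by their discriminant features, and toggling one indel feature
shifts precisely the spanning markers by the indel size. Spacers are
screened so no panel primer has an exact match outside a declared block;
two template positions adjacent to a shared reverse-primer site are pinned
to prevent a known overlap with the MHBy9-F2/MHBy16-F primer. The
multi-band ZSBy9 pairs are separated by >3 kb so cross-pair products
exceed the product ceiling. Fixtures do not emulate HMW-GS repeat-domain
structure, gene copy number (the *Bx7*^OE duplication is represented by
its junction sequences, a pure sequence property) or real intergenic
context — passing tests demonstrate the engine's logic, not performance on
raw genomic data.

Phylogeny fixtures are separate: 2400 nt coding-sequence stand-ins evolved
along a fixed reference tree by substituting disjoint site sets per
branch. Distances are therefore exactly additive, neighbor joining
recovers the generating topology, and the branch counts place the
documented sister pairs ({*Bx14*^(+), *Bx20*}, {*Bx14**, *Bx23**},
{*Bx7**, *Bx17*}, {*By15*, *By20*}, {*By8*, *By18*}) at ~99% pairwise
identity.

## Sequence comparison

Percent identity is matches / alignment columns × 100 over an optimal
global alignment (affine gaps; defaults match 1, mismatch −1, open −5,
extend −1), computed with Biopython's `PairwiseAligner` and checked in the
tests against an exhaustive small-case dynamic-programming oracle.
Pairwise identity replaces multiple alignment deliberately: the reported
percentages are pairwise, and pairwise global DP is exactly specifiable.
The tree is classic neighbor joining on 1 − identity/100 with
deterministic lexicographic tie-breaking; bootstrap support is out of
scope, so topologies are written as Newick without support values.

## Protein masses

Translation uses the standard genetic code, stopping at the first stop
codon; an ambiguous internal codon is an error naming the codon index.
Masses are average (Expasy residue masses + one water), matching the
"calculated molecular weight" convention of SDS-PAGE comparisons; the
default computes the full precursor (signal peptide included) since the
reported values do not state which form they use, with `strip_signal` for
the mature form. No post-translational modification or mobility modelling
— the assay literature itself notes mobility anomalies for these proteins.

## Numerical and degenerate-input choices

* Merged-band size is the rounded mean of merged sizes (arbitrary but
  deterministic and order-independent).
* Primer longer than template → empty site list, not an error; empty
  amplicon list → `absent` band pattern.
* An empty template list yields an empty panel-run map.
* Binding-site search is vectorized over sliding windows (numpy); tests
  hold it equal to an exhaustive per-window scan.
* All randomness (spacers, phylogeny ancestors) flows through explicit
  integer seeds; identical inputs are byte-identical outputs.

## Known limitations

* The engine reads sequence features only; polymerase, temperature and
  reaction-efficiency effects are intentionally absent, so a marker that
  fails on the bench for kinetic reasons will still "work" here.
* The gel model is a two-parameter threshold, not a migration simulation;
  it is calibrated to this panel's working range (≈250–1000 bp).
* Calling from real genomic sequence depends on the accession matching
  the panel's primer regions; draft sequences with Ns need the wildcard
  policy and deserve manual review of the evidence table.
* Registry alleles without published marker outcomes cannot be called,
  only compared by sequence.
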
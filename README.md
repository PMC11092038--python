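# glub1typer

PCR-marker genotyping of the wheat *Glu-B1* locus, in software.

In bread wheat (*Triticum aestivum*), the high-molecular-weight glutenin
subunits (HMW-GS) encoded at *Glu-B1* — a pair of tightly linked genes for
the x-type (*Glu-1Bx*) and y-type (*Glu-1By*) subunits — are major
determinants of dough strength and end-use quality. Breeding programs
screen germplasm with agarose-gel PCR markers that read out promoter/CDS
indels (15–185 bp), allele-specific SNPs (AS-PCR, where a primer's
3′-terminal base sits on the discriminating SNP so extension proceeds only
from the matching allele) and the gene-duplication junction that defines
the over-expression allele *Glu-1Bx7*^OE.

`glub1typer` implements that assay stack as a deterministic, testable
pipeline for people running or interpreting such marker panels:

* **panel** — the published 23-primer-set panel (PS1–PS23) and the
  *Glu-1Bx*/*Glu-1By* allele registry, shipped as validated data resources;
* **pcr** — a virtual AS-PCR engine: primer sites are windows with at most
  *m* internal mismatches (default 1) and an exactly matching 3′-terminal
  block (default 3 bases, modelling blocked extension from a 3′ mismatch);
  amplicons are enumerated with exact lengths on 0-based half-open
  plus-strand coordinates;
* **gel** — an agarose band model: two products co-migrate when their size
  difference is below `max(resolution_fraction · mean_size, floor_bp)`,
  with defaults calibrated to the panel's 1% vs 3% gel assignments;
* **genotype** — the discrimination logic as a decision matrix plus
  consistency-set inference: the call is the set of alleles whose expected
  marker outcomes agree with every observed band pattern, including the two
  documented ambiguity classes {*Bx14*^(+), *Bx20*} and {*By15*, *By20*};
* **fixtures** — layout-driven synthetic haplotypes embedding every primer
  site and indel, so the whole system runs and is tested with no downloads;
* **proteins** — CDS translation and average molecular mass (Expasy residue
  masses + one water) for SDS-PAGE-style calculated weights;
* **compare** — pairwise global identity (Needleman–Wunsch, affine gaps:
  match 1, mismatch −1, gap open −5, extend −1) and neighbor-joining
  topologies on *d* = 1 − identity/100.

## Worked example

Type a synthetic cultivar carrying *Glu-1Bx20* + *Glu-1By20* (the
Suwon15-type genotype):

```console
$ glub1 fixtures cultivar --bx Glu-1Bx20 --by Glu-1By20 --seed 1 --out suwon15.fasta
$ glub1 type --templates suwon15.fasta --cultivar Suwon15 | head -14
{
  "schema_version": 1,
  "cultivar": "Suwon15",
  "bx": {
    "locus": "Bx",
    "compatible_alleles": [
      "Glu-1Bx14(+)",
      "Glu-1Bx20"
    ],
    "ambiguous": true,
    "conflicts": 0,
    "evidence": [
      {
        "ps_id": "PS1",
```

The Bx call is the two-allele set {*Glu-1Bx14*^(+), *Glu-1Bx20*} with
`"ambiguous": true`: every marker of the panel behaves identically on the
two alleles (both show the 705 bp MAR product from the 185 bp promoter
insertion and the 501 bp MHBx20 product), so the engine reports the
equivalence class rather than guessing. The evidence array lists, per
primer set, the observed bands, the expected outcome and whether they
agree. The same pipeline is available from Python:

```python
from glub1typer import make_cultivar, type_cultivar

bx, by = type_cultivar(make_cultivar("Glu-1Bx7OE", "Glu-1By8*", seed=1))
print(bx.summary())   # Bx: Glu-1Bx7OE
print(by.summary())   # By: Glu-1By8*
```

Individual pieces are usable on their own, e.g. predicted products of the
MHpro13 co-dominant marker on a *Glu-1Bx13* fixture:

```console
$ glub1 fixtures make --allele Glu-1Bx13 --seed 7 --out bx13.fasta
$ glub1 amplify --template bx13.fasta --panel PS11
template_id	ps_id	start	end	length_bp	fwd_mm	rev_mm
Glu-1Bx13|fixture|seed7	PS11	750	1115	365	0	0
```

365 bp is the *Bx13* product (the promoter lacks the 54 bp cereal-box
duplication); every other Bx allele yields 419 bp at this marker.

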
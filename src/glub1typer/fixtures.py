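"""Synthetic allele-haplotype templates.

Real Glu-B1 haplotypes are multi-kilobase GenBank accessions; the fixture
generator instead builds layout-driven templates that embed, block by
block, exactly the sequence features the marker panel reads: every primer
footprint (with the allele's discriminating 3' bases), every promoter/CDS
indel, and the duplication-junction sites of Glu-1Bx7OE.  Block presence is
derived from the allele's expected marker outcomes, so by construction a
fixture amplifies into the allele's published band pattern -- and every
template is self-checked against that pattern before being returned.

Spacer sequence comes from a seeded pseudo-random stream shared by all
alleles of a locus, so two alleles' fixtures differ exactly by their
discriminant features.  Spacers are screened against exact matches of the
whole panel (both strands) to exclude accidental primer sites.

Fixtures do not emulate the HMW-GS repeat-domain structure or real
intergenic context; they are genotyping test articles, not biology.
"""

from __future__ import annotations

import random
import zlib
from dataclasses import dataclass
from functools import lru_cache

from .genotype import (
    bands_from_panel_run,
    decision_table,
    expected_pattern,
    observation_consistent,
)
from .panel import load_panel, panel_by_id, registry_by_name
from .pcr import MatchPolicy, Template, revcomp, run_panel

_FLIP = {"A": "C", "C": "A", "G": "T", "T": "G"}

PHYLO_SEQ_LENGTH = 2400


def _rng(*key) -> random.Random:
    seed = zlib.crc32("|".join(str(k) for k in key).encode())
    return random.Random(seed)


def _rand_dna(rng: random.Random, n: int) -> str:
    return "".join(rng.choice("ACGT") for _ in range(n))


def _flip(seq: str, index: int) -> str:
    return seq[:index] + _FLIP[seq[index]] + seq[index + 1 :]


@dataclass(frozen=True)
class FixtureBuild:
    """A built fixture template plus its feature coordinates (0-based, half-open)."""

    template: Template
    features: tuple[tuple[int, int, str], ...]


class _Layout:
    """Accumulates named sequence blocks into one template."""

    def __init__(self, locus: str, seed: int, salt: int = 0):
        self.locus = locus
        self.seed = seed
        self.salt = salt
        self.blocks: list[tuple[str, str]] = []

    def site(self, name: str, seq: str) -> None:
        self.blocks.append((f"site:{name}", seq))

    def feature(self, name: str, size: int) -> None:
        # feature content depends only on (locus, seed, name): identical
        # across alleles so presence/absence is the only difference
        self.blocks.append((f"feature:{name}", _rand_dna(_rng(self.locus, self.seed, "feat", name), size)))

    def gap(self, name: str, size: int, prefix: str = "") -> None:
        seq = prefix + _rand_dna(
            _rng(self.locus, self.seed, "gap", name, self.salt), size - len(prefix)
        )
        self.blocks.append((f"gap:{name}", seq))

    def assemble(self) -> tuple[str, tuple[tuple[int, int, str], ...]]:
        seq_parts, features, pos = [], [], 0
        for name, seq in self.blocks:
            if not name.startswith("gap:"):
                features.append((pos, pos + len(seq), name))
            seq_parts.append(seq)
            pos += len(seq)
        return "".join(seq_parts), tuple(features)


def _screen(sequence: str, features) -> bool:
    """True when every exact panel-primer match lies inside a declared block.

    An exact hit (either strand) whose footprint is not contained in a
    site/feature block must have arisen by accident in spacer sequence; the
    caller then re-rolls the spacers.
    """
    spans = [(s, e) for s, e, _ in features]
    for ps in load_panel():
        for primer in {ps.forward_seq, ps.reverse_seq}:
            for probe in (primer, revcomp(primer)):
                start = sequence.find(probe)
                while start != -1:
                    end = start + len(probe)
                    if not any(s <= start and end <= e for s, e in spans):
                        return False
                    start = sequence.find(probe, start + 1)
    return True


def _bx_layout(name: str, seed: int, salt: int) -> _Layout:
    o = expected_pattern(name)
    P = panel_by_id()
    lay = _Layout("Bx", seed, salt)

    # -- promoter: MAR (PS2) spans both insertions, MHBx-185 (PS5) the 185 bp one
    lay.gap("lead", 80)
    lay.site("PS2F", P["PS2"].forward_seq)
    lay.gap("p2.g1", 100)
    if o["PS2"].size_class in ("563", "748"):
        lay.feature("ins43", 43)
    lay.gap("p2.g2", 80)
    lay.site("PS5F", P["PS5"].forward_seq)
    lay.gap("p2.g3", 60)
    if o["PS2"].size_class in ("705", "748"):
        lay.feature("ins185", 185)
    lay.gap("p2.g4", 60)
    lay.site("PS5R", revcomp(P["PS5"].reverse_seq))
    lay.gap("p2.g5", 126)
    lay.site("PS2R", revcomp(P["PS2"].reverse_seq))
    lay.gap("sep1", 150)

    # -- promoter: MHpro13 (PS11) spans the 54 bp cereal-box duplication
    lay.site("PS11F", P["PS11"].forward_seq)
    lay.gap("p11.g1", 160)
    if o["PS11"].size_class == "419":
        lay.feature("dup54", 54)
    lay.gap("p11.g2", 161)
    lay.site("PS11R", revcomp(P["PS11"].reverse_seq))
    lay.gap("sep2", 150)

    # -- CDS: shared MHBx717/MHBx6 forward with the allele's reverse variant
    if o["PS1"].state == "positive" or o["PS10"].state == "positive":
        lay.site("PS1F", P["PS1"].forward_seq)  # identical to MHBx6-F / BX7-F
        lay.gap("p1.g1", 418)
        if o["PS1"].state == "positive":
            lay.site("PS1R", revcomp(P["PS1"].reverse_seq))
        else:
            lay.site("PS10R", revcomp(P["PS10"].reverse_seq))
        lay.gap("sep3", 150)

    # -- CDS: MHBx13 (PS12), Glu-1Bx13 only
    if o["PS12"].state == "positive":
        lay.site("PS12F", P["PS12"].forward_seq)
        lay.gap("p12.g1", 214)
        lay.site("PS12R", revcomp(P["PS12"].reverse_seq))
        lay.gap("sep4", 150)

    # -- CDS: MHBx20 (PS13), the Bx20/Bx14(+) SNP site
    if o["PS13"].state == "positive":
        lay.site("PS13F", P["PS13"].forward_seq)
        lay.gap("p13.g1", 461)
        lay.site("PS13R", revcomp(P["PS13"].reverse_seq))
        lay.gap("sep5", 150)

    # -- CDS: Bx7 (PS7) spans the hexapeptide-motif 18 bp indel
    lay.site("PS7F", P["PS7"].forward_seq)
    lay.gap("p7.g1", 231)
    if o["PS7"].size_class == "full":
        lay.feature("del18.ps7", 18)
    lay.gap("p7.g2", 231)
    lay.site("PS7R", revcomp(P["PS7"].reverse_seq))
    lay.gap("sep6", 150)

    # -- CDS: MHBx14(-) (PS14) spans the Bx14(-) 18 bp indel
    lay.site("PS14F", P["PS14"].forward_seq)
    lay.gap("p14.g1", 229)
    if o["PS14"].size_class == "full":
        lay.feature("del18.ps14", 18)
    lay.gap("p14.g2", 230)
    lay.site("PS14R", revcomp(P["PS14"].reverse_seq))
    lay.gap("sep7", 150)

    # -- CDS: cauBx642 (PS8) spans the 108 bp indel and the Bx6 45 bp extra
    lay.site("PS8F", P["PS8"].forward_seq)
    lay.gap("p8.g1", 165)
    if o["PS8"].size_class != "del108":
        lay.feature("seg108", 108)
    lay.gap("p8.g2", 165)
    if o["PS8"].size_class == "ins45":
        lay.feature("ins45", 45)
    lay.gap("p8.g3", 165)
    lay.site("PS8R", revcomp(P["PS8"].reverse_seq))
    lay.gap("sep8", 150)

    # -- duplication junctions (PS3/PS4), Glu-1Bx7OE only
    if o["PS3"].state == "positive":
        lay.site("PS3F", P["PS3"].forward_seq)
        lay.gap("p3.g1", 408)
        lay.site("PS3R", revcomp(P["PS3"].reverse_seq))
        lay.gap("sep9", 150)
        lay.site("PS4F", P["PS4"].forward_seq)
        lay.gap("p4.g1", 560)
        lay.site("PS4R", revcomp(P["PS4"].reverse_seq))
    lay.gap("tail", 80)
    return lay


def _by_layout(name: str, seed: int, salt: int) -> _Layout:
    o = expected_pattern(name)
    P = panel_by_id()
    lay = _Layout("By", seed, salt)

    # -- ZSBy8 / By18-SNP site (PS15/PS16): shared reverse, 3'-SNP forward
    lay.gap("lead", 80)
    if o["PS15"].state == "positive":
        fsite = P["PS15"].forward_seq  # By8: ...GTCT
    elif o["PS16"].intensity == "weak":
        fsite = _flip(P["PS16"].forward_seq, 9)  # By15/By20: internal mismatch
    else:
        fsite = P["PS16"].forward_seq  # other alleles: ...GTCC
    lay.site("PS15/16F", fsite)
    lay.gap("p15.g1", 488)
    lay.site("PS15/16R", revcomp(P["PS15"].reverse_seq))
    # the two bases after this reverse site complete an MHBy9-F2/MHBy16-F
    # match; pin them to TT so those primers cannot extend here
    lay.gap("sep1", 150, prefix="TT")

    # -- MHBy18 (PS17): 3'-SNP forward, exact only in Glu-1By18
    f17 = P["PS17"].forward_seq
    lay.site("PS17F", f17 if o["PS17"].state == "positive" else _flip(f17, len(f17) - 1))
    lay.gap("p17.g1", 502)
    lay.site("PS17R", revcomp(P["PS17"].reverse_seq))
    lay.gap("sep2", 150)

    # -- By01/ZSBy9a (PS18/PS19), nested; both span the 45 bp indel
    weak = o["PS18"].intensity == "weak"
    f18, f19 = P["PS18"].forward_seq, P["PS19"].forward_seq
    lay.site("PS18F", _flip(f18, 9) if weak else f18)
    lay.gap("p18.g1", 150)
    lay.site("PS19F", _flip(f19, 9) if weak else f19)
    lay.gap("p18.g2", 150)
    if o["PS18"].size_class != "del45":
        lay.feature("seg45", 45)
    lay.gap("p18.g3", 150)
    if o["PS18"].size_class == "larger":
        lay.feature("ins90", 90)
    lay.gap("p18.g4", 150)
    lay.site("PS19R", revcomp(P["PS19"].reverse_seq))
    lay.gap("p18.g5", 172)
    lay.site("PS18R", revcomp(P["PS18"].reverse_seq))
    lay.gap("sep3", 150)

    # -- ZSBy9 (PS22): one primer-site pair per band; pairs separated by more
    #    than the 3 kb product ceiling so cross-pair products are suppressed
    sizes = decision_table().markers["PS22"].classes[o["PS22"].size_class]
    for k, size in enumerate(sizes):
        if k:
            lay.gap(f"p22.sep{k}", 3100)
        lay.site(f"PS22F.{k}", P["PS22"].forward_seq)
        lay.gap(f"p22.g{k}", size - len(P["PS22"].forward_seq) - len(P["PS22"].reverse_seq))
        lay.site(f"PS22R.{k}", revcomp(P["PS22"].reverse_seq))
    lay.gap("sep4", 150)

    # -- MHBy16 (PS23): 3'-SNP forward, exact only in Glu-1By16
    f23 = P["PS23"].forward_seq
    lay.site("PS23F", f23 if o["PS23"].state == "positive" else _flip(f23, len(f23) - 1))
    lay.gap("p23.g1", 519)
    lay.site("PS23R", revcomp(P["PS23"].reverse_seq))
    lay.gap("tail", 80)
    return lay


def _self_check(template: Template, allele_name: str, locus: str) -> bool:
    products = run_panel([template], load_panel(), MatchPolicy())
    patterns = bands_from_panel_run(products)
    table = decision_table()
    expected = expected_pattern(allele_name)
    return all(
        observation_consistent(table.markers[ps_id], outcome, patterns[ps_id])
        for ps_id, outcome in expected.items()
        if table.markers[ps_id].locus == locus
    )


@lru_cache(maxsize=None)
def build_allele_fixture(allele_name: str, seed: int) -> FixtureBuild:
    """Build (and self-check) the fixture haplotype for one allele."""
    registry = registry_by_name()
    if allele_name not in registry:
        raise KeyError(
            f"unknown allele {allele_name!r}; valid names: {', '.join(sorted(registry))}"
        )
    if allele_name not in decision_table().rows:
        supported = ", ".join(sorted(decision_table().rows))
        raise KeyError(
            f"{allele_name} has no published marker outcomes; fixtures exist for: {supported}"
        )
    locus = registry[allele_name].locus
    builder = _bx_layout if locus == "Bx" else _by_layout
    for salt in range(10):
        lay = builder(allele_name, seed, salt)
        sequence, features = lay.assemble()
        template = Template(
            id=f"{allele_name}|fixture|seed{seed}", sequence=sequence, origin="fixture"
        )
        if _screen(sequence, features) and _self_check(template, allele_name, locus):
            return FixtureBuild(template=template, features=features)
    raise RuntimeError(f"could not build a clean fixture for {allele_name} (seed {seed})")


def make_allele_template(allele_name: str, seed: int = 0) -> Template:
    """Deterministic synthetic haplotype reproducing the allele's band pattern."""
    return build_allele_fixture(allele_name, seed).template


def make_cultivar(bx_name: str, by_name: str, seed: int = 0) -> list[Template]:
    """The two haplotype templates (Bx, By) of a synthetic cultivar."""
    registry = registry_by_name()
    for name, locus in ((bx_name, "Bx"), (by_name, "By")):
        if name in registry and registry[name].locus != locus:
            raise ValueError(f"{name} is not a {locus} allele")
    return [make_allele_template(bx_name, seed), make_allele_template(by_name, seed)]


def make_promoter_template(
    seed: int = 0, ins43: bool = False, ins185: bool = False, dup54: bool = True
) -> Template:
    """A bare Bx promoter fixture with a chosen insertion/duplication status.

    The MAR (PS2) product is 520 bp with no insertions and grows by exactly
    the inserted sizes; the MHpro13 (PS11) product is 419 bp with the 54 bp
    duplication and 365 bp without.
    """
    P = panel_by_id()
    lay = _Layout("BxPromoter", seed, 0)
    lay.gap("lead", 80)
    lay.site("PS2F", P["PS2"].forward_seq)
    lay.gap("p2.g1", 100)
    if ins43:
        lay.feature("ins43", 43)
    lay.gap("p2.g2", 80)
    lay.site("PS5F", P["PS5"].forward_seq)
    lay.gap("p2.g3", 60)
    if ins185:
        lay.feature("ins185", 185)
    lay.gap("p2.g4", 60)
    lay.site("PS5R", revcomp(P["PS5"].reverse_seq))
    lay.gap("p2.g5", 126)
    lay.site("PS2R", revcomp(P["PS2"].reverse_seq))
    lay.gap("sep1", 150)
    lay.site("PS11F", P["PS11"].forward_seq)
    lay.gap("p11.g1", 160)
    if dup54:
        lay.feature("dup54", 54)
    lay.gap("p11.g2", 161)
    lay.site("PS11R", revcomp(P["PS11"].reverse_seq))
    lay.gap("tail", 80)
    sequence, features = lay.assemble()
    tag = f"43{'+' if ins43 else '-'}185{'+' if ins185 else '-'}dup54{'+' if dup54 else '-'}"
    return Template(id=f"Bx-promoter|{tag}|seed{seed}", sequence=sequence, origin="fixture")


# ---------------------------------------------------------------------------
# phylogeny fixtures

# Nested (branch_mutation_count, subtree) structure; leaves are allele names.
# Branch counts are disjoint-site substitutions on a shared ancestor, so
# pairwise Hamming distances are exactly additive on this tree and the cherry
# pairs sit at ~99% identity over 2400 nt, mirroring the reported
# relationships among the coding sequences.
_BX_PHYLO = [
    (30, [
        (25, "Glu-1Bx6"),
        (30, [
            (25, "Glu-1Bx7"),
            (20, [(12, "Glu-1Bx7*"), (12, "Glu-1Bx17")]),
        ]),
    ]),
    (25, "Glu-1Bx14(-)"),
    (30, [
        (25, "Glu-1Bx13"),
        (25, [
            (25, "Glu-1Bx23"),
            (20, [
                (20, [(12, "Glu-1Bx14(+)"), (12, "Glu-1Bx20")]),
                (20, [(12, "Glu-1Bx14*"), (12, "Glu-1Bx23*")]),
            ]),
        ]),
    ]),
]

_BY_PHYLO = [
    (20, [(12, "Glu-1By8"), (12, "Glu-1By18")]),
    (30, "Glu-1By9"),
    (25, [
        (28, "Glu-1By16"),
        (18, [
            (22, "Glu-1By15*"),
            (16, [(12, "Glu-1By15"), (12, "Glu-1By20")]),
        ]),
    ]),
]

_NEXT_BASE = {"A": "C", "C": "G", "G": "T", "T": "A"}


@lru_cache(maxsize=None)
def phylogeny_sequences(locus: str, seed: int = 0, length: int = PHYLO_SEQ_LENGTH) -> dict[str, str]:
    """Coding-sequence stand-ins evolved along the reference allele tree.

    Synthetic: each branch substitutes a disjoint set of sites of a common
    seeded ancestor, giving additive pairwise distances whose neighbor-
    joining tree reproduces the published sister-pair structure.
    """
    if locus not in ("Bx", "By"):
        raise ValueError("locus must be 'Bx' or 'By'")
    tree = _BX_PHYLO if locus == "Bx" else _BY_PHYLO
    rng = _rng("phylo", locus, seed)
    ancestor = _rand_dna(rng, length)
    positions = list(range(length))
    rng.shuffle(positions)
    cursor = [0]

    def mutate(seq: str, k: int) -> str:
        chars = list(seq)
        for _ in range(k):
            p = positions[cursor[0]]
            cursor[0] += 1
            chars[p] = _NEXT_BASE[chars[p]]
        return "".join(chars)

    out: dict[str, str] = {}

    def walk(node, seq: str) -> None:
        if isinstance(node, str):
            out[node] = seq
            return
        for count, child in node:
            walk(child, mutate(seq, count))

    walk(tree, ancestor)
    return out
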
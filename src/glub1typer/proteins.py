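"""Translation and average molecular mass of HMW-GS coding sequences.

Masses are *average* (isotope-abundance weighted) residue masses plus one
water, the convention of the web calculators used for SDS-PAGE "calculated
molecular weight" comparisons; monoisotopic masses and post-translational
modifications are out of scope.  By default the full precursor (signal
peptide included) is computed, with an option to strip a caller-specified
signal length.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

# Expasy average residue masses (Da); free amino acid = residue + water.
RESIDUE_MASS_DA = {
    "A": 71.0788, "R": 156.1875, "N": 114.1038, "D": 115.0886, "C": 103.1388,
    "E": 129.1155, "Q": 128.1307, "G": 57.0519, "H": 137.1411, "I": 113.1594,
    "L": 113.1594, "K": 128.1741, "M": 131.1926, "F": 147.1766, "P": 97.1167,
    "S": 87.0782, "T": 101.1051, "W": 186.2132, "Y": 163.1760, "V": 99.1326,
}
WATER_DA = 18.01524

_CODON_TABLE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}


class CodonError(ValueError):
    pass


@dataclass(frozen=True)
class ProteinRecord:
    allele_name: str
    sequence: str
    mass_kda: float
    includes_signal_peptide: bool = True


def translate_cds(cds: str) -> str:
    """Standard-genetic-code translation up to (excluding) the first stop.

    A CDS not starting with ATG raises a warning, not an error.  An
    ambiguous codon (containing N) before the first stop is an error naming
    the codon index.
    """
    cds = cds.upper()
    if len(cds) < 3:
        raise CodonError("coding sequence shorter than one codon")
    if not cds.startswith("ATG"):
        warnings.warn("coding sequence does not start with ATG", stacklevel=2)
    protein = []
    for i in range(0, len(cds) - len(cds) % 3, 3):
        codon = cds[i : i + 3]
        if codon not in _CODON_TABLE:
            raise CodonError(f"ambiguous or invalid codon {codon!r} at codon index {i // 3}")
        aa = _CODON_TABLE[codon]
        if aa == "*":
            break
        protein.append(aa)
    return "".join(protein)


def average_mass(protein: str) -> float:
    """Average molecular mass of a protein in kDa (unrounded).

    Sum of average residue masses plus one water.  A non-standard residue
    raises an error naming the character.
    """
    if not protein:
        raise ValueError("empty protein sequence")
    total = WATER_DA
    for i, aa in enumerate(protein):
        try:
            total += RESIDUE_MASS_DA[aa]
        except KeyError:
            raise ValueError(f"non-standard residue {aa!r} at position {i}") from None
    return total / 1000.0


def protein_record(
    allele_name: str, cds: str, strip_signal: int = 0
) -> ProteinRecord:
    """Translate a CDS and report its average mass (2-decimal kDa).

    ``strip_signal`` removes that many N-terminal residues (the signal
    peptide) before computing the mass of the mature protein.
    """
    protein = translate_cds(cds)
    if strip_signal:
        if strip_signal >= len(protein):
            raise ValueError("strip_signal removes the entire protein")
        protein = protein[strip_signal:]
    return ProteinRecord(
        allele_name=allele_name,
        sequence=protein,
        mass_kda=round(average_mass(protein), 2),
        includes_signal_peptide=strip_signal == 0,
    )
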
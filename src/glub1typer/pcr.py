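"""Virtual allele-specific PCR.

Primer binding is modelled purely on sequence: a primer anneals at a
template window when the number of internal mismatches is within policy and
the 3'-terminal bases match exactly.  The exact-3'-end rule encodes AS-PCR
discrimination -- polymerase extension from a 3' mismatch is treated as
blocked, which is how the panel's SNP markers separate alleles.  There is no
thermodynamic model: annealing temperature, dimers and amplification
efficiency are out of scope.

Coordinates are 0-based, half-open, on the plus strand throughout, so
``length_bp == end - start`` with both primer footprints counted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .panel import PrimerSet

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

TEMPLATE_ALPHABET = set("ACGTN")


class TemplateError(ValueError):
    """Raised for templates containing characters outside A/C/G/T/N."""


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class Template:
    """A DNA sequence to amplify from (plus strand, 5'->3')."""

    id: str
    sequence: str
    origin: str = "user_fasta"  # accession | user_fasta | fixture

    def __post_init__(self) -> None:
        bad = next((i for i, c in enumerate(self.sequence) if c not in TEMPLATE_ALPHABET), None)
        if bad is not None:
            raise TemplateError(
                f"template {self.id!r}: illegal character {self.sequence[bad]!r} at position {bad}"
            )
        if not self.sequence:
            raise TemplateError(f"template {self.id!r}: empty sequence")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class MatchPolicy:
    """Allele-specific PCR matching policy.

    max_internal_mismatches
        mismatches tolerated outside the 3'-terminal window (default 1; a
        tolerated mismatch downgrades the band intensity downstream).
    three_prime_exact_len
        number of 3'-terminal primer bases that must match exactly.
    max_product_bp
        longest product reported.
    n_matches
        'never': an N in the template never pairs; 'wildcard': N pairs with
        anything (for draft sequences).
    """

    max_internal_mismatches: int = 1
    three_prime_exact_len: int = 3
    max_product_bp: int = 3000
    n_matches: str = "never"

    def __post_init__(self) -> None:
        if self.max_internal_mismatches < 0:
            raise ValueError("max_internal_mismatches must be >= 0")
        if self.three_prime_exact_len < 1:
            raise ValueError("three_prime_exact_len must be >= 1")
        if self.n_matches not in ("never", "wildcard"):
            raise ValueError("n_matches must be 'never' or 'wildcard'")


@dataclass(frozen=True, order=True)
class Amplicon:
    """A predicted PCR product delimited by the two primer footprints."""

    length_bp: int
    template_id: str = field(compare=False)
    start: int
    end: int
    fwd_mismatches: int
    rev_mismatches: int

    @property
    def total_mismatches(self) -> int:
        return self.fwd_mismatches + self.rev_mismatches


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def find_binding_sites(
    primer: str,
    template: Template,
    policy: MatchPolicy = MatchPolicy(),
    strand: str = "plus",
) -> list[tuple[int, int]]:
    """Locate primer binding windows on one strand of a template.

    Returns ``(position, mismatch_count)`` pairs where *position* is the
    0-based plus-strand start of the primer footprint.  On the minus strand
    the primer binds where the plus strand shows its reverse complement; the
    primer's 3' end then corresponds to the *leftmost* plus-strand base of
    the footprint.  A primer longer than the template yields an empty list.
    """
    if set(primer) - set("ACGT"):
        raise ValueError(f"primer must be over A/C/G/T: {primer!r}")
    if strand not in ("plus", "minus"):
        raise ValueError("strand must be 'plus' or 'minus'")
    w = len(primer)
    if w > len(template):
        return []

    if strand == "plus":
        probe = primer
        # 3'-terminal bases sit at the right edge of the window
        exact_idx = np.arange(w - policy.three_prime_exact_len, w)
    else:
        probe = revcomp(primer)
        # after reverse complement the primer 3' end is the window's left edge
        exact_idx = np.arange(0, policy.three_prime_exact_len)

    tarr = _encode(template.sequence)
    parr = _encode(probe)
    windows = np.lib.stride_tricks.sliding_window_view(tarr, w)
    diff = windows != parr
    if policy.n_matches == "never":
        # N never pairs: already a mismatch unless probe base is N too,
        # which cannot happen (primers are A/C/G/T only).
        diff |= windows == ord("N")
    else:
        diff &= windows != ord("N")
    exact_ok = ~diff[:, exact_idx].any(axis=1)
    mismatches = diff.sum(axis=1)
    ok = exact_ok & (mismatches <= policy.max_internal_mismatches)
    return [(int(i), int(mismatches[i])) for i in np.nonzero(ok)[0]]


def amplify(
    template: Template,
    ps: PrimerSet,
    policy: MatchPolicy = MatchPolicy(),
) -> list[Amplicon]:
    """Enumerate predicted products of one primer set on one template.

    Every pairing of a plus-strand forward site with a downstream
    minus-strand reverse site within ``max_product_bp`` is reported, sorted
    ascending by length.  The dominant gel band ("principal product") is by
    convention the shortest product, amplified most efficiently.
    """
    lf, lr = len(ps.forward_seq), len(ps.reverse_seq)
    out = []
    # both template orientations: (forward on plus, reverse on minus) and,
    # equivalently for the flipped template, (reverse on plus, forward on minus)
    orientations = [
        (find_binding_sites(ps.forward_seq, template, policy, "plus"),
         find_binding_sites(ps.reverse_seq, template, policy, "minus"), lr, False),
        (find_binding_sites(ps.reverse_seq, template, policy, "plus"),
         find_binding_sites(ps.forward_seq, template, policy, "minus"), lf, True),
    ]
    if ps.forward_seq == ps.reverse_seq:
        orientations = orientations[:1]
    for upstream, downstream, len_down, swapped in orientations:
        for upos, umm in upstream:
            for dpos, dmm in downstream:
                if dpos < upos:
                    continue  # downstream footprint must not start upstream
                length = dpos + len_down - upos
                if length < max(lf, lr) or length > policy.max_product_bp:
                    continue
                out.append(
                    Amplicon(
                        length_bp=length,
                        template_id=template.id,
                        start=upos,
                        end=dpos + len_down,
                        fwd_mismatches=dmm if swapped else umm,
                        rev_mismatches=umm if swapped else dmm,
                    )
                )
    out.sort()
    return out


def run_panel(
    templates: list[Template],
    panel: tuple[PrimerSet, ...],
    policy: MatchPolicy = MatchPolicy(),
) -> dict[str, list[Amplicon]]:
    """Amplify every primer set against every template.

    Returns a deterministically ordered map ``ps_id -> amplicons`` (union
    over templates, each primer set's list sorted by length).
    """
    if not templates:
        return {}
    result: dict[str, list[Amplicon]] = {}
    for ps in panel:
        hits: list[Amplicon] = []
        for template in templates:
            hits.extend(amplify(template, ps, policy))
        hits.sort()
        result[ps.id] = hits
    return result


def principal_product(amplicons: list[Amplicon]) -> Amplicon | None:
    """Shortest (dominant) product, or None when nothing amplified."""
    return amplicons[0] if amplicons else None
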
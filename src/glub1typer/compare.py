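"""Pairwise global identity and neighbor-joining topology.

Identity is computed from an optimal Needleman-Wunsch global alignment
under affine gap penalties (matches / alignment columns x 100), replacing
the multiple alignment used in the original analyses -- the reported
percentages are pairwise, and pairwise global DP is exactly specifiable.
The tree is classic neighbor joining on d = 1 - identity/100 with
deterministic lexicographic tie-breaking; bootstrap support is out of
scope.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from Bio import Align


@dataclass(frozen=True)
class AlignParams:
    match: float = 1.0
    mismatch: float = -1.0
    gap_open: float = -5.0
    gap_extend: float = -1.0


@dataclass(frozen=True)
class IdentityResult:
    pair: tuple[str, str]
    percent_identity: float
    alignment_length: int
    params: AlignParams


def _aligner(params: AlignParams) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = params.match
    aligner.mismatch_score = params.mismatch
    aligner.open_gap_score = params.gap_open
    aligner.extend_gap_score = params.gap_extend
    return aligner


def global_identity(
    a: str, b: str, params: AlignParams = AlignParams(), names: tuple[str, str] = ("a", "b")
) -> IdentityResult:
    """Percent identity over an optimal global alignment of two sequences."""
    if not a or not b:
        raise ValueError("both sequences must be non-empty")
    alignment = _aligner(params).align(a, b)[0]
    counts = alignment.counts()
    length = alignment.length
    return IdentityResult(
        pair=names,
        percent_identity=100.0 * counts.identities / length,
        alignment_length=length,
        params=params,
    )


@dataclass(frozen=True)
class TreeTopology:
    """Unrooted NJ topology as a nested grouping of leaf names."""

    structure: tuple  # nested tuples; leaves are str
    leaves: frozenset

    def newick(self) -> str:
        def fmt(node) -> str:
            if isinstance(node, str):
                return node.replace(" ", "_")
            return "(" + ",".join(fmt(c) for c in node) + ")"

        return fmt(self.structure) + ";"

    def cherries(self) -> set[frozenset]:
        """Leaf pairs attached to the same internal node."""
        found: set[frozenset] = set()

        def walk(node) -> None:
            if isinstance(node, str):
                return
            kids = [c for c in node if isinstance(c, str)]
            if len(node) == 2 and len(kids) == 2:
                found.add(frozenset(kids))
            for c in node:
                walk(c)

        walk(self.structure)
        return found

    def splits(self) -> set[frozenset]:
        """Non-trivial bipartitions in the canonical form of
        :func:`canonical_split`."""
        out: set[frozenset] = set()

        def walk(node) -> frozenset:
            if isinstance(node, str):
                return frozenset({node})
            below = frozenset().union(*(walk(c) for c in node))
            if 1 < len(below) < len(self.leaves) - 1:
                out.add(canonical_split(below, self.leaves))
            return below

        for child in self.structure:
            walk(child)
        return out


def canonical_split(side: frozenset, leaves: frozenset) -> frozenset:
    """A bipartition keyed by the side containing the smallest leaf name, so
    equal-sized sides compare unambiguously."""
    other = leaves - side
    return side if min(side) == min(leaves) else other


def distance_matrix(sequences: dict[str, str], params: AlignParams = AlignParams()):
    """Pairwise (1 - identity/100) distances, names sorted lexicographically."""
    names = sorted(sequences)
    n = len(names)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ident = global_identity(
                sequences[names[i]], sequences[names[j]], params, (names[i], names[j])
            )
            d[i, j] = d[j, i] = 1.0 - ident.percent_identity / 100.0
    return names, d


def nj_from_distances(names: list[str], d) -> TreeTopology:
    """Classic neighbor joining; ties broken by lexicographic leaf names."""
    if len(names) < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    d = np.asarray(d, dtype=float).copy()
    # each working node carries a stable label (smallest leaf name below it)
    labels = [name for name in names]
    structures: list = list(names)

    while len(structures) > 3:
        n = len(structures)
        r = d.sum(axis=1)
        best = None
        for i in range(n):
            for j in range(i + 1, n):
                q = (n - 2) * d[i, j] - r[i] - r[j]
                key = (q, *sorted((labels[i], labels[j])))
                if best is None or key < best[0]:
                    best = (key, i, j)
        _, i, j = best
        merged = (structures[i], structures[j])
        new_label = min(labels[i], labels[j])
        dij = d[i, j]
        new_row = 0.5 * (d[i, :] + d[j, :] - dij)
        keep = [k for k in range(n) if k not in (i, j)]
        d = np.vstack([d[np.ix_(keep, keep)], new_row[keep]])
        d = np.hstack([d, np.append(new_row[keep], 0.0)[:, None]])
        structures = [structures[k] for k in keep] + [merged]
        labels = [labels[k] for k in keep] + [new_label]

    order = np.argsort([labels[k] for k in range(len(structures))])
    structure = tuple(structures[k] for k in order)
    return TreeTopology(structure=structure, leaves=frozenset(names))


def nj_tree(sequences: dict[str, str], params: AlignParams = AlignParams()) -> TreeTopology:
    """Neighbor-joining topology from pairwise global-identity distances."""
    if len(sequences) != len(set(sequences)):
        raise ValueError("duplicate sequence names")
    names, d = distance_matrix(sequences, params)
    return nj_from_distances(names, d)
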
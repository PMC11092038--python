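"""Global identity and neighbor joining, with independent DP and NJ oracles."""

import functools
import random

import pytest

from conftest import rand_dna
from glub1typer.compare import (
    AlignParams,
    canonical_split,
    global_identity,
    nj_from_distances,
    nj_tree,
)
from glub1typer.fixtures import phylogeny_sequences
from glub1typer.pcr import revcomp


# --- tiny exhaustive alignment oracle (affine gaps, all co-optimal paths) ---

def _oracle_alignments(a: str, b: str, p: AlignParams):
    """All optimal global alignments of two short sequences by recursion.

    Returns (best_score, set of (identities, columns) over optimal paths).
    Affine gaps are handled by tracking the previous move state
    (0 = diagonal, 1 = gap in b, 2 = gap in a).
    """

    @functools.lru_cache(maxsize=None)
    def go(i, j, state):
        if i == len(a) and j == len(b):
            return frozenset({(0.0, 0, 0)})
        out = set()
        if i < len(a) and j < len(b):
            step = p.match if a[i] == b[j] else p.mismatch
            for s, ident, cols in go(i + 1, j + 1, 0):
                out.add((round(s + step, 6), ident + (a[i] == b[j]), cols + 1))
        if i < len(a):
            cost = p.gap_extend if state == 1 else p.gap_open
            for s, ident, cols in go(i + 1, j, 1):
                out.add((round(s + cost, 6), ident, cols + 1))
        if j < len(b):
            cost = p.gap_extend if state == 2 else p.gap_open
            for s, ident, cols in go(i, j + 1, 2):
                out.add((round(s + cost, 6), ident, cols + 1))
        best = max(s for s, _, _ in out)
        return frozenset(t for t in out if t[0] >= best - 1e-9)

    solutions = go(0, 0, 0)
    best = max(s for s, _, _ in solutions)
    return best, {(ident, cols) for s, ident, cols in solutions if s >= best - 1e-9}


class TestGlobalIdentity:
    def test_identical_sequences_are_100_percent(self):
        res = global_identity("ACGT", "ACGT")
        assert res.percent_identity == 100.0
        assert res.alignment_length == 4

    def test_symmetry(self):
        a, b = "ACGTACGTACGT", "ACGACGTTT"
        assert global_identity(a, b).percent_identity == pytest.approx(
            global_identity(b, a).percent_identity
        )

    def test_matches_exhaustive_dp_oracle(self):
        params = AlignParams()
        rng = random.Random(17)
        cases = [("ACGTACGT", "ACGACGT")]
        for _ in range(6):
            cases.append((rand_dna(rng, rng.randint(4, 8)), rand_dna(rng, rng.randint(4, 8))))
        for a, b in cases:
            res = global_identity(a, b, params)
            _best, optima = _oracle_alignments(a, b, params)
            observed = (
                round(res.percent_identity * res.alignment_length / 100),
                res.alignment_length,
            )
            assert observed in optima, (a, b, observed, optima)

    def test_invariant_under_joint_reverse_complement(self):
        rng = random.Random(23)
        a, b = rand_dna(rng, 120), rand_dna(rng, 110)
        assert global_identity(a, b).percent_identity == pytest.approx(
            global_identity(revcomp(a), revcomp(b)).percent_identity
        )

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            global_identity("", "ACGT")


def _random_additive_case(rng, n_leaves):
    """A random binary tree over n leaves and its additive distance matrix."""
    names = [f"L{i}" for i in range(n_leaves)]
    # adjacency with branch lengths
    edges = {}

    def link(u, v, w):
        edges.setdefault(u, []).append((v, w))
        edges.setdefault(v, []).append((u, w))

    pool = list(names)
    counter = 0
    while len(pool) > 1:
        i, j = sorted(rng.sample(range(len(pool)), 2), reverse=True)
        u, v = pool.pop(i), pool.pop(j)
        parent = f"I{counter}"
        counter += 1
        link(parent, u, rng.uniform(0.05, 0.6))
        link(parent, v, rng.uniform(0.05, 0.6))
        pool.append(parent)

    import numpy as np

    def dist(u, v):
        seen = {u}
        stack = [(u, 0.0)]
        while stack:
            node, acc = stack.pop()
            if node == v:
                return acc
            for nxt, w in edges.get(node, []):
                if nxt not in seen:
                    seen.add(nxt)
                    stack.append((nxt, acc + w))
        raise AssertionError

    d = np.zeros((n_leaves, n_leaves))
    for i in range(n_leaves):
        for j in range(i + 1, n_leaves):
            d[i, j] = d[j, i] = dist(names[i], names[j])

    splits = set()
    all_leaves = frozenset(names)

    def leaves_below(node, parent):
        if node.startswith("L"):
            return frozenset({node})
        out = frozenset()
        for nxt, _ in edges[node]:
            if nxt != parent:
                out |= leaves_below(nxt, node)
        return out

    for u in edges:
        for v, _ in edges[u]:
            below = leaves_below(v, u)
            if 1 < len(below) < n_leaves - 1:
                splits.add(canonical_split(below, all_leaves))
    return names, d, splits


class TestNeighborJoining:
    def test_three_leaves_single_unrooted_topology(self):
        topo = nj_tree({"A": "ACGTACGT", "B": "ACGTACGA", "C": "TTTTACGT"})
        assert topo.leaves == frozenset("ABC")
        assert len(topo.structure) == 3

    def test_fewer_than_three_rejected_and_duplicates(self):
        with pytest.raises(ValueError):
            nj_tree({"A": "ACGT", "B": "ACGT"})

    @pytest.mark.parametrize("trial", range(8))
    def test_recovers_random_additive_topologies_exactly(self, trial):
        rng = random.Random(400 + trial)
        names, d, true_splits = _random_additive_case(rng, 6)
        topo = nj_from_distances(names, d)
        assert topo.splits() == true_splits

    @pytest.mark.parametrize("trial", range(4))
    def test_agrees_with_dendropy_nj_oracle(self, trial):
        import dendropy

        rng = random.Random(900 + trial)
        names, d, _ = _random_additive_case(rng, 7)
        # perturb away from perfect additivity; both NJ implementations
        # must still pick the same topology
        for i in range(len(names)):
            for j in range(i + 1, len(names)):
                eps = rng.uniform(-0.01, 0.01)
                d[i, j] += eps
                d[j, i] += eps
        topo = nj_from_distances(names, d)

        pdm = dendropy.PhylogeneticDistanceMatrix.from_csv(
            src=_dendropy_csv(names, d), delimiter=","
        )
        ref = pdm.nj_tree()
        taxa = ref.taxon_namespace
        ref.encode_bipartitions()
        ref_splits = set()
        all_leaves = frozenset(names)
        for bipartition in ref.bipartition_encoding:
            side = frozenset(
                t.label for t in bipartition.leafset_taxa(taxa)
            )
            if 1 < len(side) < len(names) - 1:
                ref_splits.add(canonical_split(side, all_leaves))
        assert topo.splits() == ref_splits


def _dendropy_csv(names, d):
    import io

    buf = io.StringIO()
    buf.write("," + ",".join(names) + "\n")
    for i, name in enumerate(names):
        buf.write(name + "," + ",".join(f"{d[i, j]:.6f}" for j in range(len(names))) + "\n")
    buf.seek(0)
    return buf


class TestAlleleRelationships:
    def test_bx_phylogeny_reproduces_sister_pairs(self):
        topo = nj_tree(phylogeny_sequences("Bx", 0))
        cherries = topo.cherries()
        for pair in (
            {"Glu-1Bx14(+)", "Glu-1Bx20"},
            {"Glu-1Bx14*", "Glu-1Bx23*"},
            {"Glu-1Bx7*", "Glu-1Bx17"},
        ):
            assert frozenset(pair) in cherries

    def test_by_phylogeny_reproduces_sister_pairs(self):
        topo = nj_tree(phylogeny_sequences("By", 0))
        cherries = topo.cherries()
        assert frozenset({"Glu-1By15", "Glu-1By20"}) in cherries
        assert frozenset({"Glu-1By8", "Glu-1By18"}) in cherries

    def test_near_identical_pairs_round_to_99_percent(self):
        seqs = phylogeny_sequences("Bx", 0)
        res = global_identity(seqs["Glu-1Bx14(+)"], seqs["Glu-1Bx20"])
        assert round(res.percent_identity) == 99
        by = phylogeny_sequences("By", 0)
        assert round(global_identity(by["Glu-1By15"], by["Glu-1By20"]).percent_identity) == 99

    def test_newick_output_contains_all_leaves(self):
        topo = nj_tree(phylogeny_sequences("By", 0))
        newick = topo.newick()
        assert newick.endswith(";")
        for name in phylogeny_sequences("By", 0):
            assert name.replace(" ", "_") in newick
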
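"""Redundancy removal, similarity graphs and Markov clustering."""

import random

import numpy as np
import pytest

import classiphage as cp
from classiphage.clustering import SimilarityGraph, global_identity
from classiphage.genome_io import ProteinRecord

AA = "ACDEFGHIKLMNPQRSTVWY"


def _prot(pid, seq):
    return ProteinRecord(id=pid, sequence=seq, source_genome="g")


def _random_seq(rng, n=100):
    return "".join(rng.choice(AA) for _ in range(n))


def _mutate(seq, n_subs, rng):
    """Substitution-only edit: identity is exactly (len - n_subs) / len."""
    positions = rng.sample(range(len(seq)), n_subs)
    out = list(seq)
    for p in positions:
        out[p] = rng.choice([a for a in AA if a != out[p]])
    return "".join(out)


# ---------------------------------------------------------------------------
# dense brute-force MCL oracle (independent of the scipy implementation)
# ---------------------------------------------------------------------------

def mcl_oracle(nodes, edges, inflation=2.0, max_iter=100, tol=1e-6,
               loop=1.0, prune=1e-8):
    nodes = sorted(nodes)
    idx = {n: i for i, n in enumerate(nodes)}
    n = len(nodes)
    M = np.zeros((n, n))
    for (a, b), w in edges.items():
        M[idx[a], idx[b]] = M[idx[b], idx[a]] = w
    M += loop * np.eye(n)
    M = M / M.sum(axis=0, keepdims=True)
    for _ in range(max_iter):
        new = M @ M
        new = new ** inflation
        new[new < prune] = 0.0
        colsum = new.sum(axis=0, keepdims=True)
        colsum[colsum == 0] = 1.0
        new = new / colsum
        if np.abs(new - M).max() < tol:
            M = new
            break
        M = new
    # components of the support graph by BFS
    adj = (M > prune) | (M > prune).T
    seen, clusters = set(), []
    for s in range(n):
        if s in seen:
            continue
        stack, comp = [s], set()
        while stack:
            v = stack.pop()
            if v in comp:
                continue
            comp.add(v)
            stack.extend(int(u) for u in np.nonzero(adj[v])[0] if u not in comp)
        seen |= comp
        clusters.append({nodes[i] for i in comp})
    return sorted(clusters, key=lambda c: (-len(c), min(c)))


def _random_graph(rng, max_nodes=8):
    n = rng.randint(2, max_nodes)
    nodes = [f"n{i}" for i in range(n)]
    g = SimilarityGraph(nodes=nodes)
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < 0.45:
                g.add_edge(nodes[i], nodes[j], rng.choice([1.0, 2.0, 5.0, 10.0]))
    return g


# ---------------------------------------------------------------------------
# redundancy removal
# ---------------------------------------------------------------------------

class TestRemoveRedundant:
    def test_identical_pair_collapses(self):
        rng = random.Random(0)
        s = _random_seq(rng)
        reps, rmap = cp.remove_redundant([_prot("a", s), _prot("b", s)])
        assert len(reps) == 1
        assert rmap.removed_ids == {"a"} or rmap.removed_ids == {"b"}

    def test_three_dissimilar_sequences_all_kept(self):
        rng = random.Random(1)
        base = _random_seq(rng, 100)
        seqs = [base, _mutate(base, 15, rng), _mutate(base, 15, rng)]
        # substitution-count oracle: all pairwise identities <= 0.85 < 0.9
        for i in range(3):
            for j in range(i + 1, 3):
                hamming = sum(a == b for a, b in zip(seqs[i], seqs[j])) / 100
                assert hamming < 0.9
                assert global_identity(seqs[i], seqs[j]) >= hamming
        reps, rmap = cp.remove_redundant(
            [_prot(f"p{i}", s) for i, s in enumerate(seqs)], 0.9
        )
        assert len(reps) == 3 and rmap.removed_by_rep == {}

    def test_near_identical_joins_representative(self):
        rng = random.Random(2)
        base = _random_seq(rng, 100)
        variant = _mutate(base, 5, rng)  # 95% identical
        reps, rmap = cp.remove_redundant([_prot("a", base), _prot("b", variant)], 0.9)
        assert len(reps) == 1 and len(rmap.removed_ids) == 1

    def test_empty_input(self):
        reps, rmap = cp.remove_redundant([])
        assert reps == [] and rmap.removed_by_rep == {}

    def test_idempotent_on_representatives(self):
        rng = random.Random(3)
        base = _random_seq(rng, 120)
        prots = [_prot("a", base), _prot("b", _mutate(base, 4, rng)),
                 _prot("c", _random_seq(rng, 110)), _prot("d", _random_seq(rng, 90))]
        reps, _ = cp.remove_redundant(prots)
        again, rmap2 = cp.remove_redundant(reps)
        assert [r.id for r in again] == [r.id for r in reps]
        assert rmap2.removed_by_rep == {}

    def test_threshold_range_validated(self):
        with pytest.raises(ValueError):
            cp.remove_redundant([], identity_threshold=0.4)


# ---------------------------------------------------------------------------
# similarity graph
# ---------------------------------------------------------------------------

class TestSimilarityGraph:
    def test_single_protein_no_edges(self):
        g = cp.build_similarity_graph([_prot("a", "ACDEFGHIKLMNPQRST" * 5)])
        assert g.nodes == ["a"] and g.edges == {}

    def test_exact_copy_edge_at_cap_region(self):
        rng = random.Random(4)
        s = _random_seq(rng, 150)
        g = cp.build_similarity_graph([_prot("a", s), _prot("b", s)])
        assert ("a", "b") in g.edges
        assert g.edges[("a", "b")] > 50  # essentially zero E-value

    def test_unrelated_sequences_no_edge(self):
        rng = random.Random(5)
        g = cp.build_similarity_graph(
            [_prot("a", _random_seq(rng, 100)), _prot("b", _random_seq(rng, 100))]
        )
        assert g.edges == {}

    def test_self_edges_rejected_by_graph(self):
        g = SimilarityGraph(nodes=["a"])
        g.add_edge("a", "a", 1.0)
        assert g.edges == {}


# ---------------------------------------------------------------------------
# MCL
# ---------------------------------------------------------------------------

class TestMcl:
    def _clique_graph(self, groups, bridges=()):
        nodes = [n for grp in groups for n in grp]
        g = SimilarityGraph(nodes=nodes)
        for grp in groups:
            for i, a in enumerate(grp):
                for b in grp[i + 1:]:
                    g.add_edge(a, b, 5.0)
        for a, b, w in bridges:
            g.add_edge(a, b, w)
        return g

    def test_two_disjoint_cliques(self):
        g = self._clique_graph([[f"a{i}" for i in range(4)], [f"b{i}" for i in range(4)]])
        clusters = cp.mcl_cluster(g)
        assert sorted(map(sorted, clusters)) == [
            ["a0", "a1", "a2", "a3"], ["b0", "b1", "b2", "b3"]
        ]

    def test_singleton_node(self):
        clusters = cp.mcl_cluster(SimilarityGraph(nodes=["solo"]))
        assert clusters == [{"solo"}]

    def test_barbell_splits_against_oracle(self):
        a = [f"a{i}" for i in range(5)]
        b = [f"b{i}" for i in range(5)]
        g = self._clique_graph([a, b], bridges=[("a0", "b0", 1.0)])
        clusters = cp.mcl_cluster(g, inflation=2.0)
        expected = mcl_oracle(g.nodes, g.edges, inflation=2.0)
        assert clusters == expected
        assert len(clusters) == 2

    def test_partition_property(self):
        rng = random.Random(17)
        for _ in range(10):
            g = _random_graph(rng)
            clusters = cp.mcl_cluster(g)
            flat = [n for c in clusters for n in c]
            assert sorted(flat) == sorted(g.nodes)

    def test_relabel_invariance(self):
        rng = random.Random(23)
        g = _random_graph(rng, 7)
        mapping = {n: f"z{ord(n[1])}" for n in g.nodes}
        g2 = SimilarityGraph(nodes=[mapping[n] for n in g.nodes])
        for (a, b), w in g.edges.items():
            g2.add_edge(mapping[a], mapping[b], w)
        c1 = [frozenset(mapping[n] for n in c) for c in cp.mcl_cluster(g)]
        c2 = [frozenset(c) for c in cp.mcl_cluster(g2)]
        assert set(c1) == set(c2)

    def test_uniform_scaling_invariance(self):
        rng = random.Random(29)
        g = _random_graph(rng, 8)
        g2 = SimilarityGraph(nodes=list(g.nodes))
        for (a, b), w in g.edges.items():
            g2.add_edge(a, b, w * 3.5)
        # scaling all weights also scales the self-loop balance, so compare
        # with the loop scaled identically
        c1 = [frozenset(c) for c in cp.mcl_cluster(g, loop_weight=1.0)]
        c2 = [frozenset(c) for c in cp.mcl_cluster(g2, loop_weight=3.5)]
        assert set(c1) == set(c2)

    def test_matches_dense_oracle_on_small_graphs(self):
        rng = random.Random(99)
        for _ in range(25):
            g = _random_graph(rng)
            assert cp.mcl_cluster(g) == mcl_oracle(g.nodes, g.edges)

    def test_inflation_must_exceed_one(self):
        with pytest.raises(ValueError):
            cp.mcl_cluster(SimilarityGraph(nodes=["a"]), inflation=1.0)


# ---------------------------------------------------------------------------
# cluster size floor
# ---------------------------------------------------------------------------

class TestFilterClusters:
    def _prots(self, n):
        rng = random.Random(31)
        return [_prot(f"p{i:02d}", _random_seq(rng, 80)) for i in range(n)]

    def test_size_floor(self):
        prots = self._prots(17)
        ids = [p.id for p in prots]
        clusters = [set(ids[:7]), set(ids[7:12]), set(ids[12:16]), set(ids[16:])]
        kept = cp.filter_clusters(clusters, prots, min_cluster_size=5)
        assert [len(c.members) for c in kept] == [7, 5]

    def test_min_one_is_identity(self):
        prots = self._prots(4)
        clusters = [{p.id} for p in prots]
        kept = cp.filter_clusters(clusters, prots, min_cluster_size=1)
        assert len(kept) == 4

    def test_all_below_floor(self):
        prots = self._prots(4)
        kept = cp.filter_clusters([{p.id} for p in prots], prots, min_cluster_size=5)
        assert kept == []
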
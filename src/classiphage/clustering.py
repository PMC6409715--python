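"""Redundancy removal, all-vs-all similarity graphs, and Markov clustering.

Protein families are defined per phage-family label: proteins from genomes
with different labels are never clustered together, so every cluster (and
hence every model built from it) carries exactly one family label.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components

from Bio import Align
from Bio.Align import substitution_matrices

import pyhmmer
from pyhmmer import easel

from .genome_io import ProteinRecord

logger = logging.getLogger("classiphage")

#: cap on -log10(E) edge weights; identical pairs report E = 0
MAX_EDGE_WEIGHT = 200.0


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class SimilarityGraph:
    """Undirected weighted protein similarity graph (no stored self-edges)."""

    nodes: list[str]
    edges: dict[tuple[str, str], float] = field(default_factory=dict)

    def add_edge(self, a: str, b: str, weight: float) -> None:
        if a == b:
            return
        if not math.isfinite(weight) or weight < 0:
            raise ValueError(f"edge ({a},{b}) has invalid weight {weight}")
        key = (a, b) if a < b else (b, a)
        self.edges[key] = max(weight, self.edges.get(key, 0.0))


@dataclass
class RedundancyMap:
    """representative id -> ids removed as redundant with it."""

    removed_by_rep: dict[str, set[str]] = field(default_factory=dict)

    @property
    def removed_ids(self) -> set[str]:
        out: set[str] = set()
        for members in self.removed_by_rep.values():
            out |= members
        return out


@dataclass
class ProteinCluster:
    """An MCL cluster of proteins; the seed of one profile HMM."""

    cluster_id: str
    members: list[ProteinRecord]
    family_label: Optional[str] = None

    def __post_init__(self) -> None:
        ids = [m.id for m in self.members]
        if len(ids) != len(set(ids)):
            raise ValueError(f"cluster {self.cluster_id}: duplicate member ids")
        if not ids:
            raise ValueError(f"cluster {self.cluster_id}: empty")

    @property
    def member_ids(self) -> set[str]:
        return {m.id for m in self.members}


# ---------------------------------------------------------------------------
# redundancy removal (greedy incremental clustering, CD-hit style)
# ---------------------------------------------------------------------------

def _make_global_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -10.0
    aligner.extend_gap_score = -1.0
    aligner.mode = "global"
    return aligner


def _kmer_set(seq: str, k: int = 4) -> set[str]:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


def global_identity(a: str, b: str, aligner: Optional[Align.PairwiseAligner] = None) -> float:
    """Fraction of identical aligned residues over the shorter sequence length."""
    if not a or not b:
        return 0.0
    if aligner is None:
        aligner = _make_global_aligner()
    aln = aligner.align(a, b)[0]
    return aln.counts().identities / min(len(a), len(b))


def remove_redundant(
    proteins: Sequence[ProteinRecord], identity_threshold: float = 0.9
) -> tuple[list[ProteinRecord], RedundancyMap]:
    """Greedy incremental redundancy clustering.

    Sequences are processed by decreasing length (ties by id); each joins the
    first existing representative it matches at >= ``identity_threshold``
    global identity (identities over the shorter length), otherwise it opens
    a new representative.  A shared-k-mer prefilter skips alignments that
    cannot reach the threshold.
    """
    if not 0.5 < identity_threshold <= 1.0:
        raise ValueError("identity_threshold must be in (0.5, 1.0]")
    aligner = _make_global_aligner()
    ordered = sorted(proteins, key=lambda p: (-len(p.sequence), p.id))
    reps: list[ProteinRecord] = []
    rep_kmers: list[set[str]] = []
    rmap = RedundancyMap()
    for prot in ordered:
        kmers = _kmer_set(prot.sequence)
        joined = False
        for rep, rk in zip(reps, rep_kmers):
            # identity t forces roughly a (1 - 4t')-fraction of shared 4-mers;
            # 0.5 is a safe lower bound for any threshold > 0.5
            if kmers and len(kmers & rk) / len(kmers) < 0.5:
                continue
            if global_identity(prot.sequence, rep.sequence, aligner) >= identity_threshold:
                rmap.removed_by_rep.setdefault(rep.id, set()).add(prot.id)
                joined = True
                break
        if not joined:
            reps.append(prot)
            rep_kmers.append(kmers)
    reps.sort(key=lambda p: p.id)
    return reps, rmap


# ---------------------------------------------------------------------------
# similarity graph from all-vs-all profile search
# ---------------------------------------------------------------------------

def build_similarity_graph(
    proteins: Sequence[ProteinRecord],
    evalue_cutoff: float = 1e-5,
    weight: str = "neglog_evalue",
) -> SimilarityGraph:
    """All-vs-all sequence search; edges where E-value <= cutoff.

    Edge weight is ``min(-log10(E), 200)`` (or the bit score with
    ``weight='bitscore'``); the two search directions are symmetrized by
    taking the larger weight.
    """
    if not proteins:
        raise ValueError("need at least one protein")
    if weight not in ("neglog_evalue", "bitscore"):
        raise ValueError(f"unknown weight scheme {weight!r}")
    graph = SimilarityGraph(nodes=sorted(p.id for p in proteins))
    if len(proteins) == 1:
        return graph
    abc = easel.Alphabet.amino()
    digital = [
        easel.TextSequence(name=p.id.encode(), sequence=p.sequence).digitize(abc)
        for p in proteins
    ]
    block = easel.DigitalSequenceBlock(abc, digital)
    for query, tophits in zip(
        proteins, pyhmmer.hmmer.phmmer(digital, block, cpus=1, E=evalue_cutoff)
    ):
        for hit in tophits:
            target = hit.name if isinstance(hit.name, str) else hit.name.decode()
            if target == query.id or hit.evalue > evalue_cutoff:
                continue
            if weight == "bitscore":
                w = max(float(hit.score), 0.0)
            else:
                w = MAX_EDGE_WEIGHT if hit.evalue <= 0 else min(
                    -math.log10(hit.evalue), MAX_EDGE_WEIGHT
                )
            graph.add_edge(query.id, target, w)
    return graph


# ---------------------------------------------------------------------------
# Markov clustering
# ---------------------------------------------------------------------------

def mcl_cluster(
    graph: SimilarityGraph,
    inflation: float = 2.0,
    max_iter: int = 100,
    tol: float = 1e-6,
    loop_weight: float = 1.0,
    prune: float = 1e-8,
) -> list[set[str]]:
    """Markov clustering of a weighted undirected graph.

    Alternates expansion (matrix squaring) with inflation (entrywise power
    then column renormalization) on the column-stochastic flow matrix with
    self-loops, until the largest entry change falls below ``tol`` or
    ``max_iter`` rounds.  Clusters are the connected components of the
    converged flow's non-zero structure, so every node lands in exactly one
    cluster; output is sorted by (descending size, smallest node id).
    """
    if inflation <= 1:
        raise ValueError("inflation must exceed 1")
    nodes = sorted(graph.nodes)
    index = {n: i for i, n in enumerate(nodes)}
    n = len(nodes)
    if n == 0:
        return []
    rows, cols, vals = [], [], []
    for (a, b), w in graph.edges.items():
        if a == b:
            continue
        i, j = index[a], index[b]
        rows += [i, j]
        cols += [j, i]
        vals += [w, w]
    A = sp.csr_matrix((vals, (rows, cols)), shape=(n, n), dtype=float)
    if (A != A.T).nnz:  # defensive: SimilarityGraph is symmetric by construction
        logger.warning("similarity matrix not symmetric; symmetrizing by max")
        A = A.maximum(A.T)
    M = A + loop_weight * sp.identity(n, format="csr")

    def _normalize(mat: sp.csr_matrix) -> sp.csr_matrix:
        colsum = np.asarray(mat.sum(axis=0)).ravel()
        colsum[colsum == 0] = 1.0
        return mat @ sp.diags(1.0 / colsum)

    M = _normalize(M.tocsr())
    for _ in range(max_iter):
        expanded = M @ M
        inflated = expanded.power(inflation)
        inflated.data[inflated.data < prune] = 0.0
        inflated.eliminate_zeros()
        inflated = _normalize(inflated.tocsr())
        delta = abs(inflated - M).max() if (inflated - M).nnz else 0.0
        M = inflated
        if delta < tol:
            break

    support = (M > prune).astype(int)
    n_comp, labels = connected_components(support, directed=False)
    clusters: list[set[str]] = [set() for _ in range(n_comp)]
    for node, lab in zip(nodes, labels):
        clusters[lab].add(node)
    clusters.sort(key=lambda c: (-len(c), min(c)))
    return clusters


def filter_clusters(
    clusters: Sequence[set[str]],
    proteins: Sequence[ProteinRecord],
    min_cluster_size: int = 5,
    family_label: Optional[str] = None,
    id_prefix: str = "c",
) -> list[ProteinCluster]:
    """Materialize node-set clusters meeting the minimum-size floor.

    Clusters below the floor are dropped with a logged size (these are the
    protein families for which no model can be generated for lack of diverse
    members).
    """
    by_id = {p.id: p for p in proteins}
    kept: list[ProteinCluster] = []
    dropped = []
    for cl in sorted(clusters, key=lambda c: (-len(c), min(c))):
        if len(cl) < min_cluster_size:
            dropped.append(len(cl))
            continue
        members = [by_id[i] for i in sorted(cl)]
        label = family_label or members[0].family_label
        kept.append(
            ProteinCluster(
                cluster_id=f"{(label or 'na')}_{id_prefix}{len(kept):03d}",
                members=members,
                family_label=label,
            )
        )
    if dropped:
        logger.warning(
            "%d cluster(s) below min size %d dropped (sizes: %s)",
            len(dropped), min_cluster_size, dropped,
        )
    return kept


def cluster_proteins_by_family(
    proteins: Sequence[ProteinRecord],
    identity_threshold: float = 0.9,
    evalue_cutoff: float = 1e-5,
    inflation: float = 2.0,
    min_cluster_size: int = 5,
) -> tuple[list[ProteinCluster], RedundancyMap, dict]:
    """Full clustering stage: per-family redundancy removal, graph, MCL, floor.

    Returns the retained clusters, the merged redundancy map, and a per-family
    count summary (proteins, representatives, clusters, retained clusters).
    """
    by_family: dict[str, list[ProteinRecord]] = {}
    for p in proteins:
        by_family.setdefault(p.family_label or "unlabeled", []).append(p)
    all_clusters: list[ProteinCluster] = []
    rmap = RedundancyMap()
    summary: dict[str, dict[str, int]] = {}
    for family in sorted(by_family):
        fam_prots = by_family[family]
        reps, fam_rmap = remove_redundant(fam_prots, identity_threshold)
        rmap.removed_by_rep.update(fam_rmap.removed_by_rep)
        graph = build_similarity_graph(reps, evalue_cutoff)
        node_sets = mcl_cluster(graph, inflation=inflation)
        clusters = filter_clusters(
            node_sets, reps, min_cluster_size, family_label=family
        )
        all_clusters.extend(clusters)
        summary[family] = {
            "n_proteins": len(fam_prots),
            "n_representatives": len(reps),
            "n_clusters": len(node_sets),
            "n_retained_clusters": len(clusters),
        }
    return all_clusters, rmap, summary
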
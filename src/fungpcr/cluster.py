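"""Similarity-graph construction, Markov clustering, and dominant-domain
cluster summaries for the novel-receptor screen.

Markov clustering (MCL) alternates expansion (matrix squaring, spreading
flow along paths) with inflation (elementwise powering and column
renormalization, strengthening strong flows) on a column-stochastic matrix
until a fixed point; the attractor structure of the limit matrix defines
the clusters.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
from sklearn.base import BaseEstimator, ClusterMixin

from .io_formats import BlastHit, PfamAnnotation

__all__ = [
    "build_graph",
    "MarkovClustering",
    "mcl",
    "cluster_domain_summary",
    "write_clusters",
]

EVALUE_WEIGHT_CAP = 200.0


def build_graph(hits: Iterable[BlastHit], weight_mode: str = "evalue") -> nx.Graph:
    """Build a weighted undirected similarity graph from pairwise hits.

    ``weight_mode='evalue'`` uses -log10(E-value) capped at 200;
    ``'bitscore'`` uses the bit score. Asymmetric hit pairs keep the larger
    weight; self-hits are dropped. Nodes with only self-hits still appear
    (as isolated nodes).
    """
    if weight_mode not in ("evalue", "bitscore"):
        raise ValueError(f"unknown weight_mode {weight_mode!r}")
    g = nx.Graph()
    for h in hits:
        g.add_node(h.qid)
        g.add_node(h.sid)
        if h.qid == h.sid:
            continue
        if weight_mode == "evalue":
            w = min(-np.log10(max(h.evalue, 10.0 ** -EVALUE_WEIGHT_CAP)),
                    EVALUE_WEIGHT_CAP)
        else:
            w = float(h.bitscore)
        if w <= 0:
            continue
        prev = g.edges.get((h.qid, h.sid), {}).get("weight", 0.0)
        g.add_edge(h.qid, h.sid, weight=max(w, prev))
    return g


class MarkovClustering(ClusterMixin, BaseEstimator):
    """Markov clustering on a precomputed affinity matrix.

    Parameters
    ----------
    inflation : float, default 2.0
        Elementwise power applied at the inflation step; larger values give
        finer clusters.
    expansion : int, default 2
        Matrix power applied at the expansion step.
    prune_below : float, default 1e-5
        Entries below this are zeroed after each inflation (with columns
        renormalized), keeping the iteration sparse-in-effect.
    max_iter : int, default 200
    tol : float, default 1e-8
        Convergence threshold on the max absolute entry change.
    add_self_loops : bool, default True
        Give each node a self-loop equal to its maximum incident weight
        before iterating (standard practice; damps parity oscillation).

    Attributes
    ----------
    labels_ : ndarray of shape (n_nodes,)
        Cluster label per node.
    n_iter_ : int
    converged_ : bool
    """

    def __init__(self, inflation: float = 2.0, expansion: int = 2,
                 prune_below: float = 1e-5, max_iter: int = 200,
                 tol: float = 1e-8, add_self_loops: bool = True):
        self.inflation = inflation
        self.expansion = expansion
        self.prune_below = prune_below
        self.max_iter = max_iter
        self.tol = tol
        self.add_self_loops = add_self_loops

    def fit(self, X, y=None):
        """Cluster a symmetric non-negative affinity matrix ``X``."""
        A = np.asarray(X, dtype=float)
        if A.ndim != 2 or A.shape[0] != A.shape[1]:
            raise ValueError("affinity matrix must be square")
        if A.shape[0] == 0:
            raise ValueError("empty affinity matrix")
        if (A < 0).any():
            raise ValueError("affinities must be non-negative")
        n = A.shape[0]
        M = A.copy()
        np.fill_diagonal(M, 0.0)
        if self.add_self_loops:
            incident_max = M.max(axis=0)
            np.fill_diagonal(M, np.where(incident_max > 0, incident_max, 1.0))
        else:
            # isolated columns still need mass to be stochastic
            zero = M.sum(axis=0) == 0
            M[zero, zero] = 1.0
        M = M / M.sum(axis=0, keepdims=True)

        converged = False
        it = 0
        for it in range(1, self.max_iter + 1):
            prev = M
            M = np.linalg.matrix_power(M, self.expansion)
            M = np.power(M, self.inflation)
            M[M < self.prune_below] = 0.0
            colsum = M.sum(axis=0, keepdims=True)
            colsum[colsum == 0] = 1.0
            M = M / colsum
            if np.abs(M - prev).max() < self.tol:
                converged = True
                break
        if not converged:
            warnings.warn(
                f"MCL did not converge in {self.max_iter} iterations; "
                "interpreting the current matrix", RuntimeWarning)

        self.labels_ = self._interpret(M)
        self.n_iter_ = it
        self.converged_ = converged
        return self

    @staticmethod
    def _interpret(M: np.ndarray) -> np.ndarray:
        """Clusters from the (near-)limit matrix.

        Attractors are nodes with positive return flow (positive diagonal);
        each attractor's row support forms a cluster, overlapping attractor
        sets are merged, and any node left unattached becomes a singleton —
        the result is always a partition.
        """
        n = M.shape[0]
        parent = list(range(n))

        def find(a):
            while parent[a] != a:
                parent[a] = parent[parent[a]]
                a = parent[a]
            return a

        def union(a, b):
            ra, rb = find(a), find(b)
            if ra != rb:
                parent[rb] = ra

        attractors = np.where(np.diag(M) > 0)[0]
        for a in attractors:
            for j in np.where(M[a] > 0)[0]:
                union(a, j)
        roots = {}
        labels = np.empty(n, dtype=int)
        for i in range(n):
            r = find(i)
            labels[i] = roots.setdefault(r, len(roots))
        return labels


@dataclass(frozen=True)
class Clustering:
    """A partition of sequence ids into clusters (singletons included)."""

    clusters: tuple[frozenset[str], ...]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for c in self.clusters:
            if seen & c:
                raise ValueError("clusters overlap")
            seen |= c

    @property
    def node_set(self) -> frozenset[str]:
        return frozenset().union(*self.clusters) if self.clusters else frozenset()

    def __len__(self) -> int:
        return len(self.clusters)


def mcl(graph: nx.Graph, inflation: float = 2.0, expansion: int = 2,
        prune_below: float = 1e-5, max_iter: int = 200,
        tol: float = 1e-8) -> Clustering:
    """Markov-cluster a similarity graph; returns a partition of its nodes.

    Deterministic: node order is sorted before matrix construction, so any
    relabeling of input order yields the same partition.
    """
    if graph.number_of_nodes() == 0:
        raise ValueError("empty graph")
    nodes = sorted(graph.nodes())
    A = nx.to_numpy_array(graph, nodelist=nodes, weight="weight")
    est = MarkovClustering(inflation=inflation, expansion=expansion,
                           prune_below=prune_below, max_iter=max_iter,
                           tol=tol).fit(A)
    groups: dict[int, set[str]] = {}
    for node, lab in zip(nodes, est.labels_):
        groups.setdefault(int(lab), set()).add(node)
    ordered = sorted(groups.values(), key=lambda c: (-len(c), min(c)))
    return Clustering(clusters=tuple(frozenset(c) for c in ordered))


@dataclass(frozen=True)
class ClusterDomainSummary:
    cluster_index: int
    size: int
    dominant_domain: str | None
    dominant_fraction: float
    n_dominant: int
    n_other_domain: int
    n_no_domain: int
    tie: bool = False


def cluster_domain_summary(
    clustering: Clustering,
    annotations: Iterable[PfamAnnotation],
) -> list[ClusterDomainSummary]:
    """Per-cluster dominant Pfam domain and its member fraction.

    A member counts toward a domain if any of its annotations carry it;
    members with annotations but not the dominant domain are "other", the
    rest "no domain". Count ties break lexicographically and are flagged.
    """
    domains_by_seq: dict[str, set[str]] = {}
    for a in annotations:
        domains_by_seq.setdefault(a.seq_id, set()).add(a.domain_name)

    out = []
    for idx, cluster in enumerate(clustering.clusters):
        counts: dict[str, int] = {}
        n_annotated = 0
        for seq_id in cluster:
            doms = domains_by_seq.get(seq_id)
            if doms:
                n_annotated += 1
                for d in doms:
                    counts[d] = counts.get(d, 0) + 1
        if not counts:
            out.append(ClusterDomainSummary(
                idx, len(cluster), None, 0.0, 0, 0, len(cluster)))
            continue
        best_count = max(counts.values())
        tied = sorted(d for d, c in counts.items() if c == best_count)
        dominant = tied[0]
        out.append(ClusterDomainSummary(
            cluster_index=idx, size=len(cluster),
            dominant_domain=dominant,
            dominant_fraction=best_count / len(cluster),
            n_dominant=best_count,
            n_other_domain=n_annotated - best_count,
            n_no_domain=len(cluster) - n_annotated,
            tie=len(tied) > 1,
        ))
    return out


def write_clusters(clustering: Clustering, path) -> None:
    """MCL-style cluster file: one cluster per line, tab-separated ids."""
    with open(path, "w") as fh:
        for cluster in clustering.clusters:
            fh.write("\t".join(sorted(cluster)) + "\n")
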
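"""Phenotype landscape: minimum spanning tree and PCA ellipsoids.

The minimum spanning tree over pairwise Euclidean distances between
sample Z-score profiles gives a scaffold for the state landscape:
states whose members sit on their own branches are terminal phenotypes,
states whose members bridge others are transitional.  PCA with
per-group covariance ellipsoids compares the expression space occupied
by experimental groups (e.g. a constrained post-injury space lying
within the sham space).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import minimum_spanning_tree
from sklearn.decomposition import PCA

from .preprocessing import ZMatrix
from .states import StatePartition

__all__ = [
    "SampleTree",
    "EllipsoidSummary",
    "build_mst",
    "tree_distance",
    "classify_branches",
    "pca_ellipsoids",
]


@dataclass
class SampleTree:
    """Spanning tree over samples with Euclidean edge lengths."""

    graph: nx.Graph
    samples: list[str]

    def __post_init__(self) -> None:
        n = self.graph.number_of_nodes()
        if n >= 1 and self.graph.number_of_edges() != n - 1:
            raise ValueError("tree must have exactly n-1 edges")
        if n >= 1 and not nx.is_connected(self.graph):
            raise ValueError("tree must be connected")

    @property
    def total_length(self) -> float:
        return float(sum(d["length"] for _, _, d in self.graph.edges(data=True)))


@dataclass
class EllipsoidSummary:
    """Per-group PC-space centroids, ellipsoid axes, volumes, containment."""

    scores: pd.DataFrame
    groups: pd.Series
    n_pc: int
    radius_sd: float
    centroids: dict
    axes: dict
    volumes: dict
    degenerate: dict
    containment: pd.DataFrame
    explained_variance_ratio: np.ndarray


def build_mst(z: ZMatrix | pd.DataFrame) -> SampleTree:
    """Minimum spanning tree over pairwise Euclidean sample distances.

    Input is gene x sample; samples become nodes.  Ties between equal-
    length candidate edges resolve deterministically by sample order
    (the order of the input columns).  Duplicate samples yield a
    zero-length edge.
    """
    values = z.values if isinstance(z, ZMatrix) else z
    samples = [str(s) for s in values.columns]
    if len(samples) < 2:
        raise ValueError("need at least 2 samples")
    x = values.to_numpy(dtype=float).T
    diff = x[:, None, :] - x[None, :, :]
    d = np.sqrt((diff**2).sum(axis=2))
    # csgraph reads dense zeros as "no edge": lift exact-zero distances
    # (duplicate samples) to a negligible weight so their edges survive,
    # then report the true zero length on the graph.
    d_graph = d.copy()
    d_graph[d_graph == 0.0] = 1e-300
    np.fill_diagonal(d_graph, 0.0)
    mst = minimum_spanning_tree(csr_matrix(np.triu(d_graph))).toarray()
    g = nx.Graph()
    g.add_nodes_from(samples)
    for i, j in zip(*np.nonzero(mst + mst.T)):
        if i < j:
            g.add_edge(samples[i], samples[j], length=float(d[i, j]))
    return SampleTree(graph=g, samples=samples)


def tree_distance(tree: SampleTree, a: str, b: str, metric: str = "edges") -> float:
    """Unique tree-path distance between two samples.

    ``metric='edges'`` counts hops; ``metric='length'`` sums Euclidean
    edge lengths along the path.
    """
    for node in (a, b):
        if node not in tree.graph:
            raise KeyError(f"unknown node {node!r}")
    if metric == "edges":
        return float(nx.shortest_path_length(tree.graph, a, b))
    if metric == "length":
        return float(nx.shortest_path_length(tree.graph, a, b, weight="length"))
    raise ValueError("metric must be 'edges' or 'length'")


def classify_branches(
    tree: SampleTree,
    states: StatePartition,
    terminal_frac: float = 0.7,
) -> pd.DataFrame:
    """Call each state terminal or transitional from its tree placement.

    A member node is "leaf-side" when it does not lie between other
    states: removing it from the tree leaves at most one component that
    contains nodes of a different state.  A state is terminal when at
    least ``terminal_frac`` of its nodes are leaf-side — its members
    hang off a branch, and removing them would not disconnect the
    remaining states — else transitional (its members bridge other
    states, as a population caught mid-shift would).  Singleton states
    are terminal by convention and flagged.
    """
    labels = states.states
    missing = [n for n in tree.graph.nodes if n not in labels.index]
    if missing:
        raise ValueError(f"tree nodes without a state label: {missing}")

    def foreign_components(node: str) -> int:
        """Components of (tree - node) holding at least one other-state node."""
        state = labels[node]
        count = 0
        for start in tree.graph.neighbors(node):
            seen = {node, start}
            stack = [start]
            found = labels[start] != state
            while stack:
                cur = stack.pop()
                for nxt in tree.graph.neighbors(cur):
                    if nxt not in seen:
                        seen.add(nxt)
                        stack.append(nxt)
                        found = found or labels[nxt] != state
            count += found
        return count

    rows = []
    for state in states.state_labels:
        members = [n for n in tree.graph.nodes if labels[n] == state]
        leaf_side = sum(foreign_components(n) <= 1 for n in members)
        frac = leaf_side / len(members) if members else 0.0
        singleton = len(members) == 1
        call = "terminal" if (singleton or frac >= terminal_frac) else "transitional"
        rows.append(
            {"state": state, "n": len(members), "leaf_side_fraction": frac,
             "call": call, "singleton": singleton}
        )
    return pd.DataFrame(rows).set_index("state")


def _fix_pc_signs(components: np.ndarray) -> np.ndarray:
    """Deterministic sign convention: largest-|loading| entry positive."""
    flips = np.sign(components[np.arange(len(components)),
                               np.abs(components).argmax(axis=1)])
    flips[flips == 0] = 1.0
    return flips


def pca_ellipsoids(
    z: ZMatrix | pd.DataFrame,
    groups: pd.Series,
    n_pc: int = 3,
    radius_sd: float = 2.0,
) -> EllipsoidSummary:
    """Joint PCA with per-group covariance ellipsoids in PC space.

    PCA is fit on all samples together; each group is summarized by its
    centroid and covariance in the first ``n_pc`` PC scores.  The
    ellipsoid at ``radius_sd`` standard deviations has semi-axes
    ``radius_sd * sqrt(eigenvalue)`` and volume
    ``(4/3)*pi*prod(radius_sd*sqrt(lambda_i))`` (for n_pc=3).
    Containment[g, h] is the fraction of group g's points inside group
    h's ellipsoid (Mahalanobis distance <= radius_sd).
    """
    values = z.values if isinstance(z, ZMatrix) else z
    groups = pd.Series(groups).loc[values.columns]
    x = values.to_numpy(dtype=float).T  # samples x genes
    sizes = groups.value_counts()
    if (sizes < n_pc + 1).any():
        small = sizes[sizes < n_pc + 1].index.tolist()
        raise ValueError(f"groups need >= n_pc+1 samples; too small: {small}")
    pca = PCA(n_components=n_pc)
    scores = pca.fit_transform(x)
    flips = _fix_pc_signs(pca.components_)
    scores = scores * flips
    score_df = pd.DataFrame(
        scores, index=values.columns, columns=[f"PC{i+1}" for i in range(n_pc)]
    )
    unit_ball = math.pi ** (n_pc / 2) / math.gamma(n_pc / 2 + 1)
    centroids, axes, volumes, degenerate, cov_inv = {}, {}, {}, {}, {}
    for grp in sizes.index:
        pts = scores[(groups == grp).to_numpy()]
        mu = pts.mean(axis=0)
        cov = np.cov(pts, rowvar=False)
        eig = np.linalg.eigvalsh(cov)
        centroids[grp] = mu
        axes[grp] = radius_sd * np.sqrt(np.clip(eig, 0, None))[::-1]
        if np.min(eig) <= 1e-12:
            volumes[grp] = 0.0
            degenerate[grp] = True
            cov_inv[grp] = None
        else:
            volumes[grp] = float(unit_ball * np.prod(radius_sd * np.sqrt(eig)))
            degenerate[grp] = False
            cov_inv[grp] = np.linalg.inv(cov)
    grp_names = list(sizes.index)
    cont = pd.DataFrame(np.nan, index=grp_names, columns=grp_names)
    for g in grp_names:
        pts = scores[(groups == g).to_numpy()]
        for h in grp_names:
            if cov_inv[h] is None:
                continue
            delta = pts - centroids[h]
            maha = np.sqrt(np.einsum("ij,jk,ik->i", delta, cov_inv[h], delta))
            cont.loc[g, h] = float((maha <= radius_sd).mean())
    return EllipsoidSummary(
        scores=score_df, groups=groups, n_pc=n_pc, radius_sd=radius_sd,
        centroids=centroids, axes=axes, volumes=volumes, degenerate=degenerate,
        containment=cont, explained_variance_ratio=pca.explained_variance_ratio_,
    )
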
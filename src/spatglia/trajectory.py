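"""Signature-restricted pseudotime on a principal tree.

A 28-gene microglial panel (homeostatic plus disease-associated markers)
restricts the expression matrix; spots are embedded by PCA on the panel,
a principal tree is learned as k-means centroids joined by a Euclidean
minimum spanning tree, spots are projected onto the nearest tree edge,
and pseudotime is geodesic distance along the tree from a root.  The root
is chosen by the late-phase rule: the pole (leaf) *least* enriched for
the late disease group (AD, 7M) starts the trajectory, so late-group
spots sit at high pseudotime.  Branches are root-to-leaf paths;
shared-trunk spots belong to every branch whose path contains their edge.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy.sparse.csgraph import minimum_spanning_tree
from scipy.spatial.distance import cdist
from sklearn.cluster import KMeans

from .io import SpotDataset
from .preprocess import NormalizedMatrix, embed_pca, log_normalize

MICROGLIAL_PANEL = [
    "Hexb", "Cst3", "Cx3cr1", "Ctsd", "Csf1r", "Ctss", "Sparc", "Tmsb4x",
    "P2ry12", "C1qa", "C1qb", "Tmem119", "Tyrobp", "Ctsb", "Apoe", "B2m",
    "Fth1", "Lyz2", "Trem2", "Axl", "Cst7", "Ctsl", "Lpl", "Cd9", "Csf1",
    "Ccl6", "Itgax", "Timp2",
]


def panel_embedding(dataset: SpotDataset, panel=None, n_pcs: int = 10):
    """Log-normalize, restrict to the panel, z-score, PCA.

    At least half the panel must resolve in the dataset; missing genes are
    dropped with a warning.  Returns (embedding, genes_used).
    """
    panel = list(MICROGLIAL_PANEL) if panel is None else list(panel)
    present = set(dataset.gene_ids)
    used = [g for g in panel if g in present]
    missing = [g for g in panel if g not in present]
    if len(used) < max(2, int(np.ceil(len(panel) / 2))):
        raise ValueError(f"fewer than half the panel genes resolve; "
                         f"missing: {missing}")
    if missing:
        warnings.warn(f"panel genes absent from dataset: {missing}")
    norm = log_normalize(dataset)
    X = norm.dense(used)
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, ddof=0, keepdims=True)
    sd[sd == 0] = 1.0
    Z = (X - mu) / sd
    k = min(n_pcs, len(used), dataset.n_spots)
    if k < n_pcs:
        warnings.warn(f"panel supports only {k} PCs (requested {n_pcs})")
    return embed_pca(Z, n_pcs=k), used


@dataclass
class PrincipalGraph:
    """Tree over embedding centroids with per-spot edge projections."""

    node_coords: np.ndarray               # nodes x dims
    edges: list                           # (u, v) with u < v
    edge_lengths: np.ndarray
    spot_edge: np.ndarray                 # per-spot edge index
    spot_offset: np.ndarray               # position along edge in [0, 1]
    spot_node: np.ndarray                 # nearest node per spot

    @property
    def n_nodes(self) -> int:
        return len(self.node_coords)

    def tree(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(self.n_nodes))
        for (u, v), w in zip(self.edges, self.edge_lengths):
            g.add_edge(u, v, weight=float(w))
        return g

    def leaves(self) -> list:
        t = self.tree()
        return [n for n in t.nodes if t.degree(n) <= 1]


def _project_to_edges(points, node_coords, edges):
    """Nearest point on any tree edge for each spot."""
    n = len(points)
    best_d = np.full(n, np.inf)
    best_edge = np.zeros(n, dtype=int)
    best_t = np.zeros(n)
    for ei, (u, v) in enumerate(edges):
        a, b = node_coords[u], node_coords[v]
        ab = b - a
        denom = float(ab @ ab)
        if denom == 0:
            t = np.zeros(n)
        else:
            t = np.clip((points - a) @ ab / denom, 0.0, 1.0)
        proj = a + t[:, None] * ab
        d = np.einsum("ij,ij->i", points - proj, points - proj)
        upd = d < best_d
        best_d[upd] = d[upd]
        best_edge[upd] = ei
        best_t[upd] = t[upd]
    return best_edge, best_t


def _elastic_refine(pts: np.ndarray, centroids: np.ndarray,
                    elastic: float, n_iter: int) -> np.ndarray:
    """SimplePPT-style refinement: alternate the spanning tree with
    centroid updates that balance the assigned spots against a Laplacian
    pull toward tree neighbours.  Straightens the tree and suppresses
    lateral spur leaves that raw k-means+MST produces in noisy data."""
    n, k = len(pts), len(centroids)
    lam = elastic * n / k
    for _ in range(n_iter):
        D = cdist(centroids, centroids)
        mst = minimum_spanning_tree(D).tocoo()
        nbrs: list = [[] for _ in range(k)]
        for u, v in zip(mst.row, mst.col):
            nbrs[u].append(v)
            nbrs[v].append(u)
        assign = np.argmin(cdist(pts, centroids), axis=1)
        new = centroids.copy()
        for j in range(k):
            m = assign == j
            denom = m.sum() + lam * len(nbrs[j])
            if denom == 0:
                continue
            pull = lam * np.sum([centroids[l] for l in nbrs[j]], axis=0) \
                if nbrs[j] else 0.0
            new[j] = (pts[m].sum(axis=0) + pull) / denom
        centroids = new
    return centroids


def learn_principal_graph(embedding, n_nodes="auto", graph_dims: int = 2,
                          elastic: float = 1.0, n_refine: int = 10,
                          seed: int = 0) -> PrincipalGraph:
    """k-means centroids, elastic tree refinement, MST, edge projection.

    The graph lives in a low-dimensional graph space — the leading
    ``graph_dims`` dimensions of the supplied embedding (pass ``None`` to
    use all).  Trajectory learners conventionally operate in a 2-D
    embedding: with many dimensions the accumulated off-manifold noise
    between centroids rivals their on-manifold spacing and the spanning
    tree grows spurious twigs.  After k-means, ``n_refine`` iterations of
    a SimplePPT-style elastic update (strength ``elastic``; 0 disables)
    regularize the centroids toward a smooth tree.  ``n_nodes="auto"``
    uses ``clamp(ceil(n_spots / 50), 5, 100)``.  A degenerate embedding
    (all points equal) gives a single-node graph with a warning.
    """
    pts = embedding.scores if hasattr(embedding, "scores") else \
        np.asarray(embedding, dtype=float)
    if graph_dims is not None:
        pts = pts[:, :graph_dims]
    n_spots = len(pts)
    if n_spots < 10:
        raise ValueError("need >= 10 spots to learn a principal graph")
    if np.allclose(pts, pts[0]):
        warnings.warn("degenerate embedding; returning single-node graph")
        return PrincipalGraph(pts[:1].copy(), [], np.zeros(0),
                              np.zeros(n_spots, dtype=int),
                              np.zeros(n_spots), np.zeros(n_spots, dtype=int))
    if n_nodes == "auto":
        k = int(np.clip(np.ceil(n_spots / 50), 5, 100))
    else:
        k = int(n_nodes)
    k = min(k, len(np.unique(pts, axis=0)))
    km = KMeans(n_clusters=k, n_init=10, random_state=seed)
    km.fit(pts)
    centroids = km.cluster_centers_
    if elastic > 0 and n_refine > 0 and k > 1:
        centroids = _elastic_refine(pts, centroids, elastic, n_refine)
    D = cdist(centroids, centroids)
    mst = minimum_spanning_tree(D).tocoo()
    edges = [(int(min(u, v)), int(max(u, v)))
             for u, v in zip(mst.row, mst.col)]
    edges.sort()
    lengths = np.array([D[u, v] for u, v in edges])
    spot_edge, spot_t = _project_to_edges(pts, centroids, edges)
    spot_node = np.array([
        edges[e][0] if t < 0.5 else edges[e][1]
        for e, t in zip(spot_edge, spot_t)])
    return PrincipalGraph(centroids, edges, lengths, spot_edge, spot_t,
                          spot_node)


def select_root(graph: PrincipalGraph, genotype_labels, age_labels, *,
                late_group=("AD", "7M")) -> tuple[int, pd.DataFrame]:
    """Root = the leaf least enriched for the late disease group.

    Per node, the fraction of its projected spots in ``late_group`` is
    computed; among leaves with at least one projected spot, the one with
    the minimal late fraction is the root (ties broken by smallest node
    id, with a warning).  Returns (root, per-node enrichment table).
    """
    leaves = graph.leaves()
    if len(leaves) < 2:
        raise ValueError("graph needs >= 2 leaves to orient")
    late = ((np.asarray(genotype_labels) == late_group[0])
            & (np.asarray(age_labels) == late_group[1]))
    rows = []
    for node in range(graph.n_nodes):
        m = graph.spot_node == node
        rows.append({
            "node": node, "n_spots": int(m.sum()),
            "late_fraction": float(late[m].mean()) if m.any() else np.nan,
            "is_leaf": node in leaves,
        })
    enrich = pd.DataFrame(rows)
    cand = enrich[enrich["is_leaf"] & (enrich["n_spots"] > 0)]
    if cand.empty:
        raise ValueError("no leaf has projected spots")
    lo = cand["late_fraction"].min()
    tied = cand[cand["late_fraction"] == lo]["node"].tolist()
    if len(tied) > 1:
        warnings.warn(f"root tie between leaves {tied}; taking node "
                      f"{min(tied)}")
    return int(min(tied)), enrich


@dataclass
class PseudotimeAssignment:
    root: int
    pseudotime: np.ndarray
    node_pseudotime: np.ndarray
    graph: PrincipalGraph
    late_group: tuple = ("AD", "7M")
    branch_of_spot: pd.DataFrame | None = None


def compute_pseudotime(graph: PrincipalGraph,
                       root: int) -> PseudotimeAssignment:
    """Geodesic distance along the tree from the root to each projection.

    A spot projected onto edge (u, v) at offset t gets
    ``dist(root, near) + along-edge offset`` where ``near`` is the edge
    endpoint closer to the root — exactly the tree geodesic to the
    projected point.
    """
    if graph.n_nodes == 0:
        raise ValueError("empty graph")
    if not 0 <= root < graph.n_nodes:
        raise ValueError(f"root {root} is not a graph node")
    t = graph.tree()
    dist = nx.single_source_dijkstra_path_length(t, root)
    node_pt = np.array([dist[n] for n in range(graph.n_nodes)])
    pt = np.zeros(len(graph.spot_edge))
    for i, (ei, off) in enumerate(zip(graph.spot_edge, graph.spot_offset)):
        if len(graph.edges) == 0:
            pt[i] = 0.0
            continue
        u, v = graph.edges[ei]
        w = graph.edge_lengths[ei]
        if node_pt[u] <= node_pt[v]:     # u is the root-side endpoint
            pt[i] = node_pt[u] + off * w
        else:
            pt[i] = node_pt[v] + (1.0 - off) * w
    return PseudotimeAssignment(root, pt, node_pt, graph)


@dataclass
class BranchTrajectory:
    branch_id: int
    leaf: int
    node_path: list
    spot_mask: np.ndarray
    shared: np.ndarray                   # True where the spot's edge is on
                                         # more than one branch (trunk)


def extract_branches(graph: PrincipalGraph, root: int) -> list:
    """One branch per leaf (other than the root): the root-to-leaf path.

    Spots belong to each branch containing their projection edge; spots on
    a shared trunk appear in several branches with ``shared`` set.
    """
    if graph.n_nodes <= 1 or len(graph.edges) == 0:
        warnings.warn("single-node graph: no branches")
        return []
    t = graph.tree()
    leaves = [n for n in graph.leaves() if n != root]
    edge_index = {e: i for i, e in enumerate(graph.edges)}
    edge_use = np.zeros(len(graph.edges), dtype=int)
    branch_edges = []
    for leaf in leaves:
        path = nx.shortest_path(t, root, leaf)
        eids = [edge_index[(min(a, b), max(a, b))]
                for a, b in zip(path[:-1], path[1:])]
        branch_edges.append((leaf, path, eids))
        edge_use[eids] += 1
    branches = []
    for bid, (leaf, path, eids) in enumerate(branch_edges):
        on_branch = np.isin(graph.spot_edge, eids)
        shared_edges = [e for e in eids if edge_use[e] > 1]
        shared = np.isin(graph.spot_edge, shared_edges) & on_branch
        branches.append(BranchTrajectory(bid, leaf, path, on_branch, shared))
    return branches


def map_pseudotime_spatial(assignment: PseudotimeAssignment,
                           positions: pd.DataFrame,
                           branch: BranchTrajectory) -> pd.DataFrame:
    """(x, y, pseudotime) for the branch's member spots; no interpolation."""
    if len(positions) != len(assignment.pseudotime):
        raise ValueError("positions not aligned to pseudotime assignment")
    m = branch.spot_mask
    return pd.DataFrame({
        "x_px": positions["x_px"].to_numpy()[m],
        "y_px": positions["y_px"].to_numpy()[m],
        "pseudotime": assignment.pseudotime[m],
        "shared": branch.shared[m],
    }, index=positions.index[m])


def expression_along_pseudotime(normalized: NormalizedMatrix,
                                assignment: PseudotimeAssignment, genes,
                                n_windows: int = 20,
                                spot_mask=None) -> pd.DataFrame:
    """Per-gene window means (+/- sd) along equal-count pseudotime windows."""
    pt = assignment.pseudotime
    mask = np.ones(len(pt), dtype=bool) if spot_mask is None else \
        np.asarray(spot_mask)
    if mask.sum() == 0:
        raise ValueError("empty spot selection")
    idx = normalized.gene_index(list(genes))
    X = np.asarray(normalized.matrix[idx][:, mask].todense())
    order = np.argsort(pt[mask], kind="stable")
    n = order.size
    n_windows = min(n_windows, n)
    bounds = np.linspace(0, n, n_windows + 1).astype(int)
    rows = []
    for w in range(n_windows):
        sel = order[bounds[w]:bounds[w + 1]]
        if sel.size == 0:
            continue
        for gi, g in zip(range(len(idx)), genes):
            vals = X[gi, sel]
            rows.append({
                "gene": g, "window": w,
                "pseudotime_mid": float(np.median(pt[mask][sel])),
                "mean": float(vals.mean()), "sd": float(vals.std(ddof=0)),
                "n": int(sel.size),
            })
    return pd.DataFrame(rows)


def rank_branches_by_gene(normalized: NormalizedMatrix, branches,
                          gene: str) -> pd.DataFrame:
    """Helper for reporting: rank branches by mean expression of a gene."""
    vals = normalized.gene_values(gene)
    rows = [{"branch_id": b.branch_id, "leaf": b.leaf,
             "mean_expression": float(vals[b.spot_mask].mean())
             if b.spot_mask.any() else np.nan}
            for b in branches]
    return pd.DataFrame(rows).sort_values("mean_expression",
                                          ascending=False).reset_index(drop=True)
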
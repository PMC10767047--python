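"""Normalization, feature selection, embedding, clustering, markers, QC.

The stage mirrors the standard spot-clustering recipe for Visium-style
data: per-spot log-normalization (scale factor 10,000, natural log),
vst-style highly-variable-gene selection (n = 2,000), covariate
regression + z-scoring, PCA on the top 30 components, a shared-nearest-
neighbor graph and Louvain community detection at resolution 0.2, one-vs-
rest Wilcoxon cluster markers, and a per-gene-average Pearson correlation
between replicate samples as a reproducibility check.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import igraph as ig
import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.stats import mannwhitneyu
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors
from statsmodels.nonparametric.smoothers_lowess import lowess

from .diffexpr import bh_adjust, log_fold_change
from .io import SpotDataset


@dataclass
class NormalizedMatrix:
    """Log-normalized expression: ``ln(1 + count / spot_total * scale)``."""

    matrix: sp.csr_matrix          # genes x spots, 0 where count is 0
    gene_ids: np.ndarray
    spot_ids: np.ndarray
    scale_factor: float = 10_000.0

    @property
    def n_genes(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_spots(self) -> int:
        return self.matrix.shape[1]

    def gene_index(self, genes) -> np.ndarray:
        lookup = {g: i for i, g in enumerate(self.gene_ids)}
        missing = [g for g in genes if g not in lookup]
        if missing:
            raise KeyError(f"genes not in matrix: {missing}")
        return np.array([lookup[g] for g in genes], dtype=int)

    def gene_values(self, gene: str) -> np.ndarray:
        return np.asarray(self.matrix[self.gene_index([gene])[0]].todense()).ravel()

    def dense(self, genes=None) -> np.ndarray:
        if genes is None:
            return np.asarray(self.matrix.todense())
        return np.asarray(self.matrix[self.gene_index(genes)].todense())


def log_normalize(dataset: SpotDataset,
                  scale_factor: float = 10_000.0) -> NormalizedMatrix:
    """Per-spot log-normalization with a fixed scale factor (natural log)."""
    totals = dataset.spot_totals()
    zero = np.flatnonzero(totals == 0)
    if zero.size:
        raise ValueError(
            f"spots with zero total counts: {list(dataset.spot_ids[zero[:10]])}"
            + ("..." if zero.size > 10 else ""))
    mat = sp.csc_matrix(dataset.counts, dtype=float)
    scale = scale_factor / totals
    mat.data *= np.repeat(scale, np.diff(mat.indptr))
    mat.data = np.log1p(mat.data)
    return NormalizedMatrix(mat.tocsr(), dataset.gene_ids.copy(),
                            dataset.spot_ids.copy(), scale_factor)


def _gene_moments(counts: sp.csr_matrix):
    n = counts.shape[1]
    s1 = np.asarray(counts.sum(axis=1)).ravel()
    s2 = np.asarray(counts.multiply(counts).sum(axis=1)).ravel()
    mean = s1 / n
    var = (s2 - n * mean ** 2) / (n - 1)
    return mean, np.maximum(var, 0)


def hvg_statistics(dataset: SpotDataset, span: float = 0.3) -> pd.DataFrame:
    """vst-style standardized variance per gene.

    A locally-linear trend of log10(variance) on log10(mean) (lowess,
    ``frac=span``) predicts each gene's technical sd; counts are
    standardized with that sd, clipped at sqrt(n_spots), and the variance
    of the clipped values is the ranking statistic.  Constant genes get a
    standardized variance of 0.
    """
    counts = sp.csr_matrix(dataset.counts, dtype=float)
    n = counts.shape[1]
    mean, var = _gene_moments(counts)
    std_var = np.zeros(len(mean))
    ok = var > 0
    if ok.sum() >= 2:
        lx, ly = np.log10(mean[ok]), np.log10(var[ok])
        fit = lowess(ly, lx, frac=span, return_sorted=False)
        sd_pred = np.sqrt(10.0 ** fit)
        clip = np.sqrt(n)
        idx_ok = np.flatnonzero(ok)
        for j, g in enumerate(idx_ok):
            row = counts[g]
            vals = (row.data - mean[g]) / sd_pred[j]
            vals = np.minimum(vals, clip)
            z0 = max(-clip, min(clip, (0.0 - mean[g]) / sd_pred[j]))
            n_zero = n - row.nnz
            total = vals.sum() + n_zero * z0
            total_sq = (vals ** 2).sum() + n_zero * z0 ** 2
            std_var[g] = (total_sq - total ** 2 / n) / (n - 1)
    return pd.DataFrame({
        "gene": dataset.gene_ids, "mean": mean, "variance": var,
        "variance_standardized": std_var,
    }).sort_values("variance_standardized", ascending=False,
                   kind="stable").reset_index(drop=True)


def select_hvg_vst(dataset: SpotDataset, n: int = 2000,
                   span: float = 0.3) -> np.ndarray:
    """Top ``n`` highly-variable genes, ranked by standardized variance."""
    if n < 1:
        raise ValueError("n must be >= 1")
    stats = hvg_statistics(dataset, span=span)
    informative = stats[stats["variance_standardized"] > 0]
    if len(informative) < n:
        warnings.warn(
            f"only {len(informative)} genes with nonzero standardized "
            f"variance; returning those instead of {n}")
        return informative["gene"].to_numpy()
    return stats["gene"].to_numpy()[:n]


def spot_covariates(dataset: SpotDataset,
                    mito_prefix: str = "mt-") -> dict:
    """Default regression covariates: total counts and mito fraction."""
    totals = dataset.spot_totals().astype(float)
    mito = np.array([g.startswith(mito_prefix) for g in dataset.gene_ids])
    if mito.any():
        mito_counts = np.asarray(dataset.counts[mito].sum(axis=0)).ravel()
        frac = mito_counts / np.maximum(totals, 1)
    else:
        frac = np.zeros(dataset.n_spots)
    return {"total_counts": totals, "mito_fraction": frac}


def scale_and_regress(matrix, covariates: dict | None = None,
                      clip: float = 10.0) -> np.ndarray:
    """Residualize each gene on covariates, then z-score and clip.

    ``matrix`` is genes x spots (dense or sparse).  Covariates are
    residualized by least squares (with intercept); z-scoring uses the
    population sd (ddof 0); values are clipped at +-``clip``.  Constant
    covariates are dropped with a warning; genes with zero residual
    variance come back as all-zero rows.
    """
    X = np.asarray(matrix.todense() if sp.issparse(matrix) else matrix,
                   dtype=float)
    n_spots = X.shape[1]
    cols = [np.ones(n_spots)]
    if covariates:
        for name, values in covariates.items():
            v = np.asarray(values, dtype=float)
            if not np.all(np.isfinite(v)):
                raise ValueError(f"covariate {name!r} has non-finite values")
            if np.ptp(v) == 0:
                warnings.warn(f"covariate {name!r} is constant; dropped")
                continue
            cols.append(v)
    D = np.column_stack(cols)
    # residuals = X (I - D D^+)^T, computed without forming the hat matrix
    pinv = np.linalg.pinv(D)
    resid = X - (X @ pinv.T) @ D.T
    mu = resid.mean(axis=1, keepdims=True)
    sd = resid.std(axis=1, ddof=0, keepdims=True)
    flat = sd.ravel() <= 1e-12
    sd[flat.reshape(sd.shape)] = 1.0
    Z = (resid - mu) / sd
    Z[flat] = 0.0
    return np.clip(Z, -clip, clip)


@dataclass
class PCAEmbedding:
    scores: np.ndarray            # spots x n_pcs
    loadings: np.ndarray          # genes x n_pcs
    explained_variance_ratio: np.ndarray


def embed_pca(scaled: np.ndarray, n_pcs: int = 30,
              random_state: int = 0) -> PCAEmbedding:
    """PCA over spots with a fixed sign convention.

    ``scaled`` is genes x spots.  Components are ordered by decreasing
    explained variance and each is flipped so the gene with the largest
    absolute loading has a positive loading.
    """
    scaled = np.asarray(scaled)
    n_genes, n_spots = scaled.shape
    if n_pcs > min(n_genes, n_spots):
        raise ValueError(
            f"n_pcs={n_pcs} exceeds min(n_genes={n_genes}, n_spots={n_spots})")
    pca = PCA(n_components=n_pcs, svd_solver="randomized",
              random_state=random_state)
    scores = pca.fit_transform(scaled.T)
    loadings = pca.components_.T
    for j in range(n_pcs):
        top = np.argmax(np.abs(loadings[:, j]))
        if loadings[top, j] < 0:
            loadings[:, j] *= -1
            scores[:, j] *= -1
    return PCAEmbedding(scores, loadings, pca.explained_variance_ratio_)


@dataclass
class ClusterResult:
    labels: np.ndarray
    resolution: float
    n_pcs: int
    k_neighbors: int
    hvg: np.ndarray | None = None
    covariates_regressed: list = field(default_factory=list)

    @property
    def n_clusters(self) -> int:
        return int(self.labels.max()) + 1


def snn_graph(embedding: np.ndarray, k_neighbors: int = 20,
              prune: float = 1 / 15) -> sp.csr_matrix:
    """Shared-nearest-neighbor graph with Jaccard edge weights."""
    n = embedding.shape[0]
    if k_neighbors >= n:
        raise ValueError(f"k_neighbors={k_neighbors} must be < n_spots={n}")
    nn = NearestNeighbors(n_neighbors=k_neighbors + 1).fit(embedding)
    _, idx = nn.kneighbors(embedding)
    rows = np.repeat(np.arange(n), k_neighbors + 1)
    A = sp.csr_matrix((np.ones(rows.size), (rows, idx.ravel())), shape=(n, n))
    inter = (A @ A.T).tocoo()
    k = k_neighbors + 1
    jac = inter.data / (2 * k - inter.data)
    keep = (jac >= prune) & (inter.row != inter.col)
    W = sp.csr_matrix((jac[keep], (inter.row[keep], inter.col[keep])),
                      shape=(n, n))
    return W.maximum(W.T)


def cluster_spots(embedding, k_neighbors: int = 20, resolution: float = 0.2,
                  seed: int = 0, prune: float = 1 / 15) -> ClusterResult:
    """Louvain communities on the SNN graph, size-ranked labels from 0.

    Determinism contract: the vertex order is shuffled by ``seed`` before
    community detection and final labels are relabeled by decreasing
    cluster size (ties by first occurrence), so a fixed seed gives
    bit-identical labels.
    """
    scores = embedding.scores if isinstance(embedding, PCAEmbedding) else \
        np.asarray(embedding)
    n = scores.shape[0]
    W = snn_graph(scores, k_neighbors=k_neighbors, prune=prune)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    inv = np.empty(n, dtype=int)
    inv[perm] = np.arange(n)
    Wp = W[perm][:, perm].tocoo()
    upper = Wp.row < Wp.col
    g = ig.Graph(n=n, edges=list(zip(Wp.row[upper], Wp.col[upper])),
                 edge_attrs={"weight": Wp.data[upper]})
    part = g.community_multilevel(weights="weight", resolution=resolution)
    labels_perm = np.asarray(part.membership)
    labels = labels_perm[inv]
    order = pd.Series(labels).value_counts(sort=True).index.to_numpy()
    remap = {old: new for new, old in enumerate(order)}
    labels = np.array([remap[v] for v in labels])
    return ClusterResult(labels, resolution, scores.shape[1], k_neighbors)


def wilcoxon_rank_sum(a, b, method: str = "auto"):
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) p-value."""
    res = mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.pvalue)


def find_all_markers(normalized: NormalizedMatrix, clusters: np.ndarray,
                     min_logfc: float = 0.3, alpha: float = 0.05,
                     min_spots: int = 3) -> pd.DataFrame:
    """One-vs-rest Wilcoxon markers per cluster.

    Returns the retained markers (BH-adjusted p < ``alpha`` and
    logFC > ``min_logfc``, upregulated only) with columns
    ``cluster, gene, logfc, p, p_adj, pct_in, pct_out``.
    """
    clusters = np.asarray(clusters)
    uniq = np.unique(clusters)
    if len(uniq) < 2:
        raise ValueError("need >= 2 clusters to find markers")
    X = normalized.dense()
    detected = X > 0
    frames = []
    for c in uniq:
        mask = clusters == c
        if mask.sum() < min_spots:
            warnings.warn(f"cluster {c} has < {min_spots} spots; skipped")
            continue
        a, b = X[:, mask], X[:, ~mask]
        with np.errstate(all="ignore"):
            res = mannwhitneyu(a, b, alternative="two-sided",
                               method="asymptotic", axis=1)
        p = np.where(np.isnan(res.pvalue), 1.0, res.pvalue)
        lfc = log_fold_change(normalized, mask, ~mask)
        frames.append(pd.DataFrame({
            "cluster": c, "gene": normalized.gene_ids, "logfc": lfc,
            "p": p, "p_adj": bh_adjust(p),
            "pct_in": detected[:, mask].mean(axis=1),
            "pct_out": detected[:, ~mask].mean(axis=1),
        }))
    table = pd.concat(frames, ignore_index=True)
    keep = (table["p_adj"] < alpha) & (table["logfc"] > min_logfc)
    return table[keep].sort_values(["cluster", "logfc"],
                                   ascending=[True, False]).reset_index(drop=True)


def replicate_correlation(normalized: NormalizedMatrix,
                          sample_labels, sample_pairs) -> pd.Series:
    """Pearson r of per-gene average log-normalized expression per pair."""
    if normalized.n_genes < 2:
        raise ValueError("need >= 2 genes for a correlation")
    sample_labels = np.asarray(sample_labels)
    means = {}
    out = {}
    for s1, s2 in sample_pairs:
        for s in (s1, s2):
            if s not in means:
                mask = sample_labels == s
                if not mask.any():
                    raise ValueError(f"sample {s!r} has no spots")
                means[s] = np.asarray(
                    normalized.matrix[:, mask].mean(axis=1)).ravel()
        out[(s1, s2)] = float(np.corrcoef(means[s1], means[s2])[0, 1])
    return pd.Series(out)


def cluster_pipeline(dataset: SpotDataset, *, n_hvg: int = 2000,
                     n_pcs: int = 30, resolution: float = 0.2,
                     k_neighbors: int = 20, seed: int = 0,
                     covariates: dict | None = None):
    """Normalize -> HVG -> scale/regress -> PCA -> Louvain, in one call.

    Returns ``(cluster_result, embedding, normalized)``.  Covariates
    default to total counts and mitochondrial fraction.
    """
    norm = log_normalize(dataset)
    hvg = select_hvg_vst(dataset, n=min(n_hvg, dataset.n_genes))
    if covariates is None:
        covariates = spot_covariates(dataset)
    scaled = scale_and_regress(norm.matrix[norm.gene_index(hvg)], covariates)
    emb = embed_pca(scaled, n_pcs=min(n_pcs, len(hvg)))
    res = cluster_spots(emb, k_neighbors=k_neighbors, resolution=resolution,
                        seed=seed)
    res.hvg = np.asarray(hvg)
    res.covariates_regressed = list(covariates)
    return res, emb, norm


def annotate_clusters(cluster_labels, region_labels) -> dict:
    """Majority ground-truth region per cluster (synthetic-data analog of
    visual atlas annotation)."""
    df = pd.DataFrame({"cluster": cluster_labels, "region": region_labels})
    return {int(c): grp["region"].mode().iloc[0]
            for c, grp in df.groupby("cluster")}


def cluster_region_masks(cluster_labels, annotation: dict) -> dict:
    """Region -> boolean spot mask, pooling clusters with that annotation."""
    cluster_labels = np.asarray(cluster_labels)
    masks: dict = {}
    for c, region in annotation.items():
        m = cluster_labels == c
        masks[region] = masks.get(region, np.zeros_like(m)) | m
    return masks
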
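"""Binned-control module scores for DAM/DAA (and arbitrary) gene sets.

The score follows the standard binned-control recipe: genes are binned by
their average log-normalized expression (equal-frequency bins), each
signature gene draws ``n_ctrl`` control genes from its own bin, and the
per-spot score is the mean expression of the signature genes minus the
mean expression of the drawn controls.  This centres the score against
expression-matched background so that a constant matrix scores exactly 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .preprocess import NormalizedMatrix

DAM_SIGNATURE = ["Lpl", "Cst7", "Axl", "Itgax", "Spp1", "Cd9", "Ccl6", "Csf1"]
DAA_SIGNATURE = ["Ggta1", "Gsn", "Osmr", "Vim", "Serpina3n", "Ctsb", "Gfap"]


@dataclass
class SignatureScoreTable:
    """Per-spot scores for named signatures, with the parameters used."""

    scores: pd.DataFrame           # spots x signatures
    n_bins: int
    n_ctrl: int
    seed: int
    genes_used: dict = field(default_factory=dict)

    def __getitem__(self, name: str) -> np.ndarray:
        return self.scores[name].to_numpy()


def _expression_bins(avg: np.ndarray, n_bins: int) -> np.ndarray:
    """Equal-frequency bins of average expression (stable rank cuts)."""
    order = np.argsort(avg, kind="stable")
    ranks = np.empty(avg.size, dtype=int)
    ranks[order] = np.arange(avg.size)
    return (ranks * n_bins) // avg.size


def module_score(normalized: NormalizedMatrix, gene_set, *,
                 n_bins: int = 24, n_ctrl: int = 100,
                 seed: int = 0) -> tuple[np.ndarray, list]:
    """Per-spot module score for one gene set.

    Returns ``(scores, genes_used)``.  Genes absent from the matrix are
    dropped with a warning; an empty effective set is an error.  Controls
    are sampled without replacement when the gene's bin holds at least
    ``n_ctrl`` candidates, with replacement otherwise; a fixed seed makes
    the draw (and hence the scores) exactly reproducible.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    present = set(normalized.gene_ids)
    used = [g for g in gene_set if g in present]
    missing = [g for g in gene_set if g not in present]
    if missing:
        warnings.warn(f"signature genes absent from matrix: {missing}")
    if not used:
        raise ValueError(
            f"no signature gene present in the matrix; missing: {missing}")
    X = normalized.matrix
    avg = np.asarray(X.mean(axis=1)).ravel()
    bins = _expression_bins(avg, n_bins)
    sig_idx = normalized.gene_index(used)
    sig_set = set(sig_idx)

    rng = np.random.default_rng(seed)
    control_idx = []
    for gi in sig_idx:
        pool = np.flatnonzero(bins == bins[gi])
        pool = pool[np.array([p not in sig_set for p in pool])]
        if pool.size == 0:
            pool = np.flatnonzero(bins == bins[gi])
        replace = pool.size < n_ctrl
        control_idx.append(rng.choice(pool, size=n_ctrl, replace=replace))
    control_idx = np.concatenate(control_idx)

    sig_mean = np.asarray(X[sig_idx].mean(axis=0)).ravel()
    ctrl_mean = np.asarray(X[control_idx].mean(axis=0)).ravel()
    return sig_mean - ctrl_mean, used


def score_signatures(normalized: NormalizedMatrix, gene_sets: dict, *,
                     n_bins: int = 24, n_ctrl: int = 100,
                     seed: int = 0) -> SignatureScoreTable:
    """Score several named gene sets (e.g. DAMscore, DAAscore) per spot."""
    scores, used = {}, {}
    for k, (name, genes) in enumerate(gene_sets.items()):
        s, g = module_score(normalized, genes, n_bins=n_bins, n_ctrl=n_ctrl,
                            seed=seed + k)
        scores[name] = s
        used[name] = g
    table = pd.DataFrame(scores, index=pd.Index(normalized.spot_ids,
                                                name="barcode"))
    return SignatureScoreTable(table, n_bins, n_ctrl, seed, used)


def _tie_safe_wilcoxon(a: np.ndarray, b: np.ndarray) -> float:
    from scipy.stats import mannwhitneyu
    if a.size == 0 or b.size == 0:
        return float("nan")
    if np.ptp(np.concatenate([a, b])) == 0:
        return 1.0  # all values tied: no evidence of a shift
    return float(mannwhitneyu(a, b, alternative="two-sided",
                              method="asymptotic").pvalue)


def score_by_group(scores: np.ndarray, cluster_labels, genotype_labels,
                   age_labels, *, contrast=("AD", "WT")) -> pd.DataFrame:
    """Summarize a score per (cluster, genotype, age) and test AD vs WT.

    Returns one row per (cluster, age) with group means/medians/sizes, the
    mean difference, and a two-sided Wilcoxon p-value between genotypes.
    """
    df = pd.DataFrame({
        "score": np.asarray(scores, dtype=float),
        "cluster": np.asarray(cluster_labels),
        "genotype": np.asarray(genotype_labels),
        "age": np.asarray(age_labels),
    })
    rows = []
    for (cluster, age), grp in df.groupby(["cluster", "age"], sort=True):
        a = grp.loc[grp["genotype"] == contrast[0], "score"].to_numpy()
        b = grp.loc[grp["genotype"] == contrast[1], "score"].to_numpy()
        rows.append({
            "cluster": cluster, "age": age,
            f"mean_{contrast[0]}": a.mean() if a.size else np.nan,
            f"mean_{contrast[1]}": b.mean() if b.size else np.nan,
            f"median_{contrast[0]}": np.median(a) if a.size else np.nan,
            f"median_{contrast[1]}": np.median(b) if b.size else np.nan,
            f"n_{contrast[0]}": a.size, f"n_{contrast[1]}": b.size,
            "mean_diff": (a.mean() - b.mean())
                         if a.size and b.size else np.nan,
            "wilcoxon_p": _tie_safe_wilcoxon(a, b),
        })
    return pd.DataFrame(rows)


def map_scores_spatial(scores, positions: pd.DataFrame) -> pd.DataFrame:
    """Export (x, y, score) per spot for spatial plotting; no smoothing."""
    scores = np.asarray(scores, dtype=float)
    if len(scores) != len(positions):
        raise ValueError(
            f"{len(scores)} scores for {len(positions)} positions")
    return pd.DataFrame({
        "x_px": positions["x_px"].to_numpy(),
        "y_px": positions["y_px"].to_numpy(),
        "score": scores,
    }, index=positions.index)
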
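"""Downstream analyses on trained embeddings and enhanced expression.

Covers: denoised-expression export, embedding clustering, the adjusted Rand
index computed from the contingency table, one-vs-rest marker-gene (DEG)
ranking with Benjamini–Hochberg correction, paired raw-vs-enhanced
comparison tests, and 2-D UMAP projection.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import comb
from scipy.stats import ranksums, ttest_rel

from .data import SpatialCellDataset
from .features import FeatureMatrix
from .graph import SpatialGraph
from .model import HybridGraphNetwork

__all__ = [
    "ContingencyTable",
    "DEGTable",
    "enhance_expression",
    "cluster_embeddings",
    "contingency",
    "adjusted_rand_index",
    "rank_genes",
    "compare_raw_enhanced",
    "project_2d",
]


# --------------------------------------------------------------------------
# partition agreement
# --------------------------------------------------------------------------
@dataclass
class ContingencyTable:
    """Cross-tabulation n_ij of two labelings of the same cells."""

    counts: np.ndarray  # K_A x K_B integers
    row_sums: np.ndarray  # a_i
    col_sums: np.ndarray  # b_j
    n: int


def contingency(labels_a, labels_b) -> ContingencyTable:
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError(f"label vectors must be equal-length 1-D, got {a.shape} vs {b.shape}")
    _, ai = np.unique(a, return_inverse=True)
    _, bi = np.unique(b, return_inverse=True)
    counts = np.zeros((ai.max() + 1, bi.max() + 1), dtype=int)
    np.add.at(counts, (ai, bi), 1)
    return ContingencyTable(
        counts=counts,
        row_sums=counts.sum(axis=1),
        col_sums=counts.sum(axis=0),
        n=int(a.size),
    )


def adjusted_rand_index(labels_a, labels_b) -> float:
    """Chance-corrected partition agreement via pair counts:

        ARI = [Σ_ij C(n_ij,2) − Σ_i C(a_i,2) Σ_j C(b_j,2)/C(n,2)] /
              [½(Σ_i C(a_i,2) + Σ_j C(b_j,2)) − Σ_i C(a_i,2) Σ_j C(b_j,2)/C(n,2)]

    Equals 1 for identical partitions, ~0 for random agreement; symmetric
    and invariant to label renaming. Requires n >= 2.
    """
    table = contingency(labels_a, labels_b)
    if table.n < 2:
        raise ValueError("ARI needs at least 2 samples (no pairs otherwise)")
    sum_ij = comb(table.counts, 2).sum()
    sum_a = comb(table.row_sums, 2).sum()
    sum_b = comb(table.col_sums, 2).sum()
    pairs = comb(table.n, 2)
    expected = sum_a * sum_b / pairs
    max_index = 0.5 * (sum_a + sum_b)
    if max_index == expected:  # both partitions trivial (all-singletons/all-one)
        return 1.0 if sum_ij == max_index else 0.0
    return float((sum_ij - expected) / (max_index - expected))


# --------------------------------------------------------------------------
# clustering & projection
# --------------------------------------------------------------------------
def cluster_embeddings(
    Z: np.ndarray, k: int, seed: int = 0, method: str = "gmm"
) -> np.ndarray:
    """Partition cells into k clusters from an embedding matrix.

    Default is a Gaussian mixture with tied covariance (the mclust-EEE model
    standard in spatial-domain benchmarking) with k set to the number of
    annotated classes; ``method="gmm_full"``, ``"gmm_diag"`` and ``"kmeans"``
    are also available. Deterministic for a fixed seed.
    """
    Z = np.asarray(Z, dtype=float)
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > Z.shape[0]:
        raise ValueError(f"k={k} exceeds number of cells {Z.shape[0]}")
    if k == 1:
        return np.zeros(Z.shape[0], dtype=int)
    if method in ("gmm", "gmm_full", "gmm_diag"):
        from sklearn.mixture import GaussianMixture

        cov = {"gmm": "tied", "gmm_full": "full", "gmm_diag": "diag"}[method]
        gm = GaussianMixture(
            n_components=k, covariance_type=cov, n_init=5,
            random_state=seed, reg_covar=1e-5,
        )
        return gm.fit_predict(Z).astype(int)
    if method == "kmeans":
        from sklearn.cluster import KMeans

        km = KMeans(n_clusters=k, n_init=10, random_state=seed)
        return km.fit_predict(Z).astype(int)
    raise ValueError(f"unknown clustering method {method!r}")


def project_2d(Z: np.ndarray, seed: int = 0) -> np.ndarray:
    """Seeded 2-D UMAP of an embedding for visual inspection."""
    Z = np.asarray(Z, dtype=float)
    if Z.shape[0] < 10:
        raise ValueError("project_2d needs at least 10 cells")
    import umap

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # umap warns that a fixed seed disables parallelism
        reducer = umap.UMAP(n_components=2, random_state=seed)
        return np.asarray(reducer.fit_transform(Z), dtype=float)


# --------------------------------------------------------------------------
# enhanced expression
# --------------------------------------------------------------------------
def enhance_expression(
    network: HybridGraphNetwork,
    params,
    dataset: SpatialCellDataset,
    features: FeatureMatrix,
    graph: SpatialGraph,
    layer: str = "norm",
) -> np.ndarray:
    """Denoised expression: the hybrid decoder's reconstruction, clipped
    below at 0 (normalized-log expression is non-negative), stored as layer
    ``"enhanced"``."""
    if layer not in dataset.layers:
        raise KeyError(f"dataset has no layer {layer!r}; run preprocessing first")
    X = dataset.layers[layer]
    if X.shape[1] != network.config.gene_dim:
        raise ValueError(
            f"dataset has {X.shape[1]} genes but checkpoint config expects "
            f"{network.config.gene_dim}"
        )
    bundle = network.forward(X, features.values, graph, params)
    enhanced = np.clip(bundle.recon_hyb, 0.0, None)
    dataset.layers["enhanced"] = enhanced
    return enhanced


# --------------------------------------------------------------------------
# marker genes / DEGs
# --------------------------------------------------------------------------
@dataclass
class DEGTable:
    """Per-(cluster, gene) differential expression results.

    ``table`` columns: cluster, gene, log2fc, statistic, pval, padj, is_deg;
    sorted by adjusted p within cluster. ``deg_counts`` maps cluster ->
    number of genes passing both thresholds.
    """

    table: pd.DataFrame
    deg_counts: dict
    alpha: float
    lfc_min: float


def rank_genes(
    X: np.ndarray,
    labels,
    gene_names: list[str] | None = None,
    alpha: float = 0.05,
    lfc_min: float = 0.25,
) -> DEGTable:
    """One-vs-rest two-sided Wilcoxon rank-sum test per (cluster, gene), with
    Benjamini–Hochberg adjustment within each cluster's family.

    A DEG has adjusted p < ``alpha`` and |log2 fold change| >= ``lfc_min``.
    Fold changes are computed scanpy-style on expm1 of the (log-scale) layer
    means. Clusters with < 2 cells are skipped with a warning.
    """
    from statsmodels.stats.multitest import multipletests

    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    clusters = np.unique(labels)
    if len(clusters) < 2:
        raise ValueError("rank_genes needs at least 2 clusters")
    if gene_names is None:
        gene_names = [f"gene_{i}" for i in range(X.shape[1])]
    rows = []
    deg_counts: dict = {}
    for c in clusters:
        mask = labels == c
        if mask.sum() < 2:
            warnings.warn(f"cluster {c!r} has < 2 cells; skipped", stacklevel=2)
            continue
        X_in, X_out = X[mask], X[~mask]
        stat, pval = ranksums(X_in, X_out, axis=0)
        mean_in = np.expm1(X_in.mean(axis=0))
        mean_out = np.expm1(X_out.mean(axis=0))
        log2fc = np.log2((mean_in + 1e-9) / (mean_out + 1e-9))
        _, padj, _, _ = multipletests(pval, method="fdr_bh")
        is_deg = (padj < alpha) & (np.abs(log2fc) >= lfc_min)
        df = pd.DataFrame(
            {
                "cluster": c,
                "gene": gene_names,
                "log2fc": log2fc,
                "statistic": stat,
                "pval": pval,
                "padj": padj,
                "is_deg": is_deg,
            }
        ).sort_values("padj", kind="stable")
        deg_counts[c] = int(is_deg.sum())
        rows.append(df)
    table = pd.concat(rows, ignore_index=True)
    return DEGTable(table=table, deg_counts=deg_counts, alpha=alpha, lfc_min=lfc_min)


# --------------------------------------------------------------------------
# raw vs enhanced comparison
# --------------------------------------------------------------------------
def compare_raw_enhanced(
    raw: np.ndarray,
    enhanced: np.ndarray,
    region_mask: np.ndarray | None = None,
) -> dict:
    """Paired two-sided t-test of (enhanced − raw) over the selected cells.

    Returns ``{"t", "p", "direction"}`` with direction the sign of the mean
    difference ("up", "down", "none"). When the paired differences have zero
    variance but nonzero mean (an exact shift), p is reported as the
    smallest positive float rather than failing.
    """
    raw = np.asarray(raw, dtype=float)
    enhanced = np.asarray(enhanced, dtype=float)
    if raw.shape != enhanced.shape:
        raise ValueError("raw and enhanced must have equal length")
    if region_mask is not None:
        region_mask = np.asarray(region_mask, dtype=bool)
        raw, enhanced = raw[region_mask], enhanced[region_mask]
    if raw.size < 3:
        raise ValueError("need at least 3 selected cells for a paired t-test")
    diff = enhanced - raw
    mean_diff = float(diff.mean())
    direction = "up" if mean_diff > 0 else ("down" if mean_diff < 0 else "none")
    if np.allclose(diff, diff[0]):
        if mean_diff == 0.0:
            return {"t": 0.0, "p": 1.0, "direction": "none"}
        t = np.inf if mean_diff > 0 else -np.inf
        return {"t": float(t), "p": float(np.nextafter(0.0, 1.0)), "direction": direction}
    res = ttest_rel(enhanced, raw)
    return {"t": float(res.statistic), "p": float(res.pvalue), "direction": direction}
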
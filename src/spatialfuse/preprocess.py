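"""Expression preprocessing: gene-name deduplication, per-cell total-count
normalization, and natural-log transform.

Pipeline order is fixed: dedup -> normalize_total -> log1p. The composed
transform is monotone within each cell, so within-cell rank order of
expression values is preserved.
"""

from __future__ import annotations

import numpy as np

from .data import SpatialCellDataset

__all__ = ["make_names_unique", "normalize_total", "log1p", "preprocess_dataset"]


def make_names_unique(names: list[str]) -> list[str]:
    """Deduplicate names: first occurrence unchanged, k-th duplicate (k >= 2)
    suffixed ``-(k-1)``; if a suffixed candidate collides with a name already
    present, the counter keeps advancing until the result is free."""
    seen: set[str] = set()
    counts: dict[str, int] = {}
    incoming = set(names)
    out: list[str] = []
    for name in names:
        if name not in seen and (counts.get(name, 0) == 0):
            out.append(name)
            seen.add(name)
            counts[name] = 1
            continue
        k = counts.get(name, 1)
        candidate = f"{name}-{k}"
        while candidate in seen or candidate in incoming:
            k += 1
            candidate = f"{name}-{k}"
        counts[name] = k + 1
        out.append(candidate)
        seen.add(candidate)
    return out


def normalize_total(X: np.ndarray, target_sum: float = 10_000.0) -> np.ndarray:
    """Scale each cell (row) to a common total count ``target_sum``.

    Rows summing to zero are left all-zero. Idempotent.
    """
    X = np.asarray(X, dtype=float)
    if np.any(X < 0):
        raise ValueError("normalize_total requires a non-negative matrix")
    if target_sum <= 0:
        raise ValueError("target_sum must be positive")
    sums = X.sum(axis=1, keepdims=True)
    scale = np.divide(target_sum, sums, out=np.ones_like(sums), where=sums > 0)
    return X * scale


def log1p(X: np.ndarray) -> np.ndarray:
    """Elementwise natural log(1 + x); requires x >= 0."""
    X = np.asarray(X, dtype=float)
    if np.any(X < 0):
        raise ValueError("log1p requires a non-negative matrix")
    return np.log1p(X)


def preprocess_dataset(
    dataset: SpatialCellDataset,
    target_sum: float = 10_000.0,
    hvg_top_k: int | None = None,
) -> SpatialCellDataset:
    """Apply the full preprocessing chain in place, writing layer ``"norm"``.

    Gene names are deduplicated, each cell scaled to ``target_sum`` total,
    then log1p-transformed. ``hvg_top_k`` optionally subsets the dataset to
    the top-k genes by variance of the normalized layer (off by default).
    """
    dataset.gene_names = make_names_unique(dataset.gene_names)
    norm = log1p(normalize_total(dataset.expression, target_sum))
    if hvg_top_k is not None and hvg_top_k < norm.shape[1]:
        order = np.argsort(norm.var(axis=0))[::-1][:hvg_top_k]
        order = np.sort(order)
        dataset.expression = dataset.expression[:, order]
        dataset.gene_names = [dataset.gene_names[i] for i in order]
        for k in list(dataset.layers):
            dataset.layers[k] = dataset.layers[k][:, order]
        norm = norm[:, order]
    dataset.layers["norm"] = norm
    return dataset
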
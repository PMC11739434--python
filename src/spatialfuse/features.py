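"""Per-cell image feature extraction behind a pluggable extractor protocol.

Large pretrained pathology foundation models (CTransPath/UNI-class backbones)
are external integration points: their embeddings enter through
:func:`load_precomputed_features`. The built-in extractor is a deterministic,
training-free color/texture summarizer sufficient for coarse morphology
signal: per-channel intensity histograms on a spatial grid, channel
mean/std, and a gradient-magnitude histogram.

Feature columns are standardized (zero mean, unit variance across cells)
before entering the fusion model; see :func:`standardize_features`.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Protocol, runtime_checkable

import numpy as np
import pandas as pd

from .data import PatchSet, SpatialCellDataset

__all__ = [
    "FeatureExtractor",
    "FeatureMatrix",
    "BuiltinTextureExtractor",
    "builtin_texture_features",
    "extract_features",
    "standardize_features",
    "load_precomputed_features",
    "save_features",
]

_GRAD_MAX = 255.0 * np.sqrt(2.0)  # upper bound of the gradient-magnitude range


@runtime_checkable
class FeatureExtractor(Protocol):
    """Anything that maps a batch of patches to fixed-width feature rows."""

    name: str
    dim: int

    def extract_batch(self, patches: np.ndarray) -> np.ndarray:  # (b,3,S,S) -> (b,dim)
        ...


@dataclass
class FeatureMatrix:
    """cells x dim image feature matrix aligned to the dataset cell axis."""

    values: np.ndarray
    extractor_name: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature matrix contains non-finite entries")


def builtin_texture_features(patch: np.ndarray, n_bins: int = 16, grid: int = 3) -> np.ndarray:
    """Deterministic color/texture descriptor of one (3, S, S) patch.

    Concatenates, in order:
      a) per-channel intensity histograms (``n_bins`` bins over [0, 256)) on a
         ``grid x grid`` spatial partition, each histogram normalized to sum 1;
      b) per-channel mean and std, scaled to [0, 1];
      c) a gradient-magnitude histogram of the grayscale patch (``n_bins``
         bins over [0, 255*sqrt 2]), normalized to sum 1.

    Output dim = 3*n_bins*grid^2 + 6 + n_bins.
    """
    patch = np.asarray(patch, dtype=float)
    if patch.ndim != 3 or patch.shape[0] != 3:
        raise ValueError(f"expected (3, S, S) patch, got {patch.shape}")
    S = patch.shape[1]
    edges = np.linspace(0.0, 256.0, n_bins + 1)
    cuts = [np.array_split(np.arange(S), grid)[g] for g in range(grid)]
    parts: list[np.ndarray] = []
    for c in range(3):
        for gy in range(grid):
            for gx in range(grid):
                block = patch[c][np.ix_(cuts[gy], cuts[gx])]
                hist, _ = np.histogram(block, bins=edges)
                total = hist.sum()
                parts.append(hist / total if total > 0 else hist.astype(float))
    means = patch.reshape(3, -1).mean(axis=1) / 255.0
    stds = patch.reshape(3, -1).std(axis=1) / 255.0
    parts.append(np.concatenate([means, stds]))
    gray = patch.mean(axis=0)
    gy, gx = np.gradient(gray)
    mag = np.hypot(gx, gy)
    ghist, _ = np.histogram(mag, bins=np.linspace(0.0, _GRAD_MAX, n_bins + 1))
    gtot = ghist.sum()
    parts.append(ghist / gtot if gtot > 0 else ghist.astype(float))
    return np.concatenate(parts)


@dataclass
class BuiltinTextureExtractor:
    """Seedless, fully deterministic built-in extractor (defaults dim 454)."""

    n_bins: int = 16
    grid: int = 3

    @property
    def name(self) -> str:
        return f"builtin-texture(n_bins={self.n_bins},grid={self.grid})"

    @property
    def dim(self) -> int:
        return 3 * self.n_bins * self.grid**2 + 6 + self.n_bins

    def extract_batch(self, patches: np.ndarray) -> np.ndarray:
        return np.stack(
            [builtin_texture_features(p, self.n_bins, self.grid) for p in patches]
        )


def extract_features(
    patches: PatchSet, extractor: FeatureExtractor, batch_size: int = 64
) -> FeatureMatrix:
    """Run the extractor over all patches in batches; batching is invisible
    in the result (batch size never changes values)."""
    n = patches.n_cells
    rows = []
    for start in range(0, n, batch_size):
        batch = patches.patches[start : start + batch_size]
        try:
            out = np.asarray(extractor.extract_batch(batch), dtype=float)
        except Exception as exc:
            raise RuntimeError(
                f"feature extraction failed on batch {start // batch_size} "
                f"(cells {start}..{min(start + batch_size, n) - 1}): {exc}"
            ) from exc
        if out.shape != (batch.shape[0], extractor.dim):
            raise ValueError(
                f"extractor returned shape {out.shape}, expected "
                f"{(batch.shape[0], extractor.dim)}"
            )
        rows.append(out)
    values = np.vstack(rows) if rows else np.zeros((0, extractor.dim))
    return FeatureMatrix(values=values, extractor_name=extractor.name)


def standardize_features(features: FeatureMatrix) -> FeatureMatrix:
    """Column z-score across cells; constant columns are set to zero."""
    V = features.values
    mu = V.mean(axis=0)
    sd = V.std(axis=0)
    out = np.where(sd > 0, (V - mu) / np.where(sd > 0, sd, 1.0), 0.0)
    return FeatureMatrix(values=out, extractor_name=features.extractor_name + "+zscore")


def save_features(features: FeatureMatrix, dataset: SpatialCellDataset, path: str | Path) -> None:
    df = pd.DataFrame(features.values, index=pd.Index(dataset.cell_ids, name="cell_id"))
    df.to_csv(path)


def load_precomputed_features(path: str | Path, dataset: SpatialCellDataset) -> FeatureMatrix:
    """Load an externally computed feature CSV keyed by cell_id and re-align
    rows to the dataset cell order. Missing cells are an error (listed)."""
    df = pd.read_csv(path, index_col=0)
    df.index = df.index.map(str)
    missing = [c for c in dataset.cell_ids if c not in df.index]
    if missing:
        shown = ", ".join(missing[:10]) + ("..." if len(missing) > 10 else "")
        raise KeyError(f"feature file {path} is missing {len(missing)} cell ids: {shown}")
    aligned = df.loc[dataset.cell_ids].to_numpy(dtype=float)
    return FeatureMatrix(values=aligned, extractor_name=f"precomputed:{Path(path).name}")
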
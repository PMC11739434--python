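"""Core containers and I/O for single-cell spatial transcriptomics data.

The central object is :class:`SpatialCellDataset`: a cells x genes expression
matrix together with per-cell pixel coordinates in the frame of a co-registered
histology image, optional per-cell annotation labels and field-of-view (FOV)
indices, and named auxiliary layers ("raw", "norm", "enhanced", ...).

Coordinate convention: ``coords[:, 0]`` is x (image column), ``coords[:, 1]``
is y (image row), 0-based pixels. Patch windows are half-open.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import mmread

__all__ = [
    "SpatialCellDataset",
    "HistologyImage",
    "PatchSet",
    "load_dataset",
    "save_dataset",
    "load_archive",
    "crop_patches",
]


class DimensionMismatchError(ValueError):
    """Raised when per-cell or per-gene arrays disagree on an axis length."""


@dataclass
class SpatialCellDataset:
    """Expression + spatial coordinates for one tissue section.

    Parameters
    ----------
    expression : ndarray, shape (n_cells, n_genes)
        Non-negative counts or normalized units. The working matrix; raw
        input is also kept in ``layers["raw"]``.
    gene_names, cell_ids : list of str
    coords : ndarray, shape (n_cells, 2)
        (x, y) pixel coordinates in the histology image frame.
    labels : optional per-cell category strings.
    fov : optional per-cell integer field-of-view IDs.
    layers : dict of named matrices, each shaped like ``expression``.
    """

    expression: np.ndarray
    gene_names: list[str]
    cell_ids: list[str]
    coords: np.ndarray
    labels: np.ndarray | None = None
    fov: np.ndarray | None = None
    layers: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.expression = np.asarray(self.expression)
        self.coords = np.asarray(self.coords, dtype=float)
        n, g = self.expression.shape
        if np.any(self.expression < 0):
            raise ValueError("expression contains negative entries")
        if len(self.gene_names) != g:
            raise DimensionMismatchError(
                f"gene axis: expression has {g} genes but {len(self.gene_names)} names"
            )
        if len(self.cell_ids) != n:
            raise DimensionMismatchError(
                f"cell axis: expression has {n} cells but {len(self.cell_ids)} cell ids"
            )
        if self.coords.shape != (n, 2):
            raise DimensionMismatchError(
                f"cell axis: expression has {n} cells but coords shape is {self.coords.shape}"
            )
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coords must be finite")
        for name, arr in [("labels", self.labels), ("fov", self.fov)]:
            if arr is not None and len(arr) != n:
                raise DimensionMismatchError(
                    f"cell axis: expression has {n} cells but {name} has {len(arr)}"
                )
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=object)
        if self.fov is not None:
            self.fov = np.asarray(self.fov, dtype=int)
        for name, mat in self.layers.items():
            if mat.shape != (n, g):
                raise DimensionMismatchError(
                    f"layer {name!r} has shape {mat.shape}, expected {(n, g)}"
                )

    @property
    def n_cells(self) -> int:
        return self.expression.shape[0]

    @property
    def n_genes(self) -> int:
        return self.expression.shape[1]


@dataclass
class HistologyImage:
    """RGB histology raster in the same pixel frame as the cell coordinates."""

    pixels: np.ndarray  # H x W x 3, uint8-valued
    pixel_size: float | None = None  # microns per pixel, optional

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError(f"expected H x W x 3 RGB array, got {self.pixels.shape}")
        if self.pixels.shape[0] < 1 or self.pixels.shape[1] < 1:
            raise ValueError("image must have H, W >= 1")
        if self.pixels.min() < 0 or self.pixels.max() > 255:
            raise ValueError("pixel values must lie in [0, 255]")

    @classmethod
    def read(cls, path: str | Path, pixel_size: float | None = None) -> "HistologyImage":
        from PIL import Image

        with Image.open(path) as im:
            arr = np.asarray(im.convert("RGB"))
        return cls(pixels=arr, pixel_size=pixel_size)

    def write(self, path: str | Path) -> None:
        from PIL import Image

        Image.fromarray(self.pixels.astype(np.uint8)).save(path)


@dataclass
class PatchSet:
    """One cell-centered RGB patch per cell, channel-first (cells, 3, S, S)."""

    patches: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.patches)
        if p.ndim != 4 or p.shape[1] != 3 or p.shape[2] != p.shape[3]:
            raise ValueError(f"expected (cells, 3, S, S), got {p.shape}")
        self.patches = p

    @property
    def n_cells(self) -> int:
        return self.patches.shape[0]

    @property
    def size(self) -> int:
        return self.patches.shape[2]


def _read_names(path: Path) -> list[str]:
    # 10x-style sidecar: one entry per line, optionally tab-separated columns
    # (features.tsv has id<TAB>name<TAB>type; we take the second column if present).
    names = []
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            names.append(parts[1] if len(parts) >= 2 else parts[0])
    return names


def _find_sidecar(mtx_path: Path, stems: tuple[str, ...]) -> Path:
    for stem in stems:
        for ext in (".tsv", ".txt", ".csv"):
            cand = mtx_path.with_name(stem + ext)
            if cand.exists():
                return cand
    raise FileNotFoundError(
        f"no sidecar file {stems} next to {mtx_path} (tried .tsv/.txt/.csv)"
    )


def _read_coords(coords_path: str | Path, cell_ids: list[str] | None) -> np.ndarray:
    df = pd.read_csv(coords_path)
    cols = {c.lower(): c for c in df.columns}
    if "x" in cols and "y" in cols:
        xy = df[[cols["x"], cols["y"]]]
    else:  # fall back to the first two non-id columns
        non_id = [c for c in df.columns if c.lower() not in ("cell_id", "barcode", "id")]
        if len(non_id) < 2:
            raise ValueError(f"coordinate file {coords_path} needs x and y columns")
        xy = df[non_id[:2]]
    coords = np.empty((len(df), 2), dtype=float)
    for i in range(len(df)):
        for j in range(2):
            try:
                coords[i, j] = float(xy.iloc[i, j])
            except (TypeError, ValueError) as exc:
                raise ValueError(
                    f"non-numeric coordinate at row {i} of {coords_path}: {xy.iloc[i, j]!r}"
                ) from exc
    return coords


def load_dataset(
    expr_path: str | Path,
    coords_path: str | Path,
    format: str = "csv",
    labels_path: str | Path | None = None,
    fov_path: str | Path | None = None,
) -> SpatialCellDataset:
    """Load a dataset from an expression matrix plus a coordinate CSV.

    ``format="mtx"``: *expr_path* is a MatrixMarket file with 10x-style
    sidecars (``genes``/``features`` and ``barcodes``) in the same directory;
    a genes x cells matrix is transposed to cells x genes using the sidecar
    lengths. ``format="csv"``: dense matrix, header row = gene names, first
    column = cell ids.
    """
    expr_path = Path(expr_path)
    if format == "mtx":
        raw = mmread(expr_path)
        mat = np.asarray(raw.toarray() if hasattr(raw, "toarray") else raw)
        genes = _read_names(_find_sidecar(expr_path, ("genes", "features")))
        cells = [
            line.split("\t")[0]
            for line in Path(_find_sidecar(expr_path, ("barcodes",))).read_text().splitlines()
        ]
        if mat.shape == (len(genes), len(cells)) and mat.shape != (len(cells), len(genes)):
            mat = mat.T
        if mat.shape != (len(cells), len(genes)):
            raise DimensionMismatchError(
                f"matrix shape {mat.shape} inconsistent with {len(genes)} genes "
                f"and {len(cells)} barcodes"
            )
        expression, gene_names, cell_ids = mat, genes, cells
    elif format == "csv":
        df = pd.read_csv(expr_path, index_col=0)
        expression = df.to_numpy()
        gene_names = [str(c) for c in df.columns]
        cell_ids = [str(i) for i in df.index]
    else:
        raise ValueError(f"unknown format {format!r}; use 'mtx' or 'csv'")

    coords = _read_coords(coords_path, cell_ids)
    if coords.shape[0] != len(cell_ids):
        raise DimensionMismatchError(
            f"cell axis: matrix has {len(cell_ids)} cells but coordinate file "
            f"{coords_path} has {coords.shape[0]} rows"
        )
    labels = None
    if labels_path is not None:
        labels = pd.read_csv(labels_path).iloc[:, -1].to_numpy(dtype=object)
    fov = None
    if fov_path is not None:
        fov = pd.read_csv(fov_path).iloc[:, -1].to_numpy(dtype=int)

    ds = SpatialCellDataset(
        expression=expression,
        gene_names=list(gene_names),
        cell_ids=list(cell_ids),
        coords=coords,
        labels=labels,
        fov=fov,
    )
    ds.layers["raw"] = ds.expression.copy()
    return ds


def save_dataset(dataset: SpatialCellDataset, path: str | Path) -> None:
    """Persist a dataset (all layers, names, coords, labels, FOV) to one
    .h5ad archive. ``load_archive(save_dataset(...))`` is identity on content."""
    import anndata as ad

    obs = pd.DataFrame(index=pd.Index(dataset.cell_ids, name="cell_id"))
    if dataset.labels is not None:
        obs["label"] = pd.Categorical([str(x) for x in dataset.labels])
    if dataset.fov is not None:
        obs["fov"] = dataset.fov
    adata = ad.AnnData(
        X=dataset.expression,
        obs=obs,
        var=pd.DataFrame(index=pd.Index(dataset.gene_names, name="gene")),
        layers={k: v for k, v in dataset.layers.items()},
        obsm={"spatial": dataset.coords},
    )
    try:
        adata.write_h5ad(Path(path))
    except OSError as exc:
        raise OSError(f"failed to write dataset archive to {path}: {exc}") from exc


def load_archive(path: str | Path) -> SpatialCellDataset:
    """Load a dataset previously written by :func:`save_dataset`."""
    import anndata as ad

    adata = ad.read_h5ad(Path(path))
    X = adata.X
    if not isinstance(X, np.ndarray):
        X = np.asarray(X.todense())
    labels = None
    if "label" in adata.obs:
        labels = adata.obs["label"].astype(str).to_numpy(dtype=object)
    fov = adata.obs["fov"].to_numpy(dtype=int) if "fov" in adata.obs else None
    ds = SpatialCellDataset(
        expression=X,
        gene_names=[str(g) for g in adata.var_names],
        cell_ids=[str(c) for c in adata.obs_names],
        coords=np.asarray(adata.obsm["spatial"], dtype=float),
        labels=labels,
        fov=fov,
    )
    for k in adata.layers.keys():
        layer = adata.layers[k]
        ds.layers[k] = np.asarray(layer.todense()) if not isinstance(layer, np.ndarray) else layer
    return ds


def _round_half_away(x: np.ndarray) -> np.ndarray:
    """Round to nearest integer, halves away from zero (locale-independent)."""
    return np.sign(x) * np.floor(np.abs(x) + 0.5)


def crop_patches(
    image: HistologyImage, dataset: SpatialCellDataset, size: int = 240
) -> PatchSet:
    """Crop one cell-centered ``size`` x ``size`` RGB patch per cell.

    Patch *i* covers the half-open pixel window
    ``[x_i - size/2, x_i + size/2) x [y_i - size/2, y_i + size/2)``;
    pixels outside the image are zero (black) padding. Non-integer
    coordinates are rounded half-away-from-zero first.
    """
    if size < 2 or size % 2 != 0:
        raise ValueError(f"patch size must be even and >= 2, got {size}")
    img = image.pixels
    H, W = img.shape[:2]
    half = size // 2
    n = dataset.n_cells
    out = np.zeros((n, 3, size, size), dtype=img.dtype)
    centers = _round_half_away(dataset.coords).astype(int)
    for i in range(n):
        cx, cy = centers[i]
        x0, x1 = cx - half, cx + half  # columns
        y0, y1 = cy - half, cy + half  # rows
        sx0, sx1 = max(x0, 0), min(x1, W)
        sy0, sy1 = max(y0, 0), min(y1, H)
        if sx0 >= sx1 or sy0 >= sy1:
            warnings.warn(
                f"cell {dataset.cell_ids[i]!r} at ({cx}, {cy}) lies entirely "
                f"outside the {H}x{W} image; its patch is all padding",
                stacklevel=2,
            )
            continue
        dest = out[i, :, sy0 - y0 : sy1 - y0, sx0 - x0 : sx1 - x0]
        dest[...] = img[sy0:sy1, sx0:sx1, :].transpose(2, 0, 1)
    return PatchSet(patches=out)
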
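"""Model/Results interface for the hybrid graph-attention autoencoder.

Follows the familiar two-object pattern: :class:`HybridGraphModel` is built
from data (a preprocessed dataset, standardized image features and a spatial
graph) and ``fit()`` returns a :class:`HybridGraphResults` carrying the
trained weights, per-epoch loss history, embeddings and diagnostics, with
``summary()``, ``enhance()``, ``cluster()`` and ``project_2d()`` hanging off
the results object.

Example
-------
>>> ds, image, truth = generate_benchmark()
>>> preprocess_dataset(ds)
>>> graph = build_radius_graph(ds.coords, radius=30)
>>> feats = standardize_features(extract_features(crop_patches(image, ds, 32),
...                                               BuiltinTextureExtractor()))
>>> model = HybridGraphModel.from_dataset(ds, feats, graph)
>>> res = model.fit(epochs=200, seed=0)
>>> labels = res.cluster(k=4, seed=0)
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .data import SpatialCellDataset
from .downstream import cluster_embeddings, enhance_expression, project_2d
from .features import FeatureMatrix
from .graph import SpatialGraph, neighbor_stats
from .model import EmbeddingBundle, HybridGraphNetwork, ModelConfig
from .training import (
    TrainConfig,
    load_checkpoint,
    save_checkpoint,
    train_network,
)

__all__ = ["HybridGraphModel", "HybridGraphResults"]


class HybridGraphModel:
    """Unfitted hybrid fusion model bound to one tissue section."""

    def __init__(
        self,
        gene_X: np.ndarray,
        img_F: np.ndarray,
        graph: SpatialGraph,
        config: ModelConfig | None = None,
        dataset: SpatialCellDataset | None = None,
        features: FeatureMatrix | None = None,
        **config_kwargs,
    ):
        gene_X = np.asarray(gene_X, dtype=float)
        img_F = np.asarray(img_F, dtype=float)
        if config is None:
            config = ModelConfig(gene_dim=gene_X.shape[1], img_dim=img_F.shape[1], **config_kwargs)
        self.gene_X, self.img_F, self.graph = gene_X, img_F, graph
        self.config = config
        self.dataset, self.features = dataset, features
        self.network = HybridGraphNetwork(config)

    @classmethod
    def from_dataset(
        cls,
        dataset: SpatialCellDataset,
        features: FeatureMatrix,
        graph: SpatialGraph,
        layer: str = "norm",
        **config_kwargs,
    ) -> "HybridGraphModel":
        """Build from a preprocessed dataset (layer ``"norm"`` present) and
        standardized image features."""
        if layer not in dataset.layers:
            raise KeyError(f"dataset has no layer {layer!r}; run preprocess_dataset first")
        return cls(
            gene_X=dataset.layers[layer],
            img_F=features.values,
            graph=graph,
            dataset=dataset,
            features=features,
            **config_kwargs,
        )

    def fit(self, train_config: TrainConfig | None = None, **kwargs) -> "HybridGraphResults":
        """Train with the published recipe (Adam lr 1e-3, wd 1e-4, clip 5,
        1,000 epochs by default; override via kwargs, e.g. epochs=200)."""
        if train_config is None:
            train_config = TrainConfig(**kwargs)
        out = train_network(
            self.network, self.gene_X, self.img_F, self.gene_X, self.graph, train_config
        )
        return HybridGraphResults(self, out.params, out.history, out.grad_norms, train_config)


@dataclass
class HybridGraphResults:
    """Fitted model: weights, loss history, embeddings and diagnostics."""

    model: HybridGraphModel
    params: dict
    loss_history: list
    grad_norms: list
    train_config: TrainConfig

    _bundle_cache: EmbeddingBundle | None = None

    @property
    def bundle(self) -> EmbeddingBundle:
        if self._bundle_cache is None:
            self._bundle_cache = self.model.network.forward(
                self.model.gene_X, self.model.img_F, self.model.graph, self.params
            )
        return self._bundle_cache

    @property
    def z_hyb(self) -> np.ndarray:
        return self.bundle.z_hyb

    @property
    def history_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"epoch": i, "L_img": h.L_img, "L_gene": h.L_gene,
                 "L_hyb": h.L_hyb, "total": h.total, "grad_norm": g}
                for i, (h, g) in enumerate(zip(self.loss_history, self.grad_norms))
            ]
        )

    def enhance(self, dataset: SpatialCellDataset | None = None) -> np.ndarray:
        """Denoised expression (recon_hyb clipped at 0), written to layer
        ``"enhanced"`` when a dataset is attached."""
        dataset = dataset or self.model.dataset
        if dataset is not None and self.model.features is not None:
            return enhance_expression(
                self.model.network, self.params, dataset, self.model.features, self.model.graph
            )
        return np.clip(self.bundle.recon_hyb, 0.0, None)

    def cluster(self, k: int, seed: int = 0, method: str = "gmm") -> np.ndarray:
        return cluster_embeddings(self.z_hyb, k=k, seed=seed, method=method)

    def project_2d(self, seed: int = 0) -> np.ndarray:
        return project_2d(self.z_hyb, seed=seed)

    def save(self, path: str | Path) -> None:
        save_checkpoint(path, self.params, self.model.config, self.train_config)

    @staticmethod
    def load(path: str | Path, model: HybridGraphModel) -> "HybridGraphResults":
        params, model_cfg, train_cfg = load_checkpoint(path)
        if model_cfg.to_dict() != model.config.to_dict():
            raise ValueError("checkpoint config does not match the model's config")
        return HybridGraphResults(model, params, [], [], train_cfg)

    def summary(self) -> str:
        """Plain-text fit report in the two-column estimation-summary style."""
        cfg, tc = self.model.config, self.train_config
        stats = neighbor_stats(self.model.graph)
        first = self.loss_history[0] if self.loss_history else None
        last = self.loss_history[-1] if self.loss_history else None
        lines = [
            "Hybrid Graph-Attention Autoencoder Results",
            "=" * 58,
            f"{'No. cells:':<28}{self.model.gene_X.shape[0]}",
            f"{'No. genes:':<28}{cfg.gene_dim}",
            f"{'Image feature dim:':<28}{cfg.img_dim}",
            f"{'Hidden / latent dim:':<28}{cfg.hidden_dim} / {cfg.latent_dim}",
            f"{'Attention heads:':<28}{cfg.n_heads}",
            f"{'Loss weights (λ1, λ2):':<28}({cfg.lambda1}, {cfg.lambda2})",
            f"{'Graph radius (px):':<28}{self.model.graph.radius}",
            f"{'Mean degree / isolated:':<28}{stats['mean_degree']:.2f} / {stats['isolated']}",
            f"{'Epochs (lr, wd):':<28}{tc.epochs} ({tc.lr}, {tc.weight_decay})",
            f"{'Grad clip norm:':<28}{tc.grad_clip_norm}",
            f"{'Seed:':<28}{tc.seed}",
            "-" * 58,
        ]
        if first and last:
            lines += [
                f"{'Total loss (first→last):':<28}{first.total:.6f} → {last.total:.6f}",
                f"{'  L_img:':<28}{first.L_img:.6f} → {last.L_img:.6f}",
                f"{'  L_gene:':<28}{first.L_gene:.6f} → {last.L_gene:.6f}",
                f"{'  L_hyb:':<28}{first.L_hyb:.6f} → {last.L_hyb:.6f}",
                f"{'Max post-clip grad norm:':<28}{max(self.grad_norms):.4f}",
            ]
        lines.append("=" * 58)
        return "\n".join(lines)
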
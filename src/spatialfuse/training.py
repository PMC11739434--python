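"""Self-supervised full-graph training of the hybrid network.

Defaults follow the published recipe: Adam (weight decay 1e-4), learning
rate 1e-3, 1,000 epochs, global gradient-norm clipping at 5. Training is
full-batch — the whole graph every step; minibatching over neighborhoods is
an extension point, not implemented. All randomness (weight init) flows from
a single integer seed, so a fixed seed gives a bit-stable loss history on
one platform.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .graph import SpatialGraph
from .model import HybridGraphNetwork, LossBreakdown, ModelConfig

__all__ = ["TrainConfig", "AdamOptimizer", "clip_global_norm", "train_network", "set_global_seed"]

ParamTree = dict[str, dict[str, np.ndarray]]


@dataclass
class TrainConfig:
    lr: float = 0.001
    epochs: int = 1000
    grad_clip_norm: float = 5.0
    weight_decay: float = 0.0001
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8
    seed: int = 0
    log_every: int = 0  # 0 = silent

    def __post_init__(self) -> None:
        if self.lr <= 0:
            raise ValueError("lr must be > 0")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.grad_clip_norm <= 0:
            raise ValueError("grad_clip_norm must be > 0")

    def to_dict(self) -> dict:
        return {
            "lr": self.lr, "epochs": self.epochs,
            "grad_clip_norm": self.grad_clip_norm,
            "weight_decay": self.weight_decay,
            "beta1": self.beta1, "beta2": self.beta2, "eps": self.eps,
            "seed": self.seed, "log_every": self.log_every,
        }


def set_global_seed(seed: int) -> np.random.Generator:
    """Return the Generator every random stream (weight init, sampling)
    derives from. One seed, one stream, reproducible runs."""
    return np.random.default_rng(seed)


def _tree_map(tree: ParamTree, fn) -> ParamTree:
    return {lk: {wk: fn(w) for wk, w in layer.items()} for lk, layer in tree.items()}


def clip_global_norm(grads: ParamTree, max_norm: float) -> tuple[ParamTree, float]:
    """Scale all gradients jointly so the global L2 norm is <= max_norm.
    Returns (clipped grads, post-clip norm)."""
    sq = sum(float(np.sum(g * g)) for layer in grads.values() for g in layer.values())
    norm = float(np.sqrt(sq))
    if norm > max_norm and norm > 0:
        factor = max_norm / norm
        grads = _tree_map(grads, lambda g: g * factor)
        return grads, max_norm
    return grads, norm


class AdamOptimizer:
    """Adam with (coupled) L2 weight decay added to the gradient, matching
    the classic formulation the published recipe uses."""

    def __init__(self, params: ParamTree, lr: float = 0.001, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8, weight_decay: float = 0.0):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = _tree_map(params, np.zeros_like)
        self.v = _tree_map(params, np.zeros_like)

    def step(self, params: ParamTree, grads: ParamTree) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bias1 = 1.0 - b1**self.t
        bias2 = 1.0 - b2**self.t
        for lk, layer in params.items():
            for wk, w in layer.items():
                g = grads[lk][wk]
                if self.weight_decay:
                    g = g + self.weight_decay * w
                m = self.m[lk][wk] = b1 * self.m[lk][wk] + (1 - b1) * g
                v = self.v[lk][wk] = b2 * self.v[lk][wk] + (1 - b2) * g * g
                w -= self.lr * (m / bias1) / (np.sqrt(v / bias2) + self.eps)


@dataclass
class TrainOutput:
    params: ParamTree
    history: list[LossBreakdown]
    grad_norms: list[float] = field(default_factory=list)


def train_network(
    network: HybridGraphNetwork,
    gene_X: np.ndarray,
    img_F: np.ndarray,
    target: np.ndarray,
    graph: SpatialGraph,
    train_config: TrainConfig,
    params: ParamTree | None = None,
) -> TrainOutput:
    """Optimize the network on one tissue section.

    Each epoch: full-graph forward, λ-weighted MSE loss, backprop, global
    gradient-norm clip, Adam step. Aborts on a non-finite loss, reporting
    the epoch index and returning the last finite history.
    """
    rng = set_global_seed(train_config.seed)
    if params is None:
        params = network.init_params(rng)
    opt = AdamOptimizer(
        params, lr=train_config.lr, beta1=train_config.beta1,
        beta2=train_config.beta2, eps=train_config.eps,
        weight_decay=train_config.weight_decay,
    )
    history: list[LossBreakdown] = []
    grad_norms: list[float] = []
    for epoch in range(train_config.epochs):
        bundle, cache = network.forward(gene_X, img_F, graph, params, return_cache=True)
        loss = network.compute_loss(bundle, target, img_F=img_F)
        if not np.isfinite(loss.total):
            raise FloatingPointError(
                f"non-finite loss at epoch {epoch} "
                f"(last finite total: {history[-1].total if history else 'none'})"
            )
        grads = network.backward(bundle, target, params, cache)
        grads, norm = clip_global_norm(grads, train_config.grad_clip_norm)
        opt.step(params, grads)
        history.append(loss)
        grad_norms.append(norm)
        if train_config.log_every and (epoch % train_config.log_every == 0):
            print(
                f"epoch {epoch}: total={loss.total:.6f} "
                f"L_img={loss.L_img:.6f} L_gene={loss.L_gene:.6f} L_hyb={loss.L_hyb:.6f}"
            )
    return TrainOutput(params=params, history=history, grad_norms=grad_norms)


def save_checkpoint(
    path: str | Path,
    params: ParamTree,
    model_config: ModelConfig,
    train_config: TrainConfig,
) -> None:
    """Single-file checkpoint: weights + both configs + seed (npz)."""
    flat = {f"{lk}/{wk}": w for lk, layer in params.items() for wk, w in layer.items()}
    meta = json.dumps({"model": model_config.to_dict(), "train": train_config.to_dict()})
    np.savez(Path(path), __meta__=np.array(meta), **flat)


def load_checkpoint(path: str | Path) -> tuple[ParamTree, ModelConfig, TrainConfig]:
    with np.load(Path(path), allow_pickle=False) as data:
        meta = json.loads(str(data["__meta__"]))
        params: ParamTree = {}
        for key in data.files:
            if key == "__meta__":
                continue
            lk, wk = key.split("/")
            params.setdefault(lk, {})[wk] = data[key]
    return params, ModelConfig(**meta["model"]), TrainConfig(**meta["train"])
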
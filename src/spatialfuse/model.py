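"""Hybrid graph-attention autoencoder network.

Three autoencoders — image, transcriptome, hybrid — share one cellular
spatial graph. Every layer is a neighbor-attention layer: cell *i* attends
over the self-inclusive neighborhood {i} ∪ N(i) with softmaxed scaled
dot-product weights, so spatial context enters every encode/decode step.
The hybrid encoder consumes the concatenation of the image and gene latent
embeddings and yields the terminal representation z_hyb; each decoder
reconstructs the normalized log expression (by default also the image
branch, which thereby learns to predict expression from morphology).

The self-supervised objective is a λ-weighted sum of per-branch mean squared
reconstruction errors:

    L = λ1·L_img + λ2·L_gene + L_hyb,   λ1, λ2 >= 0.

Implemented in NumPy with hand-derived gradients; ``numeric_gradient`` in the
test-suite cross-checks every parameter against finite differences.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .graph import SpatialGraph

__all__ = [
    "ModelConfig",
    "EmbeddingBundle",
    "LossBreakdown",
    "AttentionLayer",
    "neighbor_attention_layer",
    "HybridGraphNetwork",
]


@dataclass
class ModelConfig:
    """Architecture and loss hyperparameters.

    ``lambda1`` weights the image-branch reconstruction loss, ``lambda2`` the
    gene branch; both default to 0.1, the hybrid branch has weight 1.
    ``recon_img_target`` selects whether the image branch reconstructs the
    expression target ("expression", default) or its own input features
    ("image").
    """

    gene_dim: int
    img_dim: int
    hidden_dim: int = 64
    latent_dim: int = 32
    n_heads: int = 1
    lambda1: float = 0.1
    lambda2: float = 0.1
    recon_img_target: str = "expression"

    def __post_init__(self) -> None:
        for name in ("gene_dim", "img_dim", "hidden_dim", "latent_dim", "n_heads"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.lambda1 < 0 or self.lambda2 < 0:
            raise ValueError("lambda1 and lambda2 must be >= 0")
        if self.recon_img_target not in ("expression", "image"):
            raise ValueError("recon_img_target must be 'expression' or 'image'")
        if self.hidden_dim % self.n_heads or self.latent_dim % self.n_heads:
            raise ValueError("hidden_dim and latent_dim must be divisible by n_heads")

    def to_dict(self) -> dict:
        return {
            "gene_dim": self.gene_dim,
            "img_dim": self.img_dim,
            "hidden_dim": self.hidden_dim,
            "latent_dim": self.latent_dim,
            "n_heads": self.n_heads,
            "lambda1": self.lambda1,
            "lambda2": self.lambda2,
            "recon_img_target": self.recon_img_target,
        }


@dataclass
class EmbeddingBundle:
    """Per-cell latent embeddings and decoder reconstructions."""

    z_img: np.ndarray
    z_gene: np.ndarray
    z_hyb: np.ndarray
    recon_img: np.ndarray
    recon_gene: np.ndarray
    recon_hyb: np.ndarray


@dataclass
class LossBreakdown:
    """Per-branch mean squared errors and the λ-weighted total."""

    L_img: float
    L_gene: float
    L_hyb: float
    total: float


def _elu(x: np.ndarray) -> np.ndarray:
    return np.where(x > 0, x, np.expm1(np.minimum(x, 0.0)))


def _elu_grad(x: np.ndarray, ex: np.ndarray) -> np.ndarray:
    # derivative of ELU in terms of pre-activation x and activation ex
    return np.where(x > 0, 1.0, ex + 1.0)


def _check_finite(name: str, arr: np.ndarray) -> np.ndarray:
    if not np.all(np.isfinite(arr)):
        raise FloatingPointError(f"non-finite values in tensor {name!r}")
    return arr


class EdgeContext:
    """Precomputed scatter structure for the self-inclusive neighborhoods.

    ``src``/``dst`` are directed edge endpoints with ``src`` sorted, so
    per-source segment reductions use ``reduceat``; scatter-by-destination
    goes through a sparse (n x E) indicator matrix.
    """

    def __init__(self, src: np.ndarray, dst: np.ndarray, n: int):
        from scipy import sparse

        self.src, self.dst, self.n = src, dst, n
        # first edge index of each source's contiguous segment
        self.starts = np.searchsorted(src, np.arange(n))
        ones = np.ones(len(dst))
        self.S_dst = sparse.csr_matrix((ones, (dst, np.arange(len(dst)))), shape=(n, len(dst)))

    @classmethod
    def from_graph(cls, graph: SpatialGraph) -> "EdgeContext":
        src, dst = graph.attention_edges()
        return cls(src, dst, graph.n_cells)

    def segment_sum(self, values: np.ndarray) -> np.ndarray:
        """Sum edge values into their source node; values (E, ...)."""
        return np.add.reduceat(values, self.starts, axis=0)

    def segment_max(self, values: np.ndarray) -> np.ndarray:
        return np.maximum.reduceat(values, self.starts, axis=0)


class AttentionLayer:
    """One neighbor-attention layer: H (n, d_in) -> (n, d_out).

    out_i = act( Σ_{j ∈ {i}∪N(i)} α_ij · (x_j Wv) + bv ),
    α_ij = softmax_j( (x_i Wq)·(x_j Wk) / sqrt(d_head) ).

    A cell with no neighbors attends only to itself (singleton softmax).
    The value-projection bias bv passes through the softmax untouched
    (attention weights sum to one).
    """

    def __init__(self, d_in: int, d_out: int, n_heads: int = 1, activation: bool = True):
        if d_out % n_heads:
            raise ValueError("d_out must be divisible by n_heads")
        self.d_in, self.d_out, self.n_heads = d_in, d_out, n_heads
        self.activation = activation

    def init_params(self, rng: np.random.Generator) -> dict[str, np.ndarray]:
        limit = np.sqrt(6.0 / (self.d_in + self.d_out))
        params = {
            w: rng.uniform(-limit, limit, size=(self.d_in, self.d_out))
            for w in ("Wq", "Wk", "Wv")
        }
        params["bv"] = np.zeros(self.d_out)
        return params

    def forward(
        self, H: np.ndarray, params: dict[str, np.ndarray], ctx: EdgeContext
    ) -> tuple[np.ndarray, dict]:
        if H.shape[1] != self.d_in:
            raise ValueError(f"input width {H.shape[1]} != layer d_in {self.d_in}")
        n = H.shape[0]
        h, dh = self.n_heads, self.d_out // self.n_heads
        scale = np.sqrt(dh)
        src, dst = ctx.src, ctx.dst
        Q = (H @ params["Wq"]).reshape(n, h, dh)
        K = (H @ params["Wk"]).reshape(n, h, dh)
        V = (H @ params["Wv"]).reshape(n, h, dh)
        e = np.einsum("ehd,ehd->eh", Q[src], K[dst]) / scale
        m = ctx.segment_max(e)
        ex = np.exp(e - m[src])
        denom = ctx.segment_sum(ex)
        alpha = ex / denom[src]
        M = ctx.segment_sum((alpha[..., None] * V[dst]).reshape(len(src), h * dh))
        pre = M.reshape(n, self.d_out) + params["bv"]
        out = _elu(pre) if self.activation else pre
        cache = {"H": H, "Q": Q, "K": K, "V": V, "alpha": alpha, "pre": pre, "out": out}
        return out, cache

    def backward(
        self,
        dOut: np.ndarray,
        params: dict[str, np.ndarray],
        cache: dict,
        ctx: EdgeContext,
    ) -> tuple[np.ndarray, dict[str, np.ndarray]]:
        H, Q, K, V = cache["H"], cache["Q"], cache["K"], cache["V"]
        alpha, pre = cache["alpha"], cache["pre"]
        n = H.shape[0]
        h, dh = self.n_heads, self.d_out // self.n_heads
        scale = np.sqrt(dh)
        src, dst = ctx.src, ctx.dst
        E = len(src)
        if self.activation:
            dpre = dOut * _elu_grad(pre, cache["out"])
        else:
            dpre = dOut
        dM = dpre.reshape(n, h, dh)
        dMs = dM[src]
        dV = (ctx.S_dst @ (alpha[..., None] * dMs).reshape(E, h * dh)).reshape(n, h, dh)
        dalpha = np.einsum("ehd,ehd->eh", dMs, V[dst])
        s = ctx.segment_sum(alpha * dalpha)
        de = alpha * (dalpha - s[src])
        dQ = ctx.segment_sum((de[..., None] * K[dst] / scale).reshape(E, h * dh)).reshape(n, h, dh)
        dK = (ctx.S_dst @ (de[..., None] * Q[src] / scale).reshape(E, h * dh)).reshape(n, h, dh)
        dQf, dKf, dVf = (x.reshape(n, self.d_out) for x in (dQ, dK, dV))
        grads = {
            "Wq": H.T @ dQf,
            "Wk": H.T @ dKf,
            "Wv": H.T @ dVf,
            "bv": dpre.sum(axis=0),
        }
        dH = dQf @ params["Wq"].T + dKf @ params["Wk"].T + dVf @ params["Wv"].T
        return dH, grads


def neighbor_attention_layer(
    H: np.ndarray,
    graph: SpatialGraph,
    params: dict[str, np.ndarray],
    n_heads: int = 1,
    activation: bool = True,
) -> np.ndarray:
    """Functional form of one attention layer over a spatial graph."""
    d_in, d_out = params["Wq"].shape
    layer = AttentionLayer(d_in, d_out, n_heads=n_heads, activation=activation)
    full = dict(params)
    full.setdefault("bv", np.zeros(d_out))
    out, _ = layer.forward(np.asarray(H, dtype=float), full, EdgeContext.from_graph(graph))
    return out


# Layer wiring: (name, d_in, d_out, activation, heads). Encoders go input->
# hidden->latent, decoders mirror latent->hidden->output with a linear final
# layer; final layers use one head since the output width is gene-space and
# need not divide by n_heads.
def _layer_specs(cfg: ModelConfig) -> list[tuple[str, int, int, bool, int]]:
    img_out = cfg.gene_dim if cfg.recon_img_target == "expression" else cfg.img_dim
    h = cfg.n_heads
    return [
        ("img_enc1", cfg.img_dim, cfg.hidden_dim, True, h),
        ("img_enc2", cfg.hidden_dim, cfg.latent_dim, True, h),
        ("img_dec1", cfg.latent_dim, cfg.hidden_dim, True, h),
        ("img_dec2", cfg.hidden_dim, img_out, False, 1),
        ("gene_enc1", cfg.gene_dim, cfg.hidden_dim, True, h),
        ("gene_enc2", cfg.hidden_dim, cfg.latent_dim, True, h),
        ("gene_dec1", cfg.latent_dim, cfg.hidden_dim, True, h),
        ("gene_dec2", cfg.hidden_dim, cfg.gene_dim, False, 1),
        ("hyb_enc1", 2 * cfg.latent_dim, cfg.hidden_dim, True, h),
        ("hyb_enc2", cfg.hidden_dim, cfg.latent_dim, True, h),
        ("hyb_dec1", cfg.latent_dim, cfg.hidden_dim, True, h),
        ("hyb_dec2", cfg.hidden_dim, cfg.gene_dim, False, 1),
    ]


class HybridGraphNetwork:
    """The three-autoencoder hybrid network over one spatial graph."""

    def __init__(self, config: ModelConfig):
        self.config = config
        self.layers: dict[str, AttentionLayer] = {
            name: AttentionLayer(d_in, d_out, heads, act)
            for name, d_in, d_out, act, heads in _layer_specs(config)
        }
        self.layer_order = [spec[0] for spec in _layer_specs(config)]

    def init_params(self, rng: np.random.Generator) -> dict[str, dict[str, np.ndarray]]:
        return {name: self.layers[name].init_params(rng) for name in self.layer_order}

    # -- forward ---------------------------------------------------------
    def forward(
        self,
        gene_X: np.ndarray,
        img_F: np.ndarray,
        graph: SpatialGraph,
        params: dict[str, dict[str, np.ndarray]],
        return_cache: bool = False,
    ):
        cfg = self.config
        gene_X = _check_finite("gene_X", np.asarray(gene_X, dtype=float))
        img_F = _check_finite("img_F", np.asarray(img_F, dtype=float))
        if gene_X.shape[1] != cfg.gene_dim:
            raise ValueError(f"gene_X has {gene_X.shape[1]} genes, config expects {cfg.gene_dim}")
        if img_F.shape[1] != cfg.img_dim:
            raise ValueError(f"img_F has {img_F.shape[1]} dims, config expects {cfg.img_dim}")
        if gene_X.shape[0] != img_F.shape[0] or gene_X.shape[0] != graph.n_cells:
            raise ValueError("gene_X, img_F and graph disagree on the cell axis")
        ctx = getattr(graph, "_edge_ctx", None)
        if ctx is None or ctx.n != graph.n_cells:
            ctx = EdgeContext.from_graph(graph)
            graph._edge_ctx = ctx  # memoized; the edge set is immutable in practice
        caches: dict[str, dict] = {}

        def run(name: str, x: np.ndarray) -> np.ndarray:
            out, cache = self.layers[name].forward(x, params[name], ctx)
            caches[name] = cache
            return _check_finite(name, out)

        h = run("img_enc1", img_F)
        z_img = run("img_enc2", h)
        h = run("img_dec1", z_img)
        recon_img = run("img_dec2", h)

        h = run("gene_enc1", gene_X)
        z_gene = run("gene_enc2", h)
        h = run("gene_dec1", z_gene)
        recon_gene = run("gene_dec2", h)

        z_cat = np.concatenate([z_img, z_gene], axis=1)
        h = run("hyb_enc1", z_cat)
        z_hyb = run("hyb_enc2", h)
        h = run("hyb_dec1", z_hyb)
        recon_hyb = run("hyb_dec2", h)

        bundle = EmbeddingBundle(
            z_img=z_img, z_gene=z_gene, z_hyb=z_hyb,
            recon_img=recon_img, recon_gene=recon_gene, recon_hyb=recon_hyb,
        )
        if return_cache:
            return bundle, {"layers": caches, "ctx": ctx, "img_F": img_F}
        return bundle

    # -- loss ------------------------------------------------------------
    def compute_loss(
        self, bundle: EmbeddingBundle, target: np.ndarray, img_F: np.ndarray | None = None
    ) -> LossBreakdown:
        cfg = self.config
        target = np.asarray(target, dtype=float)
        for name, recon in (("recon_gene", bundle.recon_gene), ("recon_hyb", bundle.recon_hyb)):
            if recon.shape != target.shape:
                raise ValueError(f"{name} shape {recon.shape} != target {target.shape}")
        img_target = target if cfg.recon_img_target == "expression" else img_F
        if img_target is None:
            raise ValueError("image-space reconstruction requires img_F")
        if bundle.recon_img.shape != img_target.shape:
            raise ValueError(
                f"recon_img shape {bundle.recon_img.shape} != target {img_target.shape}"
            )
        L_img = float(np.mean((bundle.recon_img - img_target) ** 2))
        L_gene = float(np.mean((bundle.recon_gene - target) ** 2))
        L_hyb = float(np.mean((bundle.recon_hyb - target) ** 2))
        total = cfg.lambda1 * L_img + cfg.lambda2 * L_gene + L_hyb
        return LossBreakdown(L_img=L_img, L_gene=L_gene, L_hyb=L_hyb, total=float(total))

    # -- backward --------------------------------------------------------
    def backward(
        self,
        bundle: EmbeddingBundle,
        target: np.ndarray,
        params: dict[str, dict[str, np.ndarray]],
        cache: dict,
    ) -> dict[str, dict[str, np.ndarray]]:
        """Gradient of the total loss w.r.t. every weight matrix."""
        cfg = self.config
        ctx = cache["ctx"]
        caches = cache["layers"]
        grads: dict[str, dict[str, np.ndarray]] = {}

        def back(name: str, dOut: np.ndarray) -> np.ndarray:
            dH, g = self.layers[name].backward(dOut, params[name], caches[name], ctx)
            grads[name] = g
            return dH

        img_target = target if cfg.recon_img_target == "expression" else cache["img_F"]
        d_recon_img = 2.0 * cfg.lambda1 * (bundle.recon_img - img_target) / bundle.recon_img.size
        d_recon_gene = 2.0 * cfg.lambda2 * (bundle.recon_gene - target) / bundle.recon_gene.size
        d_recon_hyb = 2.0 * (bundle.recon_hyb - target) / bundle.recon_hyb.size

        # hybrid branch back to the concatenated latents
        dh = back("hyb_dec2", d_recon_hyb)
        dz_hyb = back("hyb_dec1", dh)
        dh = back("hyb_enc2", dz_hyb)
        dz_cat = back("hyb_enc1", dh)
        dz_img_h, dz_gene_h = np.split(dz_cat, 2, axis=1)

        # image branch: decoder path + hybrid path
        dh = back("img_dec2", d_recon_img)
        dz_img = back("img_dec1", dh) + dz_img_h
        dh = back("img_enc2", dz_img)
        back("img_enc1", dh)

        # gene branch
        dh = back("gene_dec2", d_recon_gene)
        dz_gene = back("gene_dec1", dh) + dz_gene_h
        dh = back("gene_enc2", dz_gene)
        back("gene_enc1", dh)
        return grads
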
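import numpy as np
import pytest

import spatialfuse as sf
from spatialfuse.model import AttentionLayer, EdgeContext, _elu


def dense_masked_attention_oracle(H, graph, params, n_heads=1, activation=True):
    """Full n x n attention matrix, masked to {i} ∪ N(i), row-softmaxed."""
    n, d_out = H.shape[0], params["Wq"].shape[1]
    h, dh = n_heads, d_out // n_heads
    mask = np.eye(n, dtype=bool)
    for i, j in graph.edges:
        mask[i, j] = mask[j, i] = True
    Q = (H @ params["Wq"]).reshape(n, h, dh)
    K = (H @ params["Wk"]).reshape(n, h, dh)
    V = (H @ params["Wv"]).reshape(n, h, dh)
    out = np.zeros((n, h, dh))
    for head in range(h):
        scores = Q[:, head] @ K[:, head].T / np.sqrt(dh)
        scores[~mask] = -np.inf
        w = np.exp(scores - scores.max(axis=1, keepdims=True))
        w /= w.sum(axis=1, keepdims=True)
        out[:, head] = w @ V[:, head]
    pre = out.reshape(n, d_out) + params.get("bv", 0.0)
    return _elu(pre) if activation else pre


def make_params(d_in, d_out, seed):
    return AttentionLayer(d_in, d_out).init_params(np.random.default_rng(seed))


class TestNeighborAttentionLayer:
    @pytest.mark.parametrize("heads", [1, 2])
    def test_matches_dense_oracle_on_small_graphs(self, rng, heads):
        for trial in range(5):
            n = int(rng.integers(3, 11))
            coords = rng.uniform(0, 10, (n, 2))
            graph = sf.build_radius_graph(coords, 4.0)
            H = rng.normal(size=(n, 6))
            params = AttentionLayer(6, 4, n_heads=heads).init_params(
                np.random.default_rng(trial)
            )
            got = sf.neighbor_attention_layer(H, graph, params, n_heads=heads)
            want = dense_masked_attention_oracle(H, graph, params, n_heads=heads)
            np.testing.assert_allclose(got, want, atol=1e-6)

    def test_empty_graph_degenerates_to_per_cell_map(self, rng):
        # singleton softmax = 1, so output is act(value projection + bias)
        n = 5
        graph = sf.SpatialGraph(n_cells=n, edges=set(), radius=0.0)
        H = rng.normal(size=(n, 3))
        params = make_params(3, 4, seed=0)
        got = sf.neighbor_attention_layer(H, graph, params)
        want = _elu(H @ params["Wv"] + params["bv"])
        np.testing.assert_allclose(got, want, atol=1e-12)

    def test_identical_inputs_identical_outputs(self, rng, tiny_graph):
        H = np.tile(rng.normal(size=(1, 5)), (tiny_graph.n_cells, 1))
        out = sf.neighbor_attention_layer(H, tiny_graph, make_params(5, 4, 1))
        assert np.allclose(out, out[0])

    def test_dimension_mismatch_rejected(self, rng, tiny_graph):
        H = rng.normal(size=(tiny_graph.n_cells, 9))
        with pytest.raises(ValueError, match="width"):
            sf.neighbor_attention_layer(H, tiny_graph, make_params(5, 4, 1))


class TestForward:
    def _setup(self, rng, n=12, genes=7, imgd=5, **cfg_kwargs):
        coords = rng.uniform(0, 12, (n, 2))
        graph = sf.build_radius_graph(coords, 5.0)
        cfg = sf.ModelConfig(gene_dim=genes, img_dim=imgd, hidden_dim=6, latent_dim=4,
                             **cfg_kwargs)
        net = sf.HybridGraphNetwork(cfg)
        params = net.init_params(np.random.default_rng(0))
        X = rng.normal(size=(n, genes)) ** 2
        F = rng.normal(size=(n, imgd))
        return net, params, X, F, graph

    def test_shape_contract(self, rng):
        net, params, X, F, graph = self._setup(rng)
        b = net.forward(X, F, graph, params)
        n, g = X.shape
        for z in (b.z_img, b.z_gene, b.z_hyb):
            assert z.shape == (n, 4)
        for r in (b.recon_img, b.recon_gene, b.recon_hyb):
            assert r.shape == (n, g)

    def test_deterministic(self, rng):
        net, params, X, F, graph = self._setup(rng)
        b1 = net.forward(X, F, graph, params)
        b2 = net.forward(X, F, graph, params)
        assert b1.recon_hyb.tobytes() == b2.recon_hyb.tobytes()

    def test_single_cell_no_edges_matches_layer_composition(self, rng):
        graph = sf.SpatialGraph(n_cells=1, edges=set(), radius=0.0)
        cfg = sf.ModelConfig(gene_dim=3, img_dim=2, hidden_dim=4, latent_dim=2)
        net = sf.HybridGraphNetwork(cfg)
        params = net.init_params(np.random.default_rng(3))
        X = np.abs(rng.normal(size=(1, 3)))
        F = rng.normal(size=(1, 2))

        def dense(name, x, act=True):
            p = params[name]
            pre = x @ p["Wv"] + p["bv"]
            return _elu(pre) if act else pre

        z_img = dense("img_enc2", dense("img_enc1", F))
        z_gene = dense("gene_enc2", dense("gene_enc1", X))
        z_hyb = dense("hyb_enc2", dense("hyb_enc1", np.concatenate([z_img, z_gene], 1)))
        recon_hyb = dense("hyb_dec2", dense("hyb_dec1", z_hyb), act=False)
        b = net.forward(X, F, graph, params)
        np.testing.assert_allclose(b.z_hyb, z_hyb, atol=1e-6)
        np.testing.assert_allclose(b.recon_hyb, recon_hyb, atol=1e-6)

    def test_permutation_equivariance(self, rng):
        net, params, X, F, graph = self._setup(rng, n=10)
        perm = rng.permutation(10)
        inv = np.argsort(perm)
        edges_p = {tuple(sorted((int(inv[i]), int(inv[j])))) for i, j in graph.edges}
        graph_p = sf.SpatialGraph(n_cells=10, edges=edges_p, radius=graph.radius)
        b = net.forward(X, F, graph, params)
        bp = net.forward(X[perm], F[perm], graph_p, params)
        np.testing.assert_allclose(bp.z_hyb, b.z_hyb[perm], atol=1e-8)
        np.testing.assert_allclose(bp.recon_gene, b.recon_gene[perm], atol=1e-8)

    def test_nan_input_identified(self, rng):
        net, params, X, F, graph = self._setup(rng)
        X[0, 0] = np.nan
        with pytest.raises(FloatingPointError, match="gene_X"):
            net.forward(X, F, graph, params)


class TestComputeLoss:
    def _bundle(self, rng, n=5, g=4):
        mk = lambda: rng.normal(size=(n, g))
        z = rng.normal(size=(n, 2))
        return sf.EmbeddingBundle(z, z, z, mk(), mk(), mk())

    def test_perfect_reconstruction_is_zero(self, rng):
        t = rng.normal(size=(5, 4))
        z = rng.normal(size=(5, 2))
        b = sf.EmbeddingBundle(z, z, z, t.copy(), t.copy(), t.copy())
        net = sf.HybridGraphNetwork(sf.ModelConfig(gene_dim=4, img_dim=3))
        loss = net.compute_loss(b, t)
        assert loss.total == 0.0

    def test_lambda_nulling_isolates_hybrid(self, rng):
        b = self._bundle(rng)
        t = rng.normal(size=(5, 4))
        net = sf.HybridGraphNetwork(
            sf.ModelConfig(gene_dim=4, img_dim=3, lambda1=0.0, lambda2=0.0)
        )
        loss = net.compute_loss(b, t)
        assert loss.total == loss.L_hyb

    def test_hand_summed_oracle(self, rng):
        b = self._bundle(rng)
        t = rng.normal(size=(5, 4))
        net = sf.HybridGraphNetwork(
            sf.ModelConfig(gene_dim=4, img_dim=3, lambda1=0.3, lambda2=0.7)
        )
        loss = net.compute_loss(b, t)
        mse = lambda a: sum((a[i, j] - t[i, j]) ** 2 for i in range(5) for j in range(4)) / 20
        want = 0.3 * mse(b.recon_img) + 0.7 * mse(b.recon_gene) + mse(b.recon_hyb)
        assert abs(loss.total - want) < 1e-9
        assert min(loss.L_img, loss.L_gene, loss.L_hyb) >= 0.0

    def test_shape_mismatch_rejected(self, rng):
        b = self._bundle(rng)
        net = sf.HybridGraphNetwork(sf.ModelConfig(gene_dim=4, img_dim=3))
        with pytest.raises(ValueError):
            net.compute_loss(b, rng.normal(size=(5, 9)))


class TestGradients:
    @pytest.mark.parametrize("recon_img_target", ["expression", "image"])
    def test_finite_difference_agreement(self, rng, recon_img_target):
        n = 7
        coords = rng.uniform(0, 10, (n, 2))
        graph = sf.build_radius_graph(coords, 4.0)
        cfg = sf.ModelConfig(gene_dim=5, img_dim=6, hidden_dim=4, latent_dim=2,
                             recon_img_target=recon_img_target)
        net = sf.HybridGraphNetwork(cfg)
        params = net.init_params(np.random.default_rng(1))
        X = rng.normal(size=(n, 5))
        F = rng.normal(size=(n, 6))

        def total():
            return net.compute_loss(net.forward(X, F, graph, params), X, img_F=F).total

        b, cache = net.forward(X, F, graph, params, return_cache=True)
        grads = net.backward(b, X, params, cache)
        eps = 1e-5
        check = np.random.default_rng(2)
        for lk in params:
            for wk in params[lk]:
                flat = params[lk][wk].reshape(-1)
                for t in check.choice(flat.size, size=min(3, flat.size), replace=False):
                    old = flat[t]
                    flat[t] = old + eps
                    lp = total()
                    flat[t] = old - eps
                    lm = total()
                    flat[t] = old
                    num = (lp - lm) / (2 * eps)
                    ana = grads[lk][wk].reshape(-1)[t]
                    assert abs(num - ana) <= 1e-4 * max(1.0, abs(num), abs(ana)), (
                        f"{lk}/{wk}[{t}]: numeric {num} vs analytic {ana}"
                    )


class TestModelConfig:
    def test_invalid_values_rejected(self):
        with pytest.raises(ValueError):
            sf.ModelConfig(gene_dim=0, img_dim=3)
        with pytest.raises(ValueError):
            sf.ModelConfig(gene_dim=3, img_dim=3, lambda1=-0.1)
        with pytest.raises(ValueError):
            sf.ModelConfig(gene_dim=3, img_dim=3, recon_img_target="latent")

    def test_edge_context_segments(self, tiny_graph):
        ctx = EdgeContext.from_graph(tiny_graph)
        vals = np.ones((len(ctx.src), 1))
        seg = ctx.segment_sum(vals)
        deg_plus_self = tiny_graph.degrees + 1
        np.testing.assert_array_equal(seg[:, 0], deg_plus_self)
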
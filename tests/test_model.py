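"""Losses, autoencoder, GCN forward pass, and the two-stage training."""

import numpy as np
import pytest

from omicbridge import (
    Autoencoder,
    AutoencoderConfig,
    FeatureMatrix,
    GCNModel,
    HybridGraph,
    LabelSet,
    MMDConfig,
    TrainConfig,
    cosine_loss,
    cross_entropy,
    gcn_forward,
    mk_mmd,
    train,
)
from omicbridge._autograd import Adam, Tensor
from omicbridge.graph import normalize_adjacency
from omicbridge.model import ae_decode, ae_encode


class TestMKMMD:
    def test_identical_samples_zero(self, rng):
        x = rng.normal(size=(40, 5))
        assert abs(mk_mmd(x, x.copy())) <= 1e-9

    def test_singleton_closed_form(self):
        a, b = np.array([[0.0, 0.0]]), np.array([[3.0, 4.0]])  # distance 5
        sigma = 2.0
        cfg = MMDConfig(bandwidths=[sigma])
        expected = 2.0 - 2.0 * np.exp(-25.0 / (2.0 * sigma**2))
        assert mk_mmd(a, b, cfg) == pytest.approx(expected, abs=1e-9)

    def test_separated_exceeds_same_distribution(self):
        hits = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            base = rng.normal(size=(100, 3))
            same = rng.normal(size=(100, 3))
            far = rng.normal(size=(100, 3)) + 5.0
            if mk_mmd(base, far) > mk_mmd(base, same):
                hits += 1
        assert hits >= 99

    def test_symmetric_and_permutation_invariant(self, rng):
        x, y = rng.normal(size=(20, 4)), rng.normal(size=(25, 4))
        cfg = MMDConfig(bandwidths=[0.5, 1.0, 2.0])
        forward = mk_mmd(x, y, cfg)
        assert forward == pytest.approx(mk_mmd(y, x, cfg), abs=1e-12)
        perm = rng.permutation(len(x))
        assert forward == pytest.approx(mk_mmd(x[perm], y, cfg), abs=1e-12)

    def test_biased_nonnegative(self, rng):
        for _ in range(20):
            x, y = rng.normal(size=(10, 3)), rng.normal(size=(12, 3))
            assert mk_mmd(x, y) >= -1e-9

    def test_unbiased_requires_two_samples(self):
        cfg = MMDConfig(bandwidths=[1.0], estimator="unbiased")
        with pytest.raises(ValueError):
            mk_mmd(np.ones((1, 2)), np.ones((1, 2)), cfg)

    def test_beta_constraint(self):
        with pytest.raises(ValueError, match="beta"):
            MMDConfig(bandwidths=[1.0, 2.0], beta=[0.9, 0.5])


class TestCosineLoss:
    def test_matched_rows_zero(self, rng):
        src = rng.normal(size=(6, 4))
        tgt = src[[2, 0, 5]] * 3.0  # scale-invariant
        assert cosine_loss(src, tgt) == pytest.approx(0.0, abs=1e-12)

    def test_orthogonal_rows_one(self):
        src = np.array([[1.0, 0.0, 0.0], [0.0, 1.0, 0.0]])
        tgt = np.array([[0.0, 0.0, 2.0]])
        assert cosine_loss(src, tgt) == pytest.approx(1.0, abs=1e-9)

    def test_antipodal_pair_two(self):
        assert cosine_loss(np.array([[1.0, 0.0]]),
                           np.array([[-2.0, 0.0]])) == pytest.approx(2.0, abs=1e-9)

    def test_zero_norm_row_errors(self):
        with pytest.raises(ValueError, match="zero-norm"):
            cosine_loss(np.zeros((1, 3)), np.ones((1, 3)))


class TestCrossEntropy:
    def test_perfect_prediction_zero(self):
        y = np.eye(3)
        assert cross_entropy(y, y) == pytest.approx(0.0, abs=1e-9)

    def test_uniform_prediction_log_c(self):
        for c in (2, 5, 11):
            y = np.eye(c)[[0] * 4]
            p = np.full((4, c), 1.0 / c)
            assert cross_entropy(y, p) == pytest.approx(np.log(c), abs=1e-9)

    def test_half_half_binary(self):
        assert cross_entropy(np.array([[1.0, 0.0]]),
                             np.array([[0.5, 0.5]])) == pytest.approx(
            np.log(2), abs=1e-9
        )

    def test_rejects_non_stochastic_rows(self):
        with pytest.raises(ValueError, match="sum to 1"):
            cross_entropy(np.array([[1.0, 0.0]]), np.array([[0.9, 0.3]]))


class TestAutoencoder:
    cfg = AutoencoderConfig(n_sub=4, latent_dim=5, hidden=6)

    def test_zero_input_zero_latent(self):
        ae = Autoencoder(18, self.cfg, np.random.default_rng(0))
        z = ae_encode(np.zeros((3, 18)), ae)
        assert np.array_equal(z, np.zeros((3, 5)))

    def test_shapes_and_round_trip(self, rng):
        ae = Autoencoder(18, self.cfg, rng)
        x = rng.normal(size=(7, 18))
        z = ae_encode(x, ae)
        assert z.shape == (7, 5)
        xhat = ae_decode(z, ae)
        assert xhat.shape == (7, 18)

    def test_deterministic_on_identical_rows(self, rng):
        ae = Autoencoder(10, self.cfg, rng)
        x = np.tile(rng.normal(size=(1, 10)), (2, 1))
        z = ae_encode(x, ae)
        assert np.array_equal(z[0], z[1])

    def test_feature_overflow_errors(self, rng):
        ae = Autoencoder(10, AutoencoderConfig(n_sub=2, s_sub=5), rng)
        with pytest.raises(ValueError):
            ae.pad(np.ones((1, 11)))

    def test_rank_one_matrix_reconstructed(self):
        # rank-1 data is losslessly compressible at any latent dim >= 1
        rng = np.random.default_rng(0)
        x = np.outer(rng.normal(size=200), rng.normal(size=50))
        ae = Autoencoder(50, AutoencoderConfig(n_sub=5, latent_dim=4, hidden=12), rng)
        opt = Adam(ae.params, lr=5e-3)
        x_pad = ae.pad(x)
        for _ in range(400):
            z = ae.encode_t(x)
            loss = ((ae.decode_t(z) - Tensor(x_pad)) ** 2).mean()
            opt.zero_grad()
            loss.backward()
            opt.step()
        err = np.linalg.norm(ae.decode(ae.encode(x)) - x) / np.linalg.norm(x)
        assert err < 0.1


def _path_graph_norm(n=3):
    a = np.zeros((n, n))
    for i in range(n - 1):
        a[i, i + 1] = a[i + 1, i] = 1
    return normalize_adjacency(HybridGraph(n, 0, a)).normalized


class TestGCNForward:
    def test_softmax_rows_sum_to_one(self, rng):
        model = GCNModel(6, 4, 3, rng)
        h1, probs = gcn_forward(rng.normal(size=(10, 6)), np.eye(10), model)
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-6)
        assert np.all((probs > 0) & (probs < 1))

    def test_identity_graph_is_permutation_equivariant(self, rng):
        model = GCNModel(5, 4, 3, rng)
        x = rng.normal(size=(8, 5))
        _, p = gcn_forward(x, np.eye(8), model)
        perm = rng.permutation(8)
        _, p_perm = gcn_forward(x[perm], np.eye(8), model)
        assert np.allclose(p_perm, p[perm])

    def test_graph_permutation_equivariance(self, rng):
        model = GCNModel(4, 6, 2, rng)
        n = 20
        a = (rng.random((n, n)) < 0.2).astype(float)
        a = np.triu(a, 1)
        a = a + a.T
        a_norm = normalize_adjacency(HybridGraph(n, 0, a)).normalized
        x = rng.normal(size=(n, 4))
        h, p = gcn_forward(x, a_norm, model)
        perm = rng.permutation(n)
        pmat = np.eye(n)[perm]
        h2, p2 = gcn_forward(x[perm], pmat @ a_norm @ pmat.T, model)
        assert np.allclose(h2, h[perm], atol=1e-10)
        assert np.allclose(p2, p[perm], atol=1e-10)

    def test_path_graph_hand_computed(self):
        # 3-node path, scalar features [1,0,0], W0=[[1]], W1=[[1,-1]]
        a_norm = _path_graph_norm(3)
        x = np.array([[1.0], [0.0], [0.0]])
        model = GCNModel(1, 1, 2, np.random.default_rng(0))
        model.w0.value = np.array([[1.0]])
        model.w1.value = np.array([[1.0, -1.0]])
        h1, probs = gcn_forward(x, a_norm, model)
        h_exp = np.maximum(a_norm @ x, 0.0)
        logits = (a_norm @ h_exp) @ np.array([[1.0, -1.0]])
        p_exp = np.exp(logits) / np.exp(logits).sum(axis=1, keepdims=True)
        assert np.allclose(h1, h_exp, atol=1e-12)
        assert np.allclose(probs, p_exp, atol=1e-12)

    def test_single_logit_softmax_is_one(self):
        a_norm = _path_graph_norm(3)
        model = GCNModel(1, 1, 1, np.random.default_rng(0))
        model.w0.value = np.array([[1.0]])
        model.w1.value = np.array([[1.0]])
        _, probs = gcn_forward(np.array([[1.0], [0.0], [0.0]]), a_norm, model)
        assert np.allclose(probs, 1.0)


def _train_setup(n=60, m=20, g=3, seed=0, **cfg_kw):
    from omicbridge.graph import ProximityParams, build_hybrid_graph, cca_project
    from omicbridge.simulate import SimScenario, simulate

    scn = SimScenario(n_src=n, n_tgt=n, n_clusters=g, latent_dim=g + 2,
                      n_features=m, separation=10.0, seed=seed)
    src, slab, tgt, tlab, _ = simulate(scn)
    proj = cca_project(src, tgt, d_cca=5)
    graph = build_hybrid_graph(proj, ProximityParams(k_mnn=5))
    cfg = TrainConfig(epochs_stage1=8, epochs_stage2=40, seed=seed, **cfg_kw)
    ae = AutoencoderConfig(n_sub=4, latent_dim=8, hidden=8)
    return src, slab, tgt, tlab, graph, ae, cfg


class TestTraining:
    def test_seeded_runs_bit_identical(self):
        src, slab, tgt, _, graph, ae, cfg = _train_setup()
        s1, e1 = train(src, slab, tgt, graph, ae, None, cfg)
        s2, e2 = train(src, slab, tgt, graph, ae, None, cfg)
        assert s1.loss_trace_stage2[-1] == s2.loss_trace_stage2[-1]
        assert np.array_equal(e1.values, e2.values)

    def test_supervised_reduction_fits_separated_clusters(self):
        # no alignment losses, identity graph: a plain supervised classifier
        src, slab, tgt, _, graph, ae, cfg = _train_setup(
            n=150, lambda_mmd=0.0, lambda_cos=0.0
        )
        graph.adjacency[:] = 0.0
        graph = normalize_adjacency(graph)
        state, emb = train(src, slab, tgt, graph, ae, None, cfg)
        pred = state.probabilities[: src.n_cells].argmax(axis=1)
        truth = np.array([state.classes.index(l)
                          for l in slab.labels_for(src.cell_ids)])
        assert (pred == truth).mean() >= 0.99

    def test_source_labels_unused_when_ce_off(self):
        src, slab, tgt, _, graph, ae, cfg = _train_setup(lambda_ce=0.0)
        _, e1 = train(src, slab, tgt, graph, ae, None, cfg)
        shuffled = LabelSet(dict(zip(slab.mapping.keys(),
                                     np.roll(list(slab.mapping.values()), 7))))
        _, e2 = train(src, shuffled, tgt, graph, ae, None, cfg)
        assert np.array_equal(e1.values, e2.values)

    def test_stage1_reduces_latent_mmd(self):
        src, slab, tgt, _, graph, ae, cfg = _train_setup(n=100)
        rng = np.random.default_rng(cfg.seed)
        ae0_s = Autoencoder(src.n_features, ae, rng)
        ae0_t = Autoencoder(src.n_features, ae, rng)
        before = mk_mmd(ae0_s.encode(src.values), ae0_t.encode(tgt.values))
        state, _ = train(src, slab, tgt, graph, ae, None, cfg)
        after = mk_mmd(state.ae_src.encode(src.values),
                       state.ae_tgt.encode(tgt.values))
        assert after < before

    def test_smoothed_loss_traces_non_increasing(self):
        src, slab, tgt, _, graph, ae, cfg = _train_setup(n=100)
        cfg.epochs_stage1, cfg.epochs_stage2 = 30, 60
        state, _ = train(src, slab, tgt, graph, ae, None, cfg)
        for trace in (state.loss_trace_stage1, state.loss_trace_stage2):
            sm = np.convolve(trace, np.ones(10) / 10, mode="valid")
            drop = sm[0] - sm[-1]
            assert drop > 0
            assert np.diff(sm).max() <= 0.01 * drop

    def test_divergence_raises(self):
        src, slab, tgt, _, graph, ae, cfg = _train_setup()
        cfg.lr = 1e200  # guaranteed overflow to non-finite
        with pytest.raises(FloatingPointError):
            train(src, slab, tgt, graph, ae, None, cfg)

    def test_mismatched_graph_errors(self):
        src, slab, tgt, _, graph, ae, cfg = _train_setup()
        bad = HybridGraph(graph.n_s - 1, graph.n_t, graph.adjacency[1:, 1:])
        with pytest.raises(ValueError, match="node counts"):
            train(src, slab, tgt, normalize_adjacency(bad), ae, None, cfg)


def test_alignment_gain_never_improves_with_larger_shift():
    """Mean matched-pair cosine after stage-1 alignment does not increase
    as the systematic modality shift grows (paired data, 3 seeds)."""
    from omicbridge.graph import ProximityParams, build_hybrid_graph, cca_project
    from omicbridge.simulate import SimScenario, simulate

    means = []
    for shift in (0.0, 1.5, 3.0):
        sims = []
        for seed in range(3):
            scn = SimScenario(n_src=80, n_tgt=80, n_clusters=3, latent_dim=6,
                              n_features=40, separation=10.0,
                              modality_shift=shift, paired=True, seed=seed)
            src, slab, tgt, _, pairing = simulate(scn)
            proj = cca_project(src, tgt, d_cca=5)
            graph = build_hybrid_graph(proj, ProximityParams(k_mnn=5))
            cfg = TrainConfig(epochs_stage1=8, epochs_stage2=1, seed=seed)
            state, _ = train(src, slab, tgt, graph,
                             AutoencoderConfig(n_sub=4, latent_dim=8, hidden=8),
                             None, cfg)
            zs = state.ae_src.encode(src.values)
            zt = state.ae_tgt.encode(tgt.values)
            cos = np.sum(zs * zt, axis=1) / (
                np.linalg.norm(zs, axis=1) * np.linalg.norm(zt, axis=1) + 1e-12
            )
            sims.append(cos.mean())
        means.append(np.mean(sims))
    assert means[1] <= means[0] + 0.05
    assert means[2] <= means[0] + 0.05
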
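"""The spectral attention encoder: reduction to plain attention, an
independent dense re-evaluation oracle, equivariance, readout stability,
heads, and checkpointing."""

import numpy as np
import pytest

from specmol.autograd import Tensor
from specmol.fixtures import cliff_pair_generator
from specmol.molgraph import Molecule, build_graph
from specmol.multiview import ViewGraph, make_views
from specmol.network import (DenseOps, EncoderConfig, Model,
                             plain_attention, spectral_attention_block,
                             view_input_features)

PATH3 = [(0, 1), (1, 2)]


def toy_params(rng, d, prefix="enc0", alpha_init=0.1, beta_init=1.0):
    import math
    inv = lambda y: math.log(math.expm1(y))
    p = {}
    for w in ("W_Q", "W_K", "W_V", "W_HF", "W_LF", "W_O"):
        p[f"{prefix}.{w}"] = Tensor(rng.normal(0, 0.3, size=(d, d)),
                                    requires_grad=True)
    p[f"{prefix}.b_O"] = Tensor(np.zeros(d), requires_grad=True)
    p[f"{prefix}.alpha_raw"] = Tensor(np.array(inv(alpha_init)),
                                      requires_grad=True)
    p[f"{prefix}.beta_raw"] = Tensor(np.array(inv(beta_init)),
                                     requires_grad=True)
    return p


def dense_reference(X, ops, params, cfg, prefix="enc0"):
    """Straight-line NumPy re-evaluation of the block equations."""
    softplus = lambda v: np.logaddexp(0.0, v)
    d_k = cfg.d_k
    g = lambda name: params[f"{prefix}.{name}"].data
    HF = ops.ImP @ X @ g("W_HF")
    LF = ops.IpP @ X @ g("W_LF")
    Q = X @ g("W_Q") + HF
    K = X @ g("W_K") + LF
    V = X @ g("W_V")
    alpha = softplus(g("alpha_raw"))
    beta = softplus(g("beta_raw"))
    mod = alpha * ops.LkA / (1.0 + beta * ops.A)
    outs = []
    for h in range(cfg.n_heads):
        sl = slice(h * d_k, (h + 1) * d_k)
        logits = Q[:, sl] @ K[:, sl].T / np.sqrt(d_k)
        e = np.exp(logits - logits.max(axis=1, keepdims=True))
        S = e / e.sum(axis=1, keepdims=True)
        M = S + mod
        outs.append(M @ V[:, sl] + HF[:, sl] + LF[:, sl])
    return np.concatenate(outs, axis=1) @ g("W_O") + g("b_O")


class TestSpectralAttentionBlock:
    def test_matches_dense_reference(self, rng):
        cfg = EncoderConfig(d_model=8, n_heads=2, n_layers=1,
                            transformer_layers=0)
        ops = DenseOps.from_edges(PATH3, 3, k=2)
        params = toy_params(rng, 8)
        X = rng.normal(size=(3, 8))
        out = spectral_attention_block(Tensor(X), ops, cfg, params, "enc0")
        ref = dense_reference(X, ops, params, cfg)
        assert np.abs(out.data - ref).max() < 1e-8

    def test_ablated_equals_plain_attention(self, rng):
        cfg = EncoderConfig(d_model=8, n_heads=2, n_layers=1,
                            transformer_layers=0, use_HF=False,
                            use_LF=False, use_MA=False)
        ops = DenseOps.from_edges(PATH3, 3, k=2)
        params = toy_params(rng, 8)
        X = Tensor(rng.normal(size=(3, 8)))
        out = spectral_attention_block(X, ops, cfg, params, "enc0")
        ref = plain_attention(X, cfg, params, "enc0")
        assert np.abs(out.data - ref.data).max() < 1e-8

    def test_attention_rows_stochastic(self, rng):
        cfg = EncoderConfig(d_model=8, n_heads=2, n_layers=1,
                            transformer_layers=0)
        ops = DenseOps.from_edges(PATH3, 3, k=2)
        params = toy_params(rng, 8)
        collect = {}
        params["__collect__"] = collect
        spectral_attention_block(Tensor(rng.normal(size=(3, 8))), ops, cfg,
                                 params, "enc0")
        assert collect["S"]
        for S in collect["S"]:
            np.testing.assert_allclose(S.sum(axis=1), np.ones(3), atol=1e-6)

    def test_single_node_reduces_to_projections(self, rng):
        """Isolated node: P = 0, so HF = LF = X W and attention is a
        1x1 softmax; the output is V + HF + LF exactly."""
        cfg = EncoderConfig(d_model=4, n_heads=1, n_layers=1,
                            transformer_layers=0)
        ops = DenseOps.from_edges([], 1, k=2)
        params = toy_params(rng, 4)
        x = rng.normal(size=(1, 4))
        out = spectral_attention_block(Tensor(x), ops, cfg, params, "enc0")
        hf = x @ params["enc0.W_HF"].data
        lf = x @ params["enc0.W_LF"].data
        expected = (x @ params["enc0.W_V"].data + hf + lf) \
            @ params["enc0.W_O"].data
        assert np.abs(out.data - expected).max() < 1e-10

    @pytest.mark.parametrize("rule", ["modulated_div", "sum_div", "scaled_lk"])
    def test_message_rules_finite(self, rule, rng):
        cfg = EncoderConfig(d_model=8, n_heads=2, n_layers=1,
                            transformer_layers=0, message_rule=rule)
        ops = DenseOps.from_edges(PATH3, 3, k=2)
        out = spectral_attention_block(Tensor(rng.normal(size=(3, 8))), ops,
                                       cfg, toy_params(rng, 8), "enc0")
        assert np.all(np.isfinite(out.data))


class TestEncodeView:
    def test_deterministic_across_calls(self, small_model, graph_of):
        g = graph_of("CC(=O)O")
        b = make_views(g)
        h1 = small_model.encode_view(b.functional_group, g)
        h2 = small_model.encode_view(b.functional_group, g)
        assert np.array_equal(h1.data, h2.data)

    def test_shared_parameter_store(self, small_model):
        """All three views are encoded by the same parameter objects."""
        names = {n for n in small_model.params if n.startswith("enc")}
        assert names  # one stack of encoder blocks, no per-view copies
        assert not any("scaffold" in n or "pharm" in n or "functional" in n
                       for n in small_model.params)

    def test_views_identical_when_annotations_zeroed(self, small_model,
                                                     graph_of):
        g = graph_of("Oc1ccccc1")
        b = make_views(g)
        stripped = []
        for v in (b.functional_group, b.pharmacophore):
            stripped.append(ViewGraph(
                kind=v.kind, n_atoms=v.n_atoms, edge_list=v.edge_list,
                annotation=np.zeros_like(v.annotation),
                member_mask=np.zeros(v.n_atoms, dtype=bool)))
        h_f = small_model.encode_view(stripped[0], g)
        h_p = small_model.encode_view(stripped[1], g)
        assert np.array_equal(h_f.data, h_p.data)

    def test_edgeless_view_encodes_atoms_independently(self, small_model,
                                                       graph_of):
        """With no edges, each atom's embedding depends on its own row
        only: permuting input rows permutes output rows."""
        g = graph_of("CCO")
        b = make_views(g)
        scaf = b.scaffold          # ethanol: empty scaffold, no edges
        X0 = view_input_features(scaf, g)
        ops = small_model.view_operators(scaf)
        h = small_model.encode_view(scaf, g, ops=ops, X0=X0)
        perm = np.array([2, 0, 1])
        h_p = small_model.encode_view(scaf, g, ops=ops, X0=X0[perm])
        np.testing.assert_allclose(h_p.data, h.data[perm], atol=1e-10)


class TestFuseAndTransform:
    def test_single_atom_two_tokens(self, small_model, rng):
        d = small_model.cfg.d_model
        H = [Tensor(rng.normal(size=(1, d))) for _ in range(3)]
        out = small_model.fuse_and_transform(*H)
        assert out.shape == (2, d)

    def test_zero_transformer_layers_identity(self, rng):
        cfg = EncoderConfig(d_model=16, n_heads=2, n_layers=1,
                            transformer_layers=0)
        m = Model(cfg, 1, ["regression"], seed=0)
        H = [Tensor(rng.normal(size=(4, 16))) for _ in range(3)]
        out = m.fuse_and_transform(*H)
        fused = np.concatenate([h.data for h in H], axis=1) \
            @ m.params["fuse.W"].data + m.params["fuse.b"].data
        np.testing.assert_allclose(out.data[:4], fused, atol=1e-12)
        np.testing.assert_allclose(out.data[4], m.params["global_token"].data[0])

    def test_permutation_equivariance(self, small_model, rng):
        d = small_model.cfg.d_model
        H = [rng.normal(size=(5, d)) for _ in range(3)]
        out = small_model.fuse_and_transform(*[Tensor(h) for h in H]).data
        perm = rng.permutation(5)
        out_p = small_model.fuse_and_transform(
            *[Tensor(h[perm]) for h in H]).data
        np.testing.assert_allclose(out_p[:5], out[perm], atol=1e-8)
        np.testing.assert_allclose(out_p[5], out[5], atol=1e-8)

    def test_misaligned_views_rejected(self, small_model, rng):
        d = small_model.cfg.d_model
        with pytest.raises(ValueError):
            small_model.fuse_and_transform(Tensor(rng.normal(size=(3, d))),
                                           Tensor(rng.normal(size=(4, d))),
                                           Tensor(rng.normal(size=(3, d))))


class TestReadout:
    def test_single_atom_finite(self, small_model, rng):
        d = small_model.cfg.d_model
        H = Tensor(rng.normal(size=(2, d)))   # one atom + global
        out = small_model.gru_readout(H, 1)
        assert out.shape == (d,)
        assert np.all(np.isfinite(out.data))

    def test_canonical_order_stability_across_spellings(self, small_model):
        outs = []
        for smiles in ("OCC", "CCO"):
            g = build_graph(Molecule.from_smiles(smiles))
            rec = small_model.prepare(g)
            outs.append(small_model.forward(rec)["graph_embedding"].data)
        np.testing.assert_array_equal(outs[0], outs[1])

    def test_zero_weights_no_nan(self, small_cfg, rng):
        m = Model(small_cfg, 1, ["regression"], seed=1)
        for k, p in m.params.items():
            if k.startswith(("gru.", "readout.")):
                p.data = np.zeros_like(p.data)
        out = m.gru_readout(Tensor(rng.normal(size=(4, 16))), 3)
        assert np.all(np.isfinite(out.data))

    def test_empty_molecule_rejected(self, small_model, rng):
        with pytest.raises(ValueError):
            small_model.gru_readout(Tensor(rng.normal(size=(1, 16))), 0)


class TestPredict:
    def test_zero_weight_classification_head_gives_half(self, small_cfg, rng):
        m = Model(small_cfg, 1, ["classification"], seed=0)
        m.params["head0.W"].data[:] = 0.0
        m.params["head0.b"].data[:] = 0.0
        p = m.predict(Tensor(rng.normal(size=32)))[0]
        assert p.data.item() == pytest.approx(0.5)

    def test_task_count(self, small_cfg, rng):
        m = Model(small_cfg, 3, ["regression", "classification",
                                 "regression"], seed=0)
        outs = m.predict(Tensor(rng.normal(size=32)))
        assert len(outs) == 3

    def test_logit_probability_consistency(self, small_cfg, rng):
        m = Model(small_cfg, 1, ["classification"], seed=0)
        rep = Tensor(rng.normal(size=32))
        p = m.predict(rep)[0].data.item()
        z = m.predict_logit(rep, 0).data.item()
        assert np.log(p / (1 - p)) == pytest.approx(z, abs=1e-6)

    def test_task_type_mismatch_rejected(self, small_cfg):
        with pytest.raises(ValueError):
            Model(small_cfg, 2, ["regression"], seed=0)


class TestCheckpoint:
    def test_save_load_bit_exact(self, small_cfg, tmp_path):
        m = Model(small_cfg, 2, ["regression", "classification"], seed=3)
        path = tmp_path / "ckpt.npz"
        m.save(path, extra={"epoch": 7})
        m2 = Model.load(path)
        assert m2.cfg == m.cfg
        assert Model.load_meta(path)["extra"]["epoch"] == 7
        for k in m.params:
            assert np.array_equal(m.params[k].data, m2.params[k].data), k

    def test_corrupt_checkpoint_raises(self, tmp_path):
        bad = tmp_path / "bad.npz"
        bad.write_bytes(b"this is not a checkpoint")
        with pytest.raises(IOError):
            Model.load(bad)


class TestCliffSensitivityPlumbing:
    def test_hf_path_difference_localized(self, small_model):
        """For a matched pair differing by one atom, the first-block
        high-frequency activations differ only on the closed 1-hop
        neighborhood of the substituted atom."""
        pair = cliff_pair_generator(4, seed=2)[0]
        amap = dict(pair.atom_map)
        recs = [small_model.prepare(build_graph(m))
                for m in (pair.mol_low, pair.mol_high)]
        collects = [{} for _ in recs]
        for rec, col in zip(recs, collects):
            small_model.forward(rec, collect=col)
        checked = 0
        for kind in ("functional_group", "pharmacophore"):
            HF_a = collects[0][kind]["HF"][0]
            HF_b = collects[1][kind]["HF"][0]
            n = HF_a.shape[0]
            inv = {v: k for k, v in amap.items()}
            diff = np.array([np.abs(HF_a[inv[j]] - HF_b[j]).max()
                             for j in range(n)])
            support = set(np.flatnonzero(diff > 1e-10))
            g_b = build_graph(pair.mol_high)
            v = pair.sub_atom_high
            closed = {v} | {int(j) for i, j in g_b.bond_list if i == v} \
                | {int(i) for i, j in g_b.bond_list if j == v}
            assert support <= closed
            assert support, "substitution must actually perturb the HF path"
            checked += 1
        assert checked == 2
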
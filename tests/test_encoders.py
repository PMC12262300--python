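"""Graph construction, message passing, receptive field and encoder variants."""

import copy

import numpy as np
import pytest

from enzrxn.encoders import (
    EncoderConfig,
    aggregate,
    batch_graphs,
    build_reaction_graph,
    embed_graph,
    embed_reaction,
    encode_batch,
    init_encoder_weights,
    message_passing,
    morgan_fingerprint,
)
from enzrxn.reaction_core import ReactionValidationError, parse_reaction

from conftest import mapped

CHAIN_KETONE_REDUCTION = (
    "[CH3:1][CH2:2][CH2:3][CH2:4][CH2:5][CH2:6][C:7](=[O:8])[CH3:9]"
    ">>[CH3:1][CH2:2][CH2:3][CH2:4][CH2:5][CH2:6][CH:7]([OH:8])[CH3:9]"
)


def small_cfg(variant, m=None, seed=0):
    return EncoderConfig(variant=variant, message_passings=m, embedding_dim=16,
                         hidden_dim=16, seed=seed)


class TestGraphConstruction:
    def test_rc_aggregated_adds_virtual_node_wired_to_both_sides(self, pyruvate_reduction):
        g = build_reaction_graph(pyruvate_reduction, "rc_aggregated")
        assert g.n_nodes == 13  # 12 atoms + 1 virtual
        assert g.virtual_index == 12
        virt_edges = [
            (s, d) for s, d in zip(g.src, g.dst) if 12 in (s, d)
        ]
        # 2 RC atoms per side, both directions
        assert len(virt_edges) == 8
        touched = {s for s, d in virt_edges if d == 12}
        assert touched == {1, 2, 7, 8}  # RC atoms on reactant and product sides
        assert np.all(g.node_features[12] == 0)

    def test_bag_of_molecules_has_no_virtual_node(self, pyruvate_reduction):
        g = build_reaction_graph(pyruvate_reduction, "bag_of_molecules")
        assert g.n_nodes == 12 and g.virtual_index is None

    def test_cgr_one_node_per_mapped_pair(self, pyruvate_reduction):
        g = build_reaction_graph(pyruvate_reduction, "cgr")
        assert g.n_nodes == 6
        # ester-bond style formed/broken edges absent here: 5 heavy-atom bonds
        assert len(g.src) == 10

    def test_missing_rc_rejected_for_rc_variants(self):
        r = parse_reaction("[CH3:1][CH3:2]>>[CH3:1][CH3:2]")
        with pytest.raises(ReactionValidationError, match="RC"):
            build_reaction_graph(r, "rc_aggregated")

    def test_virtual_edge_feature_bit_exclusive(self, pyruvate_reduction):
        g = build_reaction_graph(pyruvate_reduction, "rc_connected")
        virt = g.edge_features[:, -1] == 1
        assert np.all(g.edge_features[virt, :-1] == 0)
        assert not np.any(g.edge_features[~virt, -1])


class TestMessagePassing:
    def test_single_atom_graph_any_depth(self):
        r = parse_reaction("C>>C")
        g = build_reaction_graph(r, "bag_of_molecules")
        cfg = small_cfg("bag_of_molecules")
        w = init_encoder_weights(cfg)
        e1 = message_passing(g, w, 1).data
        e5 = message_passing(g, w, 5).data
        assert np.allclose(e1, e5)  # no edges: depth is irrelevant

    def test_symmetric_atoms_get_identical_embeddings(self):
        r = mapped("[CH3:1][C:2](=[O:3])[CH3:4]>>[CH3:1][CH:2]([OH:3])[CH3:4]")
        g = build_reaction_graph(r, "bag_of_molecules")
        cfg = small_cfg("bag_of_molecules")
        emb = message_passing(g, init_encoder_weights(cfg), 4).data
        # the two reactant methyls are graph-automorphic
        assert np.allclose(emb[0], emb[3])

    def test_receptive_field_is_m_minus_one_bonds(self):
        r = mapped(CHAIN_KETONE_REDUCTION)
        cfg = small_cfg("rc_aggregated", m=4, seed=5)
        w = init_encoder_weights(cfg)
        g = build_reaction_graph(r, "rc_aggregated")
        base = embed_graph(g, cfg, w)
        # chain atom indices 3, 2, 1 are 3, 4, 5 bonds from the nearest RC atom
        for idx, expect_change in ((3, True), (2, False), (1, False)):
            gp = copy.deepcopy(g)
            gp.__dict__.pop("_ops_cache", None)
            gp.node_features = g.node_features.copy()
            gp.node_features[idx, -1] += 0.5
            v = embed_graph(gp, cfg, w)
            assert (not np.array_equal(v, base)) == expect_change

    def test_nonfinite_weights_rejected(self, pyruvate_reduction):
        cfg = small_cfg("bag_of_molecules")
        w = init_encoder_weights(cfg)
        w["W_msg"].data[0, 0] = np.nan
        g = build_reaction_graph(pyruvate_reduction, "bag_of_molecules")
        with pytest.raises(ValueError, match="non-finite"):
            message_passing(g, w, 2)


class TestAggregation:
    def test_rc_aggregated_uses_virtual_embedding_only(self, pyruvate_reduction):
        cfg = small_cfg("rc_aggregated")
        w = init_encoder_weights(cfg)
        g = build_reaction_graph(pyruvate_reduction, "rc_aggregated")
        node_emb = message_passing(g, w, cfg.m)
        out = aggregate(node_emb, g, "rc_aggregated", w).data[0]
        manual = node_emb.data[g.virtual_index] @ w["W_out"].data
        assert np.allclose(out, manual)

    def test_mean_variants_exclude_virtual_node(self, pyruvate_reduction):
        cfg = small_cfg("rc_connected")
        w = init_encoder_weights(cfg)
        g = build_reaction_graph(pyruvate_reduction, "rc_connected")
        node_emb = message_passing(g, w, cfg.m)
        out = aggregate(node_emb, g, "rc_connected", w).data[0]
        manual = node_emb.data[:12].mean(axis=0) @ w["W_out"].data
        assert np.allclose(out, manual)

    def test_rc_connected_with_virtual_edges_removed_equals_bag(self, pyruvate_reduction):
        cfg = small_cfg("rc_connected", seed=9)
        w = init_encoder_weights(cfg)
        g = build_reaction_graph(pyruvate_reduction, "rc_connected")
        keep = np.array(
            [g.virtual_index not in (s, d) for s, d in zip(g.src, g.dst)]
        )
        g2 = copy.deepcopy(g)
        g2.__dict__.pop("_ops_cache", None)
        old_idx = np.flatnonzero(keep)
        remap = {o: n for n, o in enumerate(old_idx)}
        g2.src, g2.dst = g.src[keep], g.dst[keep]
        g2.rev = np.array([remap[r] for r in g.rev[keep]])
        g2.edge_features = g.edge_features[keep]
        ablated = embed_graph(g2, cfg, w)

        gb = build_reaction_graph(pyruvate_reduction, "bag_of_molecules")
        node_emb = message_passing(gb, w, cfg.m)
        bag = aggregate(node_emb, gb, "bag_of_molecules", w).data[0]
        assert np.allclose(ablated, bag)

    def test_variant_graph_mismatch_rejected(self, pyruvate_reduction):
        cfg = small_cfg("bag_of_molecules")
        w = init_encoder_weights(cfg)
        g = build_reaction_graph(pyruvate_reduction, "bag_of_molecules")
        node_emb = message_passing(g, w, 2)
        with pytest.raises(ValueError, match="built for"):
            aggregate(node_emb, g, "rc_aggregated", w)


class TestMorgan:
    def test_identity_reaction_cancels_to_zero(self):
        r = parse_reaction("CCO>>CCO")
        assert np.all(morgan_fingerprint(r) == 0)

    def test_side_swap_invariance(self, ester_hydrolyses):
        me, _ = ester_hydrolyses
        fwd = morgan_fingerprint(me)
        import dataclasses

        rev = dataclasses.replace(me, reactants=me.products, products=me.reactants)
        assert np.array_equal(fwd, morgan_fingerprint(rev))

    def test_methyl_vs_ethyl_differ_only_near_extension(self, ester_hydrolyses):
        me, et = ester_hydrolyses
        a, b = morgan_fingerprint(me), morgan_fingerprint(et)
        assert np.any(a != b)
        # the shared acetyl environments cancel identically on both sides
        assert (a != b).sum() < 2048 / 4

    def test_projection_linearity(self):
        cfg = small_cfg("morgan")
        w = init_encoder_weights(cfg)
        v = np.random.default_rng(0).poisson(1.0, size=(1, 2048)).astype(float)
        from enzrxn import autodiff as ad
        from enzrxn.autodiff import Tensor

        one = ad.matmul(Tensor(v), w["W_proj"]).data
        three = ad.matmul(Tensor(3 * v), w["W_proj"]).data
        assert np.allclose(three, 3 * one)


class TestEmbedReaction:
    @pytest.mark.parametrize(
        "variant", ["rc_aggregated", "rc_connected", "bag_of_molecules", "cgr", "morgan"]
    )
    def test_permutation_invariance(self, variant):
        r1 = mapped("[CH3:1][C:2](=[O:3])[CH3:4]>>[CH3:1][CH:2]([OH:3])[CH3:4]", "a")
        r2 = mapped("[CH3:4][C:2](=[O:3])[CH3:1]>>[OH:3][CH:2]([CH3:4])[CH3:1]", "b")
        cfg = small_cfg(variant, seed=1)
        w = init_encoder_weights(cfg)
        assert np.allclose(embed_reaction(r1, cfg, w), embed_reaction(r2, cfg, w))

    def test_side_swap_changes_gnn_embedding(self, pyruvate_reduction):
        import dataclasses

        cfg = small_cfg("bag_of_molecules", seed=2)
        w = init_encoder_weights(cfg)
        r = pyruvate_reduction
        rev = dataclasses.replace(
            r,
            reactants=r.products,
            products=r.reactants,
            rc_reactant_atoms=r.rc_product_atoms,
            rc_product_atoms=r.rc_reactant_atoms,
        )
        assert not np.allclose(embed_reaction(r, cfg, w), embed_reaction(rev, cfg, w))

    def test_regression_locked_fingerprint_of_fixed_seed_model(self, pyruvate_reduction):
        """Frozen first-run checksum guards against silent numeric drift."""
        cfg = small_cfg("rc_aggregated", m=4, seed=7)
        w = init_encoder_weights(cfg)
        v = embed_reaction(pyruvate_reduction, cfg, w)
        assert float(np.abs(v).sum()) == pytest.approx(27.221567141810997, abs=1e-6)
        assert float(v[:3] @ np.ones(3)) == pytest.approx(0.8327156163230249, abs=1e-7)

    def test_batched_encoding_matches_single(self, small_reactions):
        reactions, _ = small_reactions
        subset = reactions[:6]
        for variant in ("rc_aggregated", "bag_of_molecules"):
            cfg = small_cfg(variant, seed=3)
            w = init_encoder_weights(cfg)
            batch = batch_graphs([build_reaction_graph(r, variant) for r in subset])
            B = encode_batch(batch, cfg, w).data
            for k, r in enumerate(subset):
                assert np.allclose(B[k], embed_reaction(r, cfg, w))

    def test_gradient_reaches_every_weight_matrix(self, pyruvate_reduction):
        from enzrxn import autodiff as ad

        for variant in ("rc_aggregated", "bag_of_molecules", "cgr"):
            cfg = small_cfg(variant, seed=4)
            w = init_encoder_weights(cfg)
            batch = batch_graphs([build_reaction_graph(pyruvate_reduction, variant)])
            out = encode_batch(batch, cfg, w).sum()
            out.backward()
            for name, t in w.items():
                assert t.grad is not None and np.any(t.grad != 0), (variant, name)
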
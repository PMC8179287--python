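"""Selectivity model: encoder oracle, attention closed forms, fusion,
pooling, scoring, latents, and the ablation separation of the modes."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from regioml import nn
from regioml.descriptors import default_rbf_specs
from regioml.errors import (
    DegenerateRecord,
    LengthMismatch,
    MissingDescriptor,
    UnresolvedMapNumber,
)
from regioml.fixtures import OracleSpec, oracle_table
from regioml.mol_graph import canonical_smiles
from regioml.records import CandidateOutcome, ReactionRecord, load_reaction_dataset, save_reaction_dataset
from regioml.selectivity import (
    DescriptorSource,
    SelectivityConfig,
    SelectivityModel,
    SelectivityNet,
    candidate_logits,
    encode_reactants,
    fuse_qm,
    global_attention,
    latent_distance,
    pool_reacting_pair,
    prepare_record,
    wln_encode,
)


def _gnn_prep(record, cfg):
    return prepare_record(record, "GNN", default_rbf_specs(cfg.rbf_dim), None, cfg)


class TestWLNEncoder:
    def test_one_round_matches_hand_computation(self, toy_records):
        """a(1)_v = relu(U1 a(0)_v + sum_u relu(V [a(0)_u ; f_uv])) recomputed
        with plain NumPy."""
        cfg = SelectivityConfig(hidden=6, depth=1)
        net = SelectivityNet(cfg, "GNN", np.random.default_rng(8))
        prep = _gnn_prep(toy_records[0], cfg)
        a = wln_encode(net, prep.X, prep.src, prep.dst, prep.Ef)

        relu = lambda x: np.maximum(x, 0.0)
        a0 = relu(prep.X @ net.W0.W.data + net.W0.b.data)
        msg = relu(
            np.concatenate([a0[prep.src], prep.Ef], axis=1) @ net.V.W.data + net.V.b.data
        )
        nbr = np.zeros_like(a0)
        np.add.at(nbr, prep.dst, msg)
        a1 = relu(a0 @ net.U1.W.data + net.U1.b.data + nbr)
        assert np.allclose(a.data, a1)

    def test_zero_rounds_depend_on_atom_features_only(self, toy_records):
        cfg = SelectivityConfig(hidden=6, depth=0)
        net = SelectivityNet(cfg, "GNN", np.random.default_rng(8))
        prep = _gnn_prep(toy_records[0], cfg)
        a = wln_encode(net, prep.X, prep.src, prep.dst, prep.Ef)
        relu = lambda x: np.maximum(x, 0.0)
        assert np.allclose(a.data, relu(prep.X @ net.W0.W.data + net.W0.b.data))

    def test_benzene_embeddings_identical_across_atoms(self):
        rec = ReactionRecord(
            "r", "[cH:1]1[cH:2][cH:3][cH:4][cH:5][cH:6]1.[Br:7][Br:8]",
            [CandidateOutcome((1, 7), "Brc1ccccc1"), CandidateOutcome((2, 7), "Brc1ccccc1")],
            0,
        )
        cfg = SelectivityConfig(hidden=8, depth=2)
        net = SelectivityNet(cfg, "GNN", np.random.default_rng(0))
        prep = _gnn_prep(rec, cfg)
        emb = encode_reactants(net, prep).data
        assert np.allclose(emb[:6], emb[0])  # six equivalent ring atoms


class TestGlobalAttention:
    def test_zeroed_logits_give_uniform_weights_and_mean_context(self, toy_records):
        cfg = SelectivityConfig(hidden=5, depth=1)
        net = SelectivityNet(cfg, "GNN", np.random.default_rng(2))
        net.Wq.W.data[:] = 0.0  # kills all attention logits
        prep = _gnn_prep(toy_records[1], cfg)
        a = wln_encode(net, prep.X, prep.src, prep.dst, prep.Ef)
        ctx, alpha = global_attention(net, a)
        n = a.data.shape[0]
        assert np.allclose(alpha.data, 1.0 / n)
        v = a.data @ net.Wv.W.data
        assert np.allclose(ctx.data, np.tile(v.mean(axis=0), (n, 1)))

    def test_single_atom_attends_to_itself(self):
        cfg = SelectivityConfig(hidden=4, depth=0)
        net = SelectivityNet(cfg, "GNN", np.random.default_rng(2))
        a = nn.Tensor(np.random.default_rng(0).normal(size=(1, 4)))
        ctx, alpha = global_attention(net, a)
        assert np.allclose(alpha.data, [[1.0]])
        assert np.allclose(ctx.data, a.data @ net.Wv.W.data)


class TestFusionAndPooling:
    def test_fused_width_is_embedding_plus_four_rbf_blocks(self, toy_records, toy_table):
        cfg = SelectivityConfig(hidden=16, depth=1, rbf_dim=8)
        net = SelectivityNet(cfg, "QM-GNN", np.random.default_rng(0))
        prep = prepare_record(
            toy_records[0], "QM-GNN", default_rbf_specs(8), DescriptorSource(toy_table), cfg
        )
        emb = encode_reactants(net, prep)
        fused = fuse_qm(emb, prep.qm_block)
        assert fused.data.shape[1] == 16 + 4 * 8

    def test_fused_rep_reflects_descriptors_not_just_graph(self, toy_records, toy_table):
        cfg = SelectivityConfig(hidden=8, depth=1, rbf_dim=8)
        prep = prepare_record(
            toy_records[0], "QM-GNN", default_rbf_specs(8), DescriptorSource(toy_table), cfg
        )
        # atoms with distinct descriptors yield distinct QM blocks
        assert prep.qm_block.std(axis=0).max() > 0

    def test_pair_pooling_symmetric_and_additive(self):
        fused = np.random.default_rng(0).normal(size=(5, 7))
        assert np.allclose(pool_reacting_pair(fused, (1, 3)), pool_reacting_pair(fused, (3, 1)))
        assert np.allclose(pool_reacting_pair(fused, (2, 2)), 2 * fused[2])
        assert np.allclose(pool_reacting_pair(np.zeros((4, 3)), (0, 1)), 0.0)


class TestScoring:
    def test_scores_sum_to_one_and_single_candidate_is_certain(self, toy_records, toy_table):
        model = SelectivityModel(
            list(toy_records[:8]), mode="QM-GNN", descriptor_source=toy_table,
            config=SelectivityConfig(hidden=8, depth=1, epochs=0),
        )
        res = model.fit(seed=0, epochs=0)
        for rec in toy_records[:8]:
            s = res.predict(rec)
            assert s.scores.min() >= 0 and s.scores.max() <= 1
            assert s.scores.sum() == pytest.approx(1.0)
        single = ReactionRecord(
            "s", toy_records[0].reactant_smiles, [toy_records[0].candidates[0]], 0
        )
        assert np.allclose(res.predict(single).scores, [1.0])

    def test_identical_candidates_share_the_score(self):
        rec = ReactionRecord(
            "r", "[cH:1]1[cH:2][cH:3][cH:4][cH:5][cH:6]1.[Br:7][Br:8]",
            [CandidateOutcome((1, 7), "Brc1ccccc1"), CandidateOutcome((2, 7), "Brc1ccccc1")],
            0,
        )
        model = SelectivityModel(
            [rec], mode="GNN", config=SelectivityConfig(hidden=8, depth=2, epochs=0)
        )
        res = model.fit(seed=3, epochs=0)
        assert np.allclose(res.predict(rec).scores, [0.5, 0.5])

    def test_uniform_initial_loss_is_log_k(self, toy_records):
        cfg = SelectivityConfig(hidden=8, depth=1)
        net = SelectivityNet(cfg, "GNN", np.random.default_rng(0))
        net.scorer.layers[-1].W.data[:] = 0.0
        net.scorer.layers[-1].b.data[:] = 0.0
        prep = _gnn_prep(toy_records[0], cfg)
        loss = nn.cross_entropy_logits(candidate_logits(net, prep), prep.major)
        assert loss.data == pytest.approx(np.log(len(toy_records[0].candidates)))

    def test_degenerate_record_rejected_at_load(self, toy_records):
        bad = ReactionRecord("d", toy_records[0].reactant_smiles,
                             [toy_records[0].candidates[0]], 0)
        with pytest.raises(DegenerateRecord):
            SelectivityModel([bad], mode="GNN")

    def test_unresolved_map_number_raises(self, toy_records):
        rec = toy_records[0]
        bad = ReactionRecord(
            "u", rec.reactant_smiles,
            [CandidateOutcome((999, 1), rec.candidates[0].product_smiles),
             rec.candidates[1]],
            0,
        )
        with pytest.raises(UnresolvedMapNumber):
            bad.validate()

    def test_missing_descriptor_table_entry_surfaces(self, toy_records):
        from regioml.descriptors import DescriptorTable

        with pytest.raises(MissingDescriptor):
            model = SelectivityModel(
                list(toy_records[:2]), mode="QM-GNN", descriptor_source=DescriptorTable(),
                config=SelectivityConfig(epochs=0),
            )
            model.fit(seed=0, epochs=0)


class TestLatents:
    def test_latent_distance_examples_and_errors(self):
        assert latent_distance([1.0, 2.0], [1.0, 2.0]) == 0.0
        assert latent_distance([0.0, 0.0], [3.0, 4.0]) == pytest.approx(5.0)
        with pytest.raises(LengthMismatch):
            latent_distance([1.0], [1.0, 2.0])

    @settings(deadline=None, max_examples=30)
    @given(st.integers(0, 2**31 - 1))
    def test_triangle_inequality(self, seed):
        rng = np.random.default_rng(seed)
        u, v, w = rng.normal(size=(3, 6))
        assert latent_distance(u, w) <= latent_distance(u, v) + latent_distance(v, w) + 1e-12

    def test_latent_dimension_and_symmetric_sites(self, toy_records):
        cfg = SelectivityConfig(hidden=8, depth=1, latent=12, epochs=0)
        rec = ReactionRecord(
            "r", "[cH:1]1[cH:2][cH:3][cH:4][cH:5][cH:6]1.[Br:7][Br:8]",
            [CandidateOutcome((1, 7), "Brc1ccccc1"), CandidateOutcome((3, 7), "Brc1ccccc1")],
            0,
        )
        res = SelectivityModel([rec], mode="GNN", config=cfg).fit(seed=0, epochs=0)
        v1 = res.extract_latent(rec, 0)
        v2 = res.extract_latent(rec, 1)
        assert v1.shape == (12,)
        assert latent_distance(v1, v2) == pytest.approx(0.0, abs=1e-10)
        with pytest.raises(IndexError):
            res.extract_latent(rec, 5)


class TestAblationSeparation:
    def test_poisoned_table_changes_qm_modes_but_not_gnn(self, toy_records, toy_table):
        """Strict mode separation: descriptor poisoning must alter QM and
        QM-GNN scores and leave GNN scores bitwise unchanged."""
        import copy

        poisoned = copy.deepcopy(toy_table)
        for _, d in poisoned.items():
            d.fukui_nuc = d.fukui_nuc[::-1].copy()
            d.charge = -d.charge
        records = list(toy_records[:6])
        cfg = SelectivityConfig(hidden=8, depth=1, epochs=0)

        def scores(mode, table):
            model = SelectivityModel(records, mode=mode, descriptor_source=table, config=cfg)
            res = model.fit(seed=1, epochs=0)
            return np.concatenate([res.predict(r).scores for r in records])

        assert np.array_equal(scores("GNN", None), scores("GNN", poisoned))
        assert not np.allclose(scores("QM", toy_table), scores("QM", poisoned))
        assert not np.allclose(scores("QM-GNN", toy_table), scores("QM-GNN", poisoned))

    def test_fp_mode_runs_without_descriptors(self, toy_records):
        res = SelectivityModel(
            list(toy_records[:6]), mode="FP",
            config=SelectivityConfig(epochs=1, ffnn_hidden=16, latent=8),
        ).fit(seed=0, epochs=1)
        s = res.predict(toy_records[0])
        assert s.scores.sum() == pytest.approx(1.0)


class TestDatasetIO:
    def test_reaction_csv_round_trip(self, toy_records, tmp_path):
        path = str(tmp_path / "rx.csv")
        save_reaction_dataset(list(toy_records[:10]), path)
        back = load_reaction_dataset(path)
        assert len(back) == 10
        for a, b in zip(toy_records[:10], back):
            assert a.reactant_smiles == b.reactant_smiles
            assert a.major_index == b.major_index
            assert [c.pair for c in a.candidates] == [c.pair for c in b.candidates]
            assert a.yield_pct == pytest.approx(b.yield_pct)

    def test_null_labels_are_unlearnable(self, toy_records, toy_table):
        """Permuted major labels leave held-out accuracy near the random
        baseline mean(1/k)."""
        rng = np.random.default_rng(0)
        shuffled = []
        for r in toy_records[:80]:
            wrong = int(rng.integers(len(r.candidates)))
            shuffled.append(
                ReactionRecord(r.reaction_id, r.reactant_smiles, r.candidates, wrong,
                               r.yield_pct, r.reaction_class)
            )
        train, test = shuffled[:60], shuffled[60:]
        res = SelectivityModel(
            train, mode="QM", descriptor_source=toy_table,
            config=SelectivityConfig(epochs=8),
        ).fit(seed=0)
        acc = res.top1_accuracy(test)
        baseline = np.mean([1 / len(r.candidates) for r in test])
        assert acc < baseline + 0.25
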
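"""Two-tower scorer: closed forms, training behavior, threshold and CV driver."""

import numpy as np
import pytest

from enzrxn.encoders import EncoderConfig
from enzrxn.scoring_model import (
    LossConfig,
    ModelParams,
    ProteinRecord,
    TrainConfig,
    cross_validate,
    init_params,
    load_params,
    save_params,
    score_pair,
    score_pairs,
    select_threshold,
    train,
)

from conftest import mapped

TOY = "[CH3:1][C:2](=[O:3])[CH3:4]>>[CH3:1][CH:2]([OH:3])[CH3:4]"


def tiny_cfg(seed=0, variant="rc_aggregated"):
    return EncoderConfig(variant=variant, embedding_dim=8, hidden_dim=8,
                         message_passings=2, seed=seed)


def toy_protein(vec, pid="p0"):
    return ProteinRecord(id=pid, sequence="ACDEFGHIKL", embedding=np.asarray(vec))


class TestScorePair:
    def test_orthogonal_embeddings_score_half(self):
        r = mapped(TOY)
        cfg = tiny_cfg()
        params = init_params(cfg, protein_dim=4, seed=0)
        # choose a protein embedding in the null space of the projection
        from enzrxn.encoders import embed_reaction

        z_r = embed_reaction(r, cfg, params.encoder_weights)
        W = params.protein_projection.data
        # solve W e ⟂ z_r: pick e orthogonal to W z_r direction via least squares
        v = W @ z_r
        e = np.zeros(4) if np.allclose(v, 0) else np.array([v[1], -v[0], 0, 0])
        assert score_pair(r, toy_protein(e), params) == pytest.approx(0.5)

    def test_log3_norm_scores_three_quarters(self):
        r = mapped(TOY)
        cfg = tiny_cfg(seed=1)
        params = init_params(cfg, protein_dim=8, seed=1)
        from enzrxn.encoders import embed_reaction

        z_r = embed_reaction(r, cfg, params.encoder_weights)
        # engineer W e = z_r * ln3/||z_r||^2 so the dot product is ln 3
        params.protein_projection.data = np.eye(8)
        e = z_r * np.log(3.0) / (z_r @ z_r)
        assert score_pair(r, toy_protein(e), params) == pytest.approx(0.75, abs=1e-12)

    def test_dim_mismatch_rejected(self):
        r = mapped(TOY)
        params = init_params(tiny_cfg(), protein_dim=8)
        with pytest.raises(ValueError, match="dim"):
            score_pair(r, toy_protein(np.ones(5)), params)

    def test_regression_locked_fixed_seed_score(self):
        r = mapped(TOY)
        params = init_params(tiny_cfg(seed=3), protein_dim=6, seed=3)
        s = score_pair(r, toy_protein(np.linspace(-1, 1, 6)), params)
        assert s == pytest.approx(0.8264245938480288, abs=1e-9)


@pytest.fixture(scope="module")
def toy_corpus():
    reactions = {
        "r_red": mapped(TOY, "r_red"),
        "r_est": mapped(
            "[CH3:1][C:2](=[O:3])[O:4][CH3:5].[OH2:6]"
            ">>[CH3:1][C:2](=[O:3])[OH:6].[CH3:5][OH:4]",
            "r_est",
        ),
    }
    rng = np.random.default_rng(0)
    proteins = {
        f"p{i}": ProteinRecord(f"p{i}", "ACDEFGHIKL", rng.normal(size=16))
        for i in range(4)
    }
    return reactions, proteins


class TestTrain:
    def test_memorizes_one_positive_one_negative(self, toy_corpus):
        reactions, proteins = toy_corpus
        pairs = [("p0", "r_red", 1), ("p1", "r_red", 0)]
        params, logs = train(
            pairs, reactions, proteins, tiny_cfg(),
            TrainConfig(epochs=200, batch_size=2, seed=0),
        )
        assert logs[-1].train_loss < 0.05
        # loss broadly decreasing after warmup
        assert logs[-1].train_loss < logs[5].train_loss

    def test_same_seed_identical_weights(self, toy_corpus):
        reactions, proteins = toy_corpus
        pairs = [("p0", "r_red", 1), ("p1", "r_red", 0),
                 ("p2", "r_est", 1), ("p3", "r_est", 0)]
        runs = []
        for _ in range(2):
            params, _ = train(
                pairs, reactions, proteins, tiny_cfg(),
                TrainConfig(epochs=10, batch_size=4, seed=5),
            )
            runs.append(np.concatenate([p.data.ravel() for p in params.parameters()]))
        assert np.array_equal(runs[0], runs[1])

    def test_scores_move_with_projection_scaling(self, toy_corpus):
        reactions, proteins = toy_corpus
        params = init_params(tiny_cfg(seed=2), protein_dim=16, seed=2)
        pairs = [("p0", "r_red"), ("p1", "r_est")]
        base = score_pairs(pairs, reactions, proteins, params)
        params.protein_projection.data *= 3.0
        scaled = score_pairs(pairs, reactions, proteins, params)
        assert np.all(np.abs(scaled - 0.5) >= np.abs(base - 0.5))


class TestSelectThreshold:
    def test_separated_scores_smallest_gap_midpoint(self):
        tau = select_threshold([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1])
        assert tau == pytest.approx(0.5)

    def test_enumerated_midpoint_rule(self):
        # best F1 of 1.0 at the 0.2/0.8 midpoint; smaller candidates give FP
        tau = select_threshold([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1])
        assert tau not in (0.15, 0.85)

    def test_degenerate_identical_scores(self):
        tau = select_threshold([0.4, 0.4, 0.4], [0, 1, 1])
        assert tau == pytest.approx(0.2)  # midpoint with the 0 bound

    def test_one_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            select_threshold([0.1, 0.9], [1, 1])


class TestCrossValidate:
    def _folds(self, toy_corpus):
        reactions, proteins = toy_corpus
        return {
            0: [("p0", "r_red", 1), ("p1", "r_red", 0)],
            1: [("p2", "r_est", 1), ("p3", "r_est", 0)],
            2: [("p0", "r_est", 1), ("p2", "r_red", 0)],
        }

    def test_single_cell_grid_returns_that_cell(self, toy_corpus):
        reactions, proteins = toy_corpus
        best, table = cross_validate(
            self._folds(toy_corpus), reactions, proteins, tiny_cfg(),
            grid=[{"message_passings": 2}],
            train_cfg=TrainConfig(epochs=3, batch_size=4, seed=0),
        )
        assert best == {"message_passings": 2}
        assert len(table) == 1 and table[0].per_fold_f1

    def test_identical_cells_first_wins(self, toy_corpus):
        reactions, proteins = toy_corpus
        grid = [{"seed": 1}, {"seed": 1}]
        best, table = cross_validate(
            self._folds(toy_corpus), reactions, proteins, tiny_cfg(),
            grid=grid, train_cfg=TrainConfig(epochs=2, batch_size=4, seed=0),
        )
        assert best is grid[0]

    def test_empty_grid_rejected(self, toy_corpus):
        reactions, proteins = toy_corpus
        with pytest.raises(ValueError, match="empty"):
            cross_validate(self._folds(toy_corpus), reactions, proteins,
                           tiny_cfg(), grid=[])


class TestCheckpoint:
    def test_roundtrip_preserves_scores(self, toy_corpus, tmp_path):
        reactions, proteins = toy_corpus
        params = init_params(tiny_cfg(seed=4), protein_dim=16, seed=4)
        params.threshold = 0.37
        path = tmp_path / "ckpt.npz"
        save_params(str(path), params)
        loaded = load_params(str(path))
        assert loaded.threshold == 0.37
        pairs = [("p0", "r_red"), ("p3", "r_est")]
        assert np.allclose(
            score_pairs(pairs, reactions, proteins, params),
            score_pairs(pairs, reactions, proteins, loaded),
        )
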
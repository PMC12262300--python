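"""Two-tower enzyme-reaction scorer: joint embeddings, weighted BCE, CV driver.

The protein tower is a precomputed fixed-length sequence embedding (1280-dim
by default, as produced by a protein language model) passed through a single
learned linear map; the reaction tower is one of the encoders in
:mod:`enzrxn.encoders`.  A pair's score is the sigmoid of the dot product of
the two embeddings.  Training minimizes the weighted binary cross entropy

    l(x, y) = -[ m·p·y·log σ(x) + (1 − y)·log(1 − σ(x)) ]

with m the negative multiple and p the positive multiplier (both default 3),
so the positive term carries weight m·p against the 3:1 negative
oversampling of training folds.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np

from . import autodiff as ad
from .autodiff import Adam, Tensor, sigmoid
from .encoders import (
    EncoderConfig,
    batch_graphs,
    build_reaction_graph,
    embed_reaction,
    encode_batch,
    init_encoder_weights,
    morgan_fingerprint,
)
from .reaction_core import Reaction

__all__ = [
    "ProteinRecord",
    "LossConfig",
    "TrainConfig",
    "ModelParams",
    "score_pair",
    "score_pairs",
    "loss",
    "train",
    "select_threshold",
    "cross_validate",
    "save_params",
    "load_params",
]


@dataclass
class ProteinRecord:
    """An enzyme: sequence plus its precomputed embedding vector."""

    id: str
    sequence: str
    embedding: np.ndarray

    def __post_init__(self):
        self.embedding = np.asarray(self.embedding, dtype=np.float64)
        if not np.all(np.isfinite(self.embedding)):
            raise ValueError(f"protein {self.id!r}: non-finite embedding")


@dataclass(frozen=True)
class LossConfig:
    """m = negative multiple, p = positive multiplier of the weighted BCE."""

    m: float = 3.0
    p: float = 3.0

    def __post_init__(self):
        if self.m <= 0 or self.p <= 0:
            raise ValueError("m and p must be positive")

    @property
    def pos_weight(self) -> float:
        return self.m * self.p


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 25
    batch_size: int = 256
    learning_rate: float = 1e-3
    seed: int = 0

    def __post_init__(self):
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")


@dataclass
class ModelParams:
    """All learnable weights of the two-tower scorer plus the decision threshold."""

    protein_projection: Tensor  # (protein_dim, d)
    encoder_weights: dict[str, Tensor]
    encoder_config: EncoderConfig
    threshold: float = 0.5

    def parameters(self) -> list[Tensor]:
        return [self.protein_projection, *self.encoder_weights.values()]


def init_params(
    cfg: EncoderConfig, protein_dim: int = 1280, seed: int | None = None
) -> ModelParams:
    s = cfg.seed if seed is None else seed
    rng = np.random.default_rng(s + 1)
    scale = np.sqrt(6.0 / (protein_dim + cfg.embedding_dim))
    w = rng.uniform(-scale, scale, size=(protein_dim, cfg.embedding_dim))
    return ModelParams(
        protein_projection=Tensor(w, requires_grad=True),
        encoder_weights=init_encoder_weights(replace(cfg, seed=s)),
        encoder_config=cfg,
    )


# ---------------------------------------------------------------------------
# scoring
# ---------------------------------------------------------------------------


def score_pair(r: Reaction, prot: ProteinRecord, params: ModelParams) -> float:
    """σ(⟨reaction embedding, W · protein embedding⟩)."""
    z_r = embed_reaction(r, params.encoder_config, params.encoder_weights)
    if prot.embedding.shape[0] != params.protein_projection.shape[0]:
        raise ValueError(
            f"protein embedding dim {prot.embedding.shape[0]} does not match "
            f"projection input dim {params.protein_projection.shape[0]}"
        )
    z_p = prot.embedding @ params.protein_projection.data
    return float(sigmoid(np.array([z_r @ z_p]))[0])


class _ReactionBank:
    """Precomputed graph/fingerprint batch over a fixed reaction set."""

    def __init__(self, reactions: dict[str, Reaction], cfg: EncoderConfig):
        self.ids = sorted(reactions)
        self.index = {rid: k for k, rid in enumerate(self.ids)}
        self.cfg = cfg
        if cfg.variant == "morgan":
            self.batch = np.stack(
                [
                    morgan_fingerprint(
                        reactions[rid], cfg.morgan_radius, cfg.morgan_nbits
                    )
                    for rid in self.ids
                ]
            )
        else:
            self.batch = batch_graphs(
                [build_reaction_graph(reactions[rid], cfg.variant) for rid in self.ids]
            )

    def embeddings(self, weights: dict[str, Tensor]) -> Tensor:
        return encode_batch(self.batch, self.cfg, weights)


def score_pairs(
    pairs: list[tuple[str, str]],
    reactions: dict[str, Reaction],
    proteins: dict[str, ProteinRecord],
    params: ModelParams,
) -> np.ndarray:
    """Vectorized scores for (protein_id, reaction_id) pairs."""
    bank = _ReactionBank(
        {rid: reactions[rid] for _, rid in pairs}, params.encoder_config
    )
    R = bank.embeddings(params.encoder_weights).data
    pid_list = sorted({p for p, _ in pairs})
    pidx = {p: k for k, p in enumerate(pid_list)}
    E = np.stack([proteins[p].embedding for p in pid_list])
    Z = E @ params.protein_projection.data
    logits = np.array(
        [R[bank.index[rid]] @ Z[pidx[pid]] for pid, rid in pairs]
    )
    return sigmoid(logits)


# ---------------------------------------------------------------------------
# loss
# ---------------------------------------------------------------------------


def loss(x, y, cfg: LossConfig | None = None) -> float:
    """Weighted BCE on logits, numerically stabilized; batch inputs are averaged."""
    cfg = cfg or LossConfig()
    x = np.atleast_1d(np.asarray(x, dtype=np.float64))
    y = np.atleast_1d(np.asarray(y, dtype=np.float64))
    if not np.all((y == 0) | (y == 1)):
        raise ValueError("labels must be 0 or 1")
    sp_neg = np.maximum(-x, 0.0) + np.log1p(np.exp(-np.abs(x)))  # -log σ(x)
    sp_pos = np.maximum(x, 0.0) + np.log1p(np.exp(-np.abs(x)))  # -log(1-σ(x))
    per = cfg.pos_weight * y * sp_neg + (1.0 - y) * sp_pos
    return float(per.mean())


def loss_grad(x, y, cfg: LossConfig | None = None) -> np.ndarray:
    """Analytic d loss / d x (per element, before batch averaging)."""
    cfg = cfg or LossConfig()
    x = np.atleast_1d(np.asarray(x, dtype=np.float64))
    y = np.atleast_1d(np.asarray(y, dtype=np.float64))
    s = sigmoid(x)
    return cfg.pos_weight * y * (s - 1.0) + (1.0 - y) * s


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------


@dataclass
class EpochLog:
    epoch: int
    train_loss: float
    val_loss: float | None = None
    val_auc: float | None = None


def _pair_indices(pairs, bank: _ReactionBank, pidx: dict[str, int]):
    ridx = np.array([bank.index[r] for _, r, _ in pairs], dtype=np.intp)
    pix = np.array([pidx[p] for p, _, _ in pairs], dtype=np.intp)
    y = np.array([lab for _, _, lab in pairs], dtype=np.float64)
    return pix, ridx, y


def train(
    train_pairs: list[tuple[str, str, int]],
    reactions: dict[str, Reaction],
    proteins: dict[str, ProteinRecord],
    encoder_cfg: EncoderConfig,
    train_cfg: TrainConfig | None = None,
    loss_cfg: LossConfig | None = None,
    val_pairs: list[tuple[str, str, int]] | None = None,
) -> tuple[ModelParams, list[EpochLog]]:
    """Fit the two-tower scorer by minibatch Adam on the weighted BCE.

    ``train_pairs`` / ``val_pairs`` are (protein_id, reaction_id, label)
    triples.  Deterministic given the seeds in the configs (single
    threaded).  Per-epoch train loss and, when validation pairs are given,
    validation loss and ranking quality (ROC area) are logged.
    """
    tc = train_cfg or TrainConfig()
    lc = loss_cfg or LossConfig()
    rng = np.random.default_rng(tc.seed)

    all_pairs = train_pairs + (val_pairs or [])
    rxn_subset = {rid: reactions[rid] for _, rid, _ in all_pairs}
    bank = _ReactionBank(rxn_subset, encoder_cfg)
    pid_list = sorted({p for p, _, _ in all_pairs})
    pidx = {p: k for k, p in enumerate(pid_list)}
    E = np.stack([proteins[p].embedding for p in pid_list])
    protein_dim = E.shape[1]

    params = init_params(encoder_cfg, protein_dim=protein_dim, seed=tc.seed)
    opt = Adam(params.parameters(), lr=tc.learning_rate)

    tr_p, tr_r, tr_y = _pair_indices(train_pairs, bank, pidx)
    if val_pairs:
        va_p, va_r, va_y = _pair_indices(val_pairs, bank, pidx)

    n = len(train_pairs)
    logs: list[EpochLog] = []
    for epoch in range(tc.epochs):
        order = rng.permutation(n)
        ep_loss = 0.0
        for start in range(0, n, tc.batch_size):
            sel = order[start : start + tc.batch_size]
            opt.zero_grad()
            R = bank.embeddings(params.encoder_weights)
            Z = ad.matmul(Tensor(E), params.protein_projection)
            logits = ad.rowwise_dot(
                ad.gather_rows(R, tr_r[sel]), ad.gather_rows(Z, tr_p[sel])
            )
            batch_loss = ad.weighted_bce_with_logits(
                logits, tr_y[sel], pos_weight=lc.pos_weight
            )
            if not np.isfinite(batch_loss.data):
                raise FloatingPointError(
                    f"non-finite loss at epoch {epoch}: {batch_loss.data}"
                )
            batch_loss.backward()
            opt.step()
            ep_loss += float(batch_loss.data) * len(sel)
        log = EpochLog(epoch=epoch, train_loss=ep_loss / n)
        if val_pairs:
            R = bank.embeddings(params.encoder_weights).data
            Z = E @ params.protein_projection.data
            vx = (R[va_r] * Z[va_p]).sum(axis=1)
            log.val_loss = loss(vx, va_y, lc)
            log.val_auc = _roc_auc(sigmoid(vx), va_y)
        logs.append(log)

    if val_pairs:
        R = bank.embeddings(params.encoder_weights).data
        Z = E @ params.protein_projection.data
        scores = sigmoid((R[va_r] * Z[va_p]).sum(axis=1))
        if len(set(va_y)) == 2:
            params.threshold = select_threshold(scores, va_y)
    return params, logs


def _roc_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    from sklearn.metrics import roc_auc_score

    if len(set(labels)) < 2:
        return float("nan")
    return float(roc_auc_score(labels, scores))


# ---------------------------------------------------------------------------
# threshold selection
# ---------------------------------------------------------------------------


def select_threshold(scores, labels) -> float:
    """The validation-F1-maximizing threshold over observed score midpoints.

    Candidates are midpoints of consecutive distinct scores; a degenerate
    all-identical score vector falls back to midpoints with the 0/1 bounds.
    Ties go to the smallest threshold.
    """
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels)
    if len(set(labels.tolist())) < 2:
        raise ValueError("threshold selection needs both classes present")
    uniq = np.unique(scores)
    if len(uniq) == 1:
        cands = [(0.0 + uniq[0]) / 2, (uniq[0] + 1.0) / 2]
    else:
        cands = ((uniq[:-1] + uniq[1:]) / 2).tolist()
    best_tau, best_f1 = None, -1.0
    for tau in cands:
        pred = scores >= tau
        tp = int(np.sum(pred & (labels == 1)))
        fp = int(np.sum(pred & (labels == 0)))
        fn = int(np.sum(~pred & (labels == 1)))
        f1 = 2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) else 0.0
        if f1 > best_f1 + 1e-12:
            best_tau, best_f1 = tau, f1
    return float(best_tau)


# ---------------------------------------------------------------------------
# grid search + k-fold CV
# ---------------------------------------------------------------------------


@dataclass
class CVCell:
    overrides: dict
    mean_f1: float
    sd_f1: float
    mean_accuracy: float
    per_fold_f1: list[float] = field(default_factory=list)


def cross_validate(
    fold_pairs: dict[int, list[tuple[str, str, int]]],
    reactions: dict[str, Reaction],
    proteins: dict[str, ProteinRecord],
    base_encoder_cfg: EncoderConfig,
    grid: list[dict],
    train_cfg: TrainConfig | None = None,
    loss_cfg: LossConfig | None = None,
) -> tuple[dict, list[CVCell]]:
    """Grid search with k-fold CV over the inner folds.

    Each grid cell is a dict of :class:`EncoderConfig` field overrides.  For
    every cell, each fold in turn is held out for validation while the rest
    train; the cell with the highest mean validation F1 wins, ties going to
    the first cell in grid order.  Returns the winning overrides and the
    full table (mean ± sd per cell) for depth-sweep style analyses.
    """
    if not grid:
        raise ValueError("empty hyperparameter grid")
    folds = sorted(fold_pairs)
    table: list[CVCell] = []
    for overrides in grid:
        cfg = replace(base_encoder_cfg, **overrides)
        f1s, accs = [], []
        for held in folds:
            tr = [p for f in folds if f != held for p in fold_pairs[f]]
            va = fold_pairs[held]
            params, _ = train(
                tr, reactions, proteins, cfg, train_cfg, loss_cfg, val_pairs=va
            )
            scores = score_pairs(
                [(p, r) for p, r, _ in va], reactions, proteins, params
            )
            y = np.array([lab for _, _, lab in va])
            pred = scores >= params.threshold
            tp = int(np.sum(pred & (y == 1)))
            fp = int(np.sum(pred & (y == 0)))
            fn = int(np.sum(~pred & (y == 1)))
            f1s.append(2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) else 0.0)
            accs.append(float((pred == y).mean()))
        table.append(
            CVCell(
                overrides=overrides,
                mean_f1=float(np.mean(f1s)),
                sd_f1=float(np.std(f1s)),
                mean_accuracy=float(np.mean(accs)),
                per_fold_f1=f1s,
            )
        )
    best = max(range(len(table)), key=lambda i: table[i].mean_f1)
    # explicit first-wins tie rule
    for i in range(len(table)):
        if table[i].mean_f1 >= table[best].mean_f1 - 1e-12:
            best = i
            break
    return grid[best], table


# ---------------------------------------------------------------------------
# checkpoint container
# ---------------------------------------------------------------------------


def save_params(path: str, params: ModelParams) -> None:
    """NPZ container: JSON config header plus named weight arrays."""
    cfg = params.encoder_config
    header = json.dumps(
        {
            "variant": cfg.variant,
            "message_passings": cfg.m,
            "embedding_dim": cfg.embedding_dim,
            "hidden_dim": cfg.h,
            "morgan_radius": cfg.morgan_radius,
            "morgan_nbits": cfg.morgan_nbits,
            "seed": cfg.seed,
            "threshold": params.threshold,
        }
    )
    arrays = {f"enc_{k}": v.data for k, v in params.encoder_weights.items()}
    np.savez(
        path,
        config=np.frombuffer(header.encode(), dtype=np.uint8),
        protein_projection=params.protein_projection.data,
        **arrays,
    )


def load_params(path: str) -> ModelParams:
    with np.load(path) as z:
        header = json.loads(bytes(z["config"].tobytes()).decode())
        cfg = EncoderConfig(
            variant=header["variant"],
            message_passings=header["message_passings"],
            embedding_dim=header["embedding_dim"],
            hidden_dim=header["hidden_dim"],
            morgan_radius=header["morgan_radius"],
            morgan_nbits=header["morgan_nbits"],
            seed=header["seed"],
        )
        enc = {
            k[4:]: Tensor(z[k], requires_grad=True)
            for k in z.files
            if k.startswith("enc_")
        }
        return ModelParams(
            protein_projection=Tensor(z["protein_projection"], requires_grad=True),
            encoder_weights=enc,
            encoder_config=cfg,
            threshold=float(header["threshold"]),
        )
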
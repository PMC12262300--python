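"""Classification metrics, similarity-binned performance, RC-proximity analysis.

Besides standard confusion-matrix metrics and ROC curves, two analyses
specific to this problem are provided: per-bin performance as a function of
each test entity's measured maximum similarity to the training pool (the
generalization-difficulty axis), and the RC-proximity analysis, which asks
whether an encoder maps reactions sharing a reaction center close to the
embedding of the RC itself — evidence that it has learned mechanism-local
patterns.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .autodiff import sigmoid
from .encoders import EncoderConfig, embed_reaction
from .reaction_core import Reaction, rc_as_reaction

__all__ = [
    "MetricsReport",
    "BinnedReport",
    "compute_metrics",
    "binned_performance",
    "rc_proximity_analysis",
    "compare_encoder_proximity",
    "group_reactions_by_rc",
]


@dataclass
class MetricsReport:
    """Confusion-matrix metrics at a threshold plus the ROC curve.

    Metrics whose denominator is empty (e.g. precision with no predicted
    positives, ROC area with one class) are ``None`` — an explicit
    undefined marker, never NaN.
    """

    n: int
    tp: int
    fp: int
    tn: int
    fn: int
    accuracy: float
    precision: float | None
    recall: float | None
    f1: float | None
    roc_auc: float | None
    roc_points: list[tuple[float, float]] = field(default_factory=list)

    def as_dict(self) -> dict:
        return {
            "n": self.n,
            "tp": self.tp,
            "fp": self.fp,
            "tn": self.tn,
            "fn": self.fn,
            "accuracy": self.accuracy,
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
            "roc_auc": self.roc_auc,
        }


def compute_metrics(scores, labels, tau: float) -> MetricsReport:
    """Standard metrics at threshold ``tau``; ROC by threshold sweep."""
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels)
    if scores.size < 1:
        raise ValueError("need at least one score")
    pred = scores >= tau
    tp = int(np.sum(pred & (labels == 1)))
    fp = int(np.sum(pred & (labels == 0)))
    fn = int(np.sum(~pred & (labels == 1)))
    tn = int(np.sum(~pred & (labels == 0)))
    n = scores.size
    precision = tp / (tp + fp) if (tp + fp) else None
    recall = tp / (tp + fn) if (tp + fn) else None
    f1 = (
        2 * precision * recall / (precision + recall)
        if precision is not None and recall is not None and (precision + recall) > 0
        else (0.0 if precision is not None and recall is not None else None)
    )
    roc_auc = None
    roc_points: list[tuple[float, float]] = []
    if len(set(labels.tolist())) == 2:
        from sklearn.metrics import roc_curve, auc

        fpr, tpr, _ = roc_curve(labels, scores)
        roc_auc = float(auc(fpr, tpr))
        roc_points = list(zip(fpr.tolist(), tpr.tolist()))
    return MetricsReport(
        n=n,
        tp=tp,
        fp=fp,
        tn=tn,
        fn=fn,
        accuracy=float((tp + tn) / n),
        precision=precision,
        recall=recall,
        f1=f1,
        roc_auc=roc_auc,
        roc_points=roc_points,
    )


@dataclass
class BinnedReport:
    """Per-bin metrics over max-train-similarity; bins partition [0, 1]."""

    edges: list[float]
    reports: list[MetricsReport | None]  # None for empty bins
    counts: list[int]
    low_confidence: list[bool]

    def as_dict(self) -> dict:
        out = []
        for i in range(len(self.edges) - 1):
            out.append(
                {
                    "bin": [self.edges[i], self.edges[i + 1]],
                    "n": self.counts[i],
                    "low_confidence": self.low_confidence[i],
                    "metrics": self.reports[i].as_dict() if self.reports[i] else None,
                }
            )
        return {"bins": out}


DEFAULT_BIN_EDGES = [0.0, 0.2, 0.4, 0.6, 0.8, 1.0]


def binned_performance(
    pairs: list[tuple[str, str, int]],
    scores,
    entity_similarity: dict[str, float],
    tau: float,
    edges: list[float] | None = None,
    split_entity: str = "reaction",
    min_bin_n: int = 10,
) -> BinnedReport:
    """Metrics per bin of the test pairs' entity max-train similarity.

    Each pair is binned by its split entity's realized maximum similarity to
    the training pool (as measured by ``verify_split``); bins with fewer
    than ``min_bin_n`` pairs are flagged low-confidence.
    """
    edges = edges or DEFAULT_BIN_EDGES
    scores = np.asarray(scores, dtype=np.float64)
    nb = len(edges) - 1
    bin_scores: list[list[float]] = [[] for _ in range(nb)]
    bin_labels: list[list[int]] = [[] for _ in range(nb)]
    for (pid, rid, label), s in zip(pairs, scores):
        eid = rid if split_entity == "reaction" else pid
        if eid not in entity_similarity:
            raise KeyError(f"no realized similarity for split entity {eid!r}")
        v = entity_similarity[eid]
        k = min(int(np.searchsorted(edges, v, side="right")) - 1, nb - 1)
        k = max(k, 0)
        bin_scores[k].append(float(s))
        bin_labels[k].append(label)
    reports, counts, lowc = [], [], []
    for k in range(nb):
        counts.append(len(bin_scores[k]))
        lowc.append(len(bin_scores[k]) < min_bin_n)
        reports.append(
            compute_metrics(np.array(bin_scores[k]), np.array(bin_labels[k]), tau)
            if bin_scores[k]
            else None
        )
    return BinnedReport(edges=list(edges), reports=reports, counts=counts,
                        low_confidence=lowc)


# ---------------------------------------------------------------------------
# RC proximity
# ---------------------------------------------------------------------------


def group_reactions_by_rc(reactions: list[Reaction]) -> dict[str, list[Reaction]]:
    """Group reactions by the canonical form of their extracted RC reaction."""
    groups: dict[str, list[Reaction]] = {}
    for r in reactions:
        key = rc_as_reaction(r).canonical_smiles(keep_maps=False)
        groups.setdefault(key, []).append(r)
    return groups


@dataclass
class RCProximityRecord:
    rc_key: str
    n_members: int
    similarity: float  # σ(⟨mean member embedding, RC embedding⟩)
    dot: float  # the raw dot product (σ saturates in float for large dots)
    degenerate: bool  # single-member group


def rc_proximity_analysis(
    reactions: list[Reaction],
    cfg: EncoderConfig,
    weights,
    threshold: float = 0.8,
) -> tuple[list[RCProximityRecord], float]:
    """Per shared-RC group: similarity of the members' mean embedding to the RC's own.

    The similarity is computed exactly as an enzyme-reaction score —
    sigmoid of the dot product — which is valid because all inputs live in
    the same embedding space.  Returns the records and the fraction of
    groups at or above ``threshold``.  Single-member groups are included
    but flagged degenerate.
    """
    groups = group_reactions_by_rc(reactions)
    if not groups:
        raise ValueError("no RC groups")
    records = []
    for key, members in sorted(groups.items()):
        mean_emb = np.mean(
            [embed_reaction(r, cfg, weights) for r in members], axis=0
        )
        rc_emb = embed_reaction(rc_as_reaction(members[0]), cfg, weights)
        dot = float(mean_emb @ rc_emb)
        s = float(sigmoid(np.array([dot]))[0])
        records.append(
            RCProximityRecord(
                rc_key=key,
                n_members=len(members),
                similarity=s,
                dot=dot,
                degenerate=len(members) < 2,
            )
        )
    frac = float(np.mean([r.similarity >= threshold for r in records]))
    return records, frac


def compare_encoder_proximity(
    reactions: list[Reaction],
    cfg_a: EncoderConfig,
    weights_a,
    cfg_b: EncoderConfig,
    weights_b,
) -> dict:
    """RC-by-RC comparison of two encoders' proximity scores.

    Returns per-RC rows (similarity under each encoder, which wins) and the
    fraction of RC groups where encoder A's members-mean lies closer to the
    RC embedding than encoder B's.  "Closer" is decided on the raw dot
    product — the same ordering as the sigmoid similarity, but immune to
    floating-point saturation of σ at large dot products.
    """
    rec_a, _ = rc_proximity_analysis(reactions, cfg_a, weights_a)
    rec_b, _ = rc_proximity_analysis(reactions, cfg_b, weights_b)
    rows = []
    wins_a = 0
    for a, b in zip(rec_a, rec_b):
        assert a.rc_key == b.rc_key
        win = a.dot > b.dot
        wins_a += win
        rows.append(
            {
                "rc_key": a.rc_key,
                "n_members": a.n_members,
                "similarity_a": a.similarity,
                "similarity_b": b.similarity,
                "a_wins": bool(win),
            }
        )
    return {"rows": rows, "fraction_a_wins": wins_a / len(rows) if rows else None}
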
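"""Similarity-stratified data splitting and global negative sampling.

The split guarantees, by construction, that every test entity's maximum
similarity to the training pool is below its stratum's upper bound: entities
are clustered at each similarity bound (single-linkage connected components
of the thresholded similarity graph) and whole clusters are sampled into the
test fold, so no cross-split pair can reach the bound.  Bounds are then
relaxed in ascending order to fill the next stratum.  The realized maximum
cross-split similarity of every test entity is measured afterwards and its
stratum recorded from measurement, never assumed.

Negatives are drawn globally: uniformly from all unobserved (protein,
reaction) pairs of each fold, with no similarity biasing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .similarity import SimilarityMatrix

__all__ = [
    "SplitConfig",
    "SplitAssignment",
    "PairDataset",
    "SplitCollapseError",
    "cluster_at_bound",
    "stratified_similarity_split",
    "verify_split",
    "sample_negatives",
    "misassignment_bound",
]


class SplitCollapseError(RuntimeError):
    """The pool collapsed into a single cluster at some bound; quota unreachable."""

    def __init__(self, bound: float):
        self.bound = bound
        super().__init__(
            f"dataset collapses into a single cluster at similarity bound {bound}; "
            "stratified splitting is infeasible below this bound"
        )


@dataclass(frozen=True)
class SplitConfig:
    """Configuration of a stratified similarity split.

    ``bounds`` are the ascending stratum upper bounds (last must be 1.0);
    stratum i covers [bounds[i-1], bounds[i]) with the first stratum starting
    at 0.  ``quota_fractions`` (one per stratum) sum to ``test_fraction``;
    by default the test fraction is spread evenly over strata.
    """

    bounds: tuple[float, ...] = (0.4, 0.6, 0.8, 1.0)
    split_entity: str = "reaction"  # or "protein"
    test_fraction: float = 0.2
    quota_fractions: tuple[float, ...] | None = None
    cv_folds: int = 3
    seed: int = 0

    def __post_init__(self):
        b = self.bounds
        if any(b[i] >= b[i + 1] for i in range(len(b) - 1)) or b[-1] != 1.0:
            raise ValueError("bounds must be strictly ascending and end at 1.0")
        if self.split_entity not in ("reaction", "protein"):
            raise ValueError("split_entity must be 'reaction' or 'protein'")
        q = self.effective_quotas()
        if abs(sum(q) - self.test_fraction) > 1e-9:
            raise ValueError("quota fractions must sum to the test fraction")

    def effective_quotas(self) -> tuple[float, ...]:
        if self.quota_fractions is not None:
            return self.quota_fractions
        k = len(self.bounds)
        return tuple(self.test_fraction / k for _ in range(k))


@dataclass
class EntityAssignment:
    fold: str  # "test" | "trainval"
    cv_fold: int | None  # inner fold index for trainval entities
    declared_stratum: tuple[float, float] | None  # half-open [lo, hi)
    realized_max_sim: float | None = None


@dataclass
class SplitAssignment:
    """Fold layout over split entities plus measured cross-split similarities."""

    entity_ids: list[str]
    entries: dict[str, EntityAssignment]
    config: SplitConfig

    def fold_of(self, eid: str) -> str:
        return self.entries[eid].fold

    def test_ids(self) -> list[str]:
        return [e for e in self.entity_ids if self.entries[e].fold == "test"]

    def trainval_ids(self) -> list[str]:
        return [e for e in self.entity_ids if self.entries[e].fold == "trainval"]

    def cv_ids(self, fold: int) -> list[str]:
        return [
            e
            for e in self.entity_ids
            if self.entries[e].fold == "trainval" and self.entries[e].cv_fold == fold
        ]

    def to_rows(self) -> list[dict]:
        rows = []
        for e in self.entity_ids:
            a = self.entries[e]
            rows.append(
                {
                    "entity_id": e,
                    "fold": a.fold,
                    "cv_fold": "" if a.cv_fold is None else a.cv_fold,
                    "declared_stratum": ""
                    if a.declared_stratum is None
                    else f"[{a.declared_stratum[0]:g},{a.declared_stratum[1]:g})",
                    "realized_max_sim": ""
                    if a.realized_max_sim is None
                    else f"{a.realized_max_sim:.6f}",
                }
            )
        return rows


@dataclass
class PairDataset:
    """Positive and sampled-negative (protein, reaction, label) triples per fold.

    ``fold`` of a pair is inherited from its split entity.
    """

    pairs: list[tuple[str, str, int, str]] = field(default_factory=list)
    # (protein_id, reaction_id, label, fold)

    def by_fold(self, fold: str) -> list[tuple[str, str, int]]:
        return [(p, r, y) for p, r, y, f in self.pairs if f == fold]

    def positives(self) -> set[tuple[str, str]]:
        return {(p, r) for p, r, y, _ in self.pairs if y == 1}

    def negatives(self) -> set[tuple[str, str]]:
        return {(p, r) for p, r, y, _ in self.pairs if y == 0}


# ---------------------------------------------------------------------------
# clustering
# ---------------------------------------------------------------------------


def cluster_at_bound(m: SimilarityMatrix, bound: float) -> list[list[int]]:
    """Single-linkage clusters: connected components of {score >= bound} edges.

    Maximum similarity between items in different clusters is therefore
    strictly below ``bound``.
    """
    if not (0 < bound <= 1):
        raise ValueError("bound must lie in (0, 1]")
    adj = (m.scores >= bound).astype(np.int8)
    np.fill_diagonal(adj, 0)
    n_comp, labels = connected_components(csr_matrix(adj), directed=False)
    clusters: list[list[int]] = [[] for _ in range(n_comp)]
    for idx, lab in enumerate(labels):
        clusters[lab].append(idx)
    return clusters


def _subset_clusters(m: SimilarityMatrix, pool: list[int], bound: float) -> list[list[int]]:
    sub = m.scores[np.ix_(pool, pool)]
    adj = (sub >= bound).astype(np.int8)
    np.fill_diagonal(adj, 0)
    n_comp, labels = connected_components(csr_matrix(adj), directed=False)
    clusters: list[list[int]] = [[] for _ in range(n_comp)]
    for k, lab in enumerate(labels):
        clusters[lab].append(pool[k])
    return clusters


# ---------------------------------------------------------------------------
# stratified similarity split
# ---------------------------------------------------------------------------


def _sample_strata(
    m: SimilarityMatrix,
    pool: list[int],
    bounds: tuple[float, ...],
    quotas_n: list[int],
    rng: np.random.Generator,
    strict_collapse: bool = True,
) -> tuple[list[int], dict[int, tuple[float, float]], list[int]]:
    """Sample whole clusters into a held-out set, stratum by stratum.

    Returns (held indices, declared stratum per held index, remaining pool).
    Cluster sampling is without replacement, uniform over clusters weighted
    by cluster size, so expected stratum sizes match quotas.  Overshoot by
    cluster granularity is tolerated up to half the stratum quota; clusters
    too large to fit are left for a more permissive bound, where single
    linkage breaks them into finer pieces, and unfilled quota rolls forward
    likewise.
    """
    remaining = list(pool)
    held: list[int] = []
    declared: dict[int, tuple[float, float]] = {}
    carry = 0
    for si, bound in enumerate(bounds):
        lo = 0.0 if si == 0 else bounds[si - 1]
        quota = quotas_n[si] + carry
        if quota <= 0:
            carry = 0
            continue
        clusters = _subset_clusters(m, remaining, bound)
        if strict_collapse and len(clusters) == 1 and len(remaining) > 1:
            raise SplitCollapseError(bound)
        slack = max(1, quota // 2)
        taken = 0
        order = rng.permutation(len(clusters))
        sizes = np.array([len(clusters[k]) for k in order], dtype=float)
        # size-weighted order: draw clusters with probability proportional to size
        probs = sizes / sizes.sum()
        order = rng.choice(order, size=len(order), replace=False, p=probs)
        for k in order:
            cl = clusters[k]
            if taken >= quota:
                break
            if len(cl) >= len(remaining):
                # taking the only / whole-pool cluster would empty the pool
                continue
            if taken + len(cl) > quota + slack:
                continue  # too coarse for this stratum; finer at the next bound
            held.extend(cl)
            for idx in cl:
                declared[idx] = (lo, bound)
            remaining = [x for x in remaining if x not in set(cl)]
            taken += len(cl)
        carry = max(quota - taken, 0)
    return held, declared, remaining


def stratified_similarity_split(
    m: SimilarityMatrix, cfg: SplitConfig
) -> SplitAssignment:
    """Assign every entity to test or a train/validation inner-CV fold.

    Test entities are drawn stratum by stratum (ascending bounds, whole
    clusters).  The remaining pool is split into ``cv_folds`` inner folds by
    the same cluster-sampling procedure, re-stratified within the pool.
    Afterwards each test entity's realized maximum similarity to the
    train/validation pool is measured and its stratum re-labeled from the
    measurement.  Deterministic given the seed.
    """
    m.validate()
    n = len(m.ids)
    rng = np.random.default_rng(cfg.seed)
    quotas_n = [int(round(q * n)) for q in cfg.effective_quotas()]
    pool = list(range(n))
    test_idx, declared, remaining = _sample_strata(
        m, pool, cfg.bounds, quotas_n, rng, strict_collapse=True
    )

    entries: dict[str, EntityAssignment] = {}
    for idx in test_idx:
        entries[m.ids[idx]] = EntityAssignment(
            fold="test", cv_fold=None, declared_stratum=declared[idx]
        )

    # inner CV folds over the remaining pool, same procedure per fold
    cv_pool = list(remaining)
    k = cfg.cv_folds
    for fold in range(k):
        if fold == k - 1:
            fold_idx = list(cv_pool)
        else:
            frac = 1.0 / (k - fold)
            fq = [int(round(frac * len(cv_pool) / len(cfg.bounds)))] * len(cfg.bounds)
            fold_idx, _, cv_pool = _sample_strata(
                m, cv_pool, cfg.bounds, fq, rng, strict_collapse=False
            )
        for idx in fold_idx:
            entries[m.ids[idx]] = EntityAssignment(
                fold="trainval", cv_fold=fold, declared_stratum=None
            )

    assignment = SplitAssignment(entity_ids=list(m.ids), entries=entries, config=cfg)
    _measure_realized(assignment, m)
    return assignment


def _measure_realized(assignment: SplitAssignment, m: SimilarityMatrix) -> None:
    """Measure test entities' max similarity to the trainval pool; re-label strata."""
    idx = m.index()
    train_cols = [idx[e] for e in assignment.trainval_ids()]
    bounds = assignment.config.bounds
    for eid in assignment.test_ids():
        row = m.scores[idx[eid], train_cols] if train_cols else np.array([0.0])
        realized = float(row.max()) if row.size else 0.0
        a = assignment.entries[eid]
        a.realized_max_sim = realized
        lo = 0.0
        for b in bounds:
            if realized < b:
                a.declared_stratum = (lo, b)
                break
            lo = b
        else:  # realized == 1.0 exactly: top stratum
            a.declared_stratum = (bounds[-2] if len(bounds) > 1 else 0.0, bounds[-1])


# ---------------------------------------------------------------------------
# verification
# ---------------------------------------------------------------------------


@dataclass
class SplitReport:
    per_entity: list[dict]
    stratum_counts: dict[str, int]
    n_violations: int

    @property
    def all_pass(self) -> bool:
        return self.n_violations == 0

    def histogram(self, edges: list[float]) -> dict[str, int]:
        """Counts of realized max-train similarity per bin (export format)."""
        vals = [e["realized_max_sim"] for e in self.per_entity]
        out = {}
        for i in range(len(edges) - 1):
            lo, hi = edges[i], edges[i + 1]
            top = i == len(edges) - 2
            out[f"[{lo:g},{hi:g}{']' if top else ')'}"] = sum(
                lo <= v < hi or (top and v == hi) for v in vals
            )
        return out


def verify_split(assignment: SplitAssignment, m: SimilarityMatrix) -> SplitReport:
    """Check every test entity's realized max-train similarity against its stratum."""
    idx = m.index()
    train_cols = [idx[e] for e in assignment.trainval_ids()]
    rows = []
    counts: dict[str, int] = {}
    violations = 0
    for eid in assignment.test_ids():
        a = assignment.entries[eid]
        realized = (
            float(m.scores[idx[eid], train_cols].max()) if train_cols else 0.0
        )
        lo, hi = a.declared_stratum
        ok = lo <= realized < hi or (hi == 1.0 and realized == 1.0 and lo <= realized)
        ok = ok and realized < hi  # strict upper bound is the hard guarantee
        key = f"[{lo:g},{hi:g})"
        counts[key] = counts.get(key, 0) + 1
        if not ok:
            violations += 1
        rows.append(
            {
                "entity_id": eid,
                "realized_max_sim": realized,
                "declared_stratum": key,
                "pass": ok,
            }
        )
    return SplitReport(per_entity=rows, stratum_counts=counts, n_violations=violations)


# ---------------------------------------------------------------------------
# negative sampling
# ---------------------------------------------------------------------------


def sample_negatives(
    positives: list[tuple[str, str]],
    protein_ids: list[str],
    reaction_ids: list[str],
    assignment: SplitAssignment,
    ratios: dict[str, int],
    seed: int,
    val_cv_fold: int = 0,
) -> PairDataset:
    """Draw unobserved pairs per fold, globally and uniformly.

    ``positives`` are (protein_id, reaction_id).  Pairs inherit the fold of
    their split entity; folds are labeled ``test``, ``val`` (the designated
    inner CV fold) and ``train`` (the remaining CV folds).  Per fold,
    ``ratios[fold]`` negatives are drawn per positive, without replacement,
    from {fold entities} x {all counterpart entities} minus the *global*
    positive set.  Deterministic given the seed.
    """
    for fold, r in ratios.items():
        if not (isinstance(r, int) and r > 0):
            raise ValueError(f"ratio for fold {fold!r} must be a positive integer")
    rng = np.random.default_rng(seed)
    pos_set = set(positives)
    by_reaction = assignment.config.split_entity == "reaction"

    def fold_label(eid: str) -> str:
        a = assignment.entries[eid]
        if a.fold == "test":
            return "test"
        return "val" if a.cv_fold == val_cv_fold else "train"

    ds = PairDataset()
    fold_pos: dict[str, list[tuple[str, str]]] = {"test": [], "val": [], "train": []}
    for p, r in positives:
        eid = r if by_reaction else p
        if eid not in assignment.entries:
            raise KeyError(f"split entity {eid!r} missing from assignment")
        f = fold_label(eid)
        fold_pos[f].append((p, r))
        ds.pairs.append((p, r, 1, f))

    fold_entities: dict[str, list[str]] = {"test": [], "val": [], "train": []}
    entity_ids = reaction_ids if by_reaction else protein_ids
    counterparts = protein_ids if by_reaction else reaction_ids
    for eid in entity_ids:
        fold_entities[fold_label(eid)].append(eid)

    for f in ("train", "val", "test"):
        need = ratios.get(f, 0) * len(fold_pos[f])
        if need == 0:
            continue
        candidates = []
        for eid in fold_entities[f]:
            for cp in counterparts:
                pair = (cp, eid) if by_reaction else (eid, cp)
                if pair not in pos_set:
                    candidates.append(pair)
        if len(candidates) < need:
            raise ValueError(
                f"fold {f!r}: only {len(candidates)} unobserved pairs available, "
                f"{need} requested"
            )
        chosen = rng.choice(len(candidates), size=need, replace=False)
        for k in sorted(chosen):
            p, r = candidates[k]
            ds.pairs.append((p, r, 0, f))
    return ds


# ---------------------------------------------------------------------------
# misassignment bound
# ---------------------------------------------------------------------------


def misassignment_bound(observed_density: float, assumed_coverage: float) -> float:
    """Upper bound on the probability a sampled negative is a true positive.

    If observed positives have density ``observed_density`` in the bipartite
    adjacency matrix, and current knowledge covers at least
    ``assumed_coverage`` of true catalysis, the true-positive density is at
    most ``observed_density / assumed_coverage`` — and so is the chance that
    a uniformly sampled unobserved pair is secretly positive.
    """
    if not (0 < observed_density <= assumed_coverage <= 1):
        raise ValueError(
            "require 0 < observed_density <= assumed_coverage <= 1 "
            f"(got {observed_density}, {assumed_coverage})"
        )
    return observed_density / assumed_coverage
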
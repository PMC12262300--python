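"""Pairwise similarity metrics: RCMCS for reactions and GSI for protein sequences.

RCMCS (reaction-center maximum common subgraph) scores two reactions by the
number of atoms in the largest common subgraph of their disjoint-union graphs
— reactant atoms matched to reactant atoms, product atoms to product atoms —
constrained to contain a full correspondence between the two reaction
centers, divided by the atom count of the larger reaction.  Pairs whose RCs
admit no criteria-compatible correspondence score 0.

GSI (global sequence identity) locally aligns two amino-acid sequences
(BLOSUM62, affine gaps) and divides the number of identically aligned
residues by the length of the longer sequence.

The MCS is solved exactly by branch-and-bound maximum clique search on the
modular product of the two sided graphs, seeded with every valid RC
bijection.  A deterministic search-step budget guards pathological pairs;
when it is exceeded the best correspondence found so far is returned and the
pair is flagged in the fallback log.  ``mcs_oracle`` is an independent,
purely exhaustive search used to validate the production path on small
graphs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from .reaction_core import Reaction, ReactionValidationError, side_atoms

logger = logging.getLogger(__name__)

__all__ = [
    "AtomMatchCriteria",
    "SimilarityMatrix",
    "rcmcs",
    "rcmcs_numerator",
    "mcs_oracle",
    "gsi",
    "pairwise_matrix",
]


@dataclass(frozen=True)
class AtomMatchCriteria:
    """Atom/bond compatibility rules for the common-subgraph search.

    Element matching is mandatory.  Defaults: element + aromaticity + bond
    order, charge ignored (charges are neutralized upstream).
    """

    match_aromaticity: bool = True
    match_charge: bool = False
    match_bond_order: bool = True


@dataclass
class SimilarityMatrix:
    """Dense symmetric pairwise similarity scores in [0, 1]."""

    ids: list[str]
    scores: np.ndarray
    metric: str
    fallback_pairs: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self):
        n = len(self.ids)
        assert self.scores.shape == (n, n)

    def validate(self) -> None:
        s = self.scores
        if not np.allclose(np.diag(s), 1.0):
            raise ValueError("similarity matrix diagonal must be 1")
        if not np.allclose(s, s.T):
            raise ValueError("similarity matrix must be symmetric")
        if s.min() < 0 or s.max() > 1 + 1e-12:
            raise ValueError("similarity scores must lie in [0, 1]")

    def index(self) -> dict[str, int]:
        return {i: k for k, i in enumerate(self.ids)}


# ---------------------------------------------------------------------------
# sided graph extraction
# ---------------------------------------------------------------------------


class _SidedGraph:
    """Disjoint union of both sides of a reaction, with side tags and RC set."""

    __slots__ = ("n", "side", "elem", "arom", "charge", "bonds", "adj", "rc")

    def __init__(self, r: Reaction):
        self.side: list[int] = []
        self.elem: list[str] = []
        self.arom: list[bool] = []
        self.charge: list[int] = []
        self.bonds: dict[frozenset[int], float] = {}
        n_react = sum(m.GetNumAtoms() for m in r.reactants)
        for s, mols in ((0, r.reactants), (1, r.products)):
            off = 0 if s == 0 else n_react
            moff = off
            for m in mols:
                for a in m.GetAtoms():
                    self.side.append(s)
                    self.elem.append(a.GetSymbol())
                    self.arom.append(a.GetIsAromatic())
                    self.charge.append(a.GetFormalCharge())
                for b in m.GetBonds():
                    i = moff + b.GetBeginAtomIdx()
                    j = moff + b.GetEndAtomIdx()
                    self.bonds[frozenset((i, j))] = b.GetBondTypeAsDouble()
                moff += m.GetNumAtoms()
        self.n = len(self.elem)
        self.adj: list[set[int]] = [set() for _ in range(self.n)]
        for key in self.bonds:
            i, j = tuple(key)
            self.adj[i].add(j)
            self.adj[j].add(i)
        self.rc = sorted(r.rc_reactant_atoms) + sorted(
            g + n_react for g in r.rc_product_atoms
        )


def _nodes_compatible(g1, g2, i, j, c: AtomMatchCriteria) -> bool:
    if g1.side[i] != g2.side[j] or g1.elem[i] != g2.elem[j]:
        return False
    if c.match_aromaticity and g1.arom[i] != g2.arom[j]:
        return False
    if c.match_charge and g1.charge[i] != g2.charge[j]:
        return False
    return True


def _pairs_consistent(g1, g2, p, q, c: AtomMatchCriteria) -> bool:
    """Modular-product edge test between candidate pairs p=(i1,j1), q=(i2,j2)."""
    i1, j1 = p
    i2, j2 = q
    if i1 == i2 or j1 == j2:
        return False
    b1 = g1.bonds.get(frozenset((i1, i2)))
    b2 = g2.bonds.get(frozenset((j1, j2)))
    if (b1 is None) != (b2 is None):
        return False
    if b1 is not None and c.match_bond_order and b1 != b2:
        return False
    return True


# ---------------------------------------------------------------------------
# RC seed enumeration
# ---------------------------------------------------------------------------


def _rc_bijections(g1, g2, c: AtomMatchCriteria):
    """Yield every pairwise-consistent bijection between the two RC atom sets."""
    rc1, rc2 = g1.rc, g2.rc
    if len(rc1) != len(rc2):
        return
    # side-respecting necessary condition
    def seed_extend(k, used, current):
        if k == len(rc1):
            yield tuple(current)
            return
        i = rc1[k]
        for j in rc2:
            if j in used or not _nodes_compatible(g1, g2, i, j, c):
                continue
            p = (i, j)
            if all(_pairs_consistent(g1, g2, p, q, c) for q in current):
                current.append(p)
                used.add(j)
                yield from seed_extend(k + 1, used, current)
                used.discard(j)
                current.pop()

    yield from seed_extend(0, set(), [])


# ---------------------------------------------------------------------------
# exact maximum clique (branch and bound with greedy coloring)
# ---------------------------------------------------------------------------


class _BudgetExceeded(Exception):
    pass


def _max_clique(cand: list[int], compat: list[set[int]], budget: list[int]) -> int:
    """Largest clique size among ``cand`` under adjacency ``compat``.

    ``budget[0]`` is decremented per expansion; raises when exhausted with the
    incumbent attached, so callers can fall back to the best found so far.
    """
    best = [0]

    def color_bound(nodes: list[int]) -> list[tuple[int, int]]:
        # greedy coloring: returns (node, color_index+1) in expansion order
        colors: list[set[int]] = []
        order: list[tuple[int, int]] = []
        for v in nodes:
            for ci, cls in enumerate(colors):
                if not (compat[v] & cls):
                    cls.add(v)
                    order.append((v, ci + 1))
                    break
            else:
                colors.append({v})
                order.append((v, len(colors)))
        order.sort(key=lambda t: t[1])
        return order

    def expand(nodes: list[int], size: int):
        budget[0] -= 1
        if budget[0] < 0:
            exc = _BudgetExceeded()
            exc.best = best[0]  # type: ignore[attr-defined]
            raise exc
        if not nodes:
            best[0] = max(best[0], size)
            return
        order = color_bound(nodes)
        while order:
            v, bound = order.pop()
            if size + bound <= best[0]:
                return
            rest = [u for u, _ in order if u in compat[v]]
            expand(rest, size + 1)

    try:
        expand(cand, 0)
    except _BudgetExceeded as exc:
        exc.best = max(best[0], getattr(exc, "best", 0))  # type: ignore[attr-defined]
        raise
    return best[0]


def _rc_mcs_size(
    r1: Reaction,
    r2: Reaction,
    criteria: AtomMatchCriteria,
    budget: int,
) -> tuple[int, bool]:
    """Atoms in the RC-containing MCS; second value flags a budget fallback."""
    for r in (r1, r2):
        if not r.rc_reactant_atoms and not r.rc_product_atoms:
            raise ReactionValidationError(f"reaction {r.id!r} has an empty RC")
    g1, g2 = _SidedGraph(r1), _SidedGraph(r2)
    best = 0
    fell_back = False
    state = [budget]
    for seed in _rc_bijections(g1, g2, criteria):
        rc1_set = set(g1.rc)
        rc2_set = set(g2.rc)
        # candidate non-RC pairs compatible with the whole seed
        pairs = [
            (i, j)
            for i in range(g1.n)
            if i not in rc1_set
            for j in range(g2.n)
            if j not in rc2_set and _nodes_compatible(g1, g2, i, j, criteria)
        ]
        pairs = [
            p
            for p in pairs
            if all(_pairs_consistent(g1, g2, p, q, criteria) for q in seed)
        ]
        compat = [
            {
                k
                for k, q in enumerate(pairs)
                if k != idx and _pairs_consistent(g1, g2, p, q, criteria)
            }
            for idx, p in enumerate(pairs)
        ]
        try:
            ext = _max_clique(list(range(len(pairs))), compat, state)
        except _BudgetExceeded as exc:
            ext = exc.best  # type: ignore[attr-defined]
            fell_back = True
            best = max(best, len(seed) + ext)
            break
        best = max(best, len(seed) + ext)
    return best, fell_back


DEFAULT_STEP_BUDGET = 2_000_000


def rcmcs_numerator(
    r1: Reaction,
    r2: Reaction,
    criteria: AtomMatchCriteria | None = None,
    step_budget: int = DEFAULT_STEP_BUDGET,
) -> int:
    """Atom count of the RC-containing maximum common subgraph (0 if no RC match)."""
    c = criteria or AtomMatchCriteria()
    size, fell_back = _rc_mcs_size(r1, r2, c, step_budget)
    if fell_back:
        logger.warning(
            "MCS step budget exceeded for (%s, %s); bounded-search result used",
            r1.id, r2.id,
        )
    return size


def rcmcs(
    r1: Reaction,
    r2: Reaction,
    criteria: AtomMatchCriteria | None = None,
    step_budget: int = DEFAULT_STEP_BUDGET,
) -> float:
    """RCMCS similarity: RC-containing MCS atoms over the larger reaction's atoms."""
    num = rcmcs_numerator(r1, r2, criteria, step_budget)
    return num / max(r1.n_atoms(), r2.n_atoms())


# ---------------------------------------------------------------------------
# exhaustive oracle
# ---------------------------------------------------------------------------

ORACLE_MAX_ATOMS_PER_SIDE = 16


def mcs_oracle(
    r1: Reaction, r2: Reaction, criteria: AtomMatchCriteria | None = None
) -> int:
    """Exhaustive RC-constrained common-subgraph search (test oracle).

    Enumerates every pairwise-consistent correspondence outright — no bounds,
    no pruning beyond consistency — and returns the true maximum atom count.
    Refuses graphs above ~16 atoms per reaction side.
    """
    c = criteria or AtomMatchCriteria()
    for r in (r1, r2):
        n_side = max(
            sum(m.GetNumAtoms() for m in r.reactants),
            sum(m.GetNumAtoms() for m in r.products),
        )
        if n_side > ORACLE_MAX_ATOMS_PER_SIDE:
            raise ValueError(
                f"oracle refuses reaction {r.id!r}: {n_side} atoms on one side"
            )
        if not r.rc_reactant_atoms and not r.rc_product_atoms:
            raise ReactionValidationError(f"reaction {r.id!r} has an empty RC")
    g1, g2 = _SidedGraph(r1), _SidedGraph(r2)
    best = 0
    for seed in _rc_bijections(g1, g2, c):
        rc1_set, rc2_set = set(g1.rc), set(g2.rc)
        pairs = [
            (i, j)
            for i in range(g1.n)
            if i not in rc1_set
            for j in range(g2.n)
            if j not in rc2_set
            and _nodes_compatible(g1, g2, i, j, c)
            and all(_pairs_consistent(g1, g2, (i, j), q, c) for q in seed)
        ]

        def grow(start: int, chosen: list[tuple[int, int]]) -> int:
            m = len(chosen)
            for k in range(start, len(pairs)):
                p = pairs[k]
                if all(_pairs_consistent(g1, g2, p, q, c) for q in chosen):
                    chosen.append(p)
                    m = max(m, grow(k + 1, chosen))
                    chosen.pop()
            return m

        best = max(best, len(seed) + grow(0, []))
    return best


# ---------------------------------------------------------------------------
# GSI
# ---------------------------------------------------------------------------

_AA = set("ACDEFGHIKLMNPQRSTVWYX")
_ALIGNER = None


def _aligner() -> Align.PairwiseAligner:
    global _ALIGNER
    if _ALIGNER is None:
        a = Align.PairwiseAligner()
        a.mode = "local"
        a.substitution_matrix = substitution_matrices.load("BLOSUM62")
        a.open_gap_score = -11.0
        a.extend_gap_score = -1.0
        _ALIGNER = a
    return _ALIGNER


def gsi(seq1: str, seq2: str) -> float:
    """Global sequence identity from a local alignment.

    Identically aligned residues of the best local alignment (BLOSUM62,
    gap open 11 / extend 1) divided by the longer sequence's length.
    """
    for s in (seq1, seq2):
        if not s:
            raise ValueError("empty sequence")
        for pos, ch in enumerate(s):
            if ch not in _AA:
                raise ValueError(f"non-standard residue {ch!r} at position {pos}")
    aln = _aligner().align(seq1, seq2)
    if aln.score <= 0:
        return 0.0
    identities = aln[0].counts().identities
    return identities / max(len(seq1), len(seq2))


# ---------------------------------------------------------------------------
# pairwise matrix
# ---------------------------------------------------------------------------


def pairwise_matrix(
    items,
    metric: str,
    criteria: AtomMatchCriteria | None = None,
    step_budget: int = DEFAULT_STEP_BUDGET,
) -> SimilarityMatrix:
    """All-pairs similarity matrix.

    ``items``: list of :class:`Reaction` for ``metric='rcmcs'``; list of
    ``(id, sequence)`` for ``metric='gsi'``.  Pairs exceeding the MCS step
    budget use the bounded-search value and are recorded in
    ``fallback_pairs``.
    """
    if len(items) < 2:
        raise ValueError("need at least 2 items")
    if metric == "rcmcs":
        ids = [r.id for r in items]
    elif metric == "gsi":
        ids = [i for i, _ in items]
    else:
        raise ValueError(f"unknown metric {metric!r}")
    n = len(items)
    s = np.eye(n)
    fallback: list[tuple[str, str]] = []
    c = criteria or AtomMatchCriteria()
    for i in range(n):
        for j in range(i + 1, n):
            if metric == "rcmcs":
                size, fell = _rc_mcs_size(items[i], items[j], c, step_budget)
                val = size / max(items[i].n_atoms(), items[j].n_atoms())
                if fell:
                    fallback.append((ids[i], ids[j]))
            else:
                val = gsi(items[i][1], items[j][1])
            s[i, j] = s[j, i] = val
    return SimilarityMatrix(ids=ids, scores=s, metric=metric, fallback_pairs=fallback)
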
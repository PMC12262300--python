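"""Reaction encoders: five ways to map a reaction to a fixed-length vector.

All graph variants share one directed-edge (bond-centric) message-passing
core: hidden states live on directed bonds, and each update aggregates the
states of edges flowing into an edge's source atom, excluding the reverse
edge.  With M message passings in total (the initialization pass plus M−1
updates), a node's readout embedding depends only on features within M−1
bonds — the receptive field that makes the RC-aggregated encoder's locality
claim exact.

Variants
--------
bag_of_molecules    mean of all atom embeddings, no RC information
rc_connected        virtual node wired to the RC atoms of both sides; mean
                    of all *atom* embeddings (the virtual node is excluded)
rc_aggregated       same augmentation; the reaction is represented by the
                    virtual node's embedding alone
cgr                 condensed graph of reaction: one node per mapped atom
                    pair carrying reactant and product features side by side
morgan              summed circular count fingerprints per side, elementwise
                    absolute difference, learned linear projection
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem
from rdkit.Chem import rdFingerprintGenerator

from . import autodiff as ad
from .autodiff import Tensor
from .reaction_core import Reaction, ReactionValidationError

__all__ = [
    "EncoderConfig",
    "ReactionGraph",
    "ATOM_FEATURE_DIM",
    "BOND_FEATURE_DIM",
    "atom_features",
    "bond_features",
    "build_reaction_graph",
    "batch_graphs",
    "init_encoder_weights",
    "message_passing",
    "aggregate",
    "morgan_encode",
    "morgan_fingerprint",
    "embed_reaction",
    "embed_graph",
    "encode_batch",
]

GNN_VARIANTS = ("bag_of_molecules", "rc_connected", "rc_aggregated", "cgr")
VARIANTS = GNN_VARIANTS + ("morgan",)

_ELEMENTS = ("C", "N", "O", "S", "P", "F", "Cl", "Br", "I")
_HYBRID = (
    Chem.HybridizationType.SP,
    Chem.HybridizationType.SP2,
    Chem.HybridizationType.SP3,
    Chem.HybridizationType.SP3D,
    Chem.HybridizationType.SP3D2,
)

# one-hot blocks: element(+other) | degree 0-5(+other) | charge -2..2(+other)
# | H count 0-4(+other) | hybridization(+other) | aromatic | scaled mass
ATOM_FEATURE_DIM = (len(_ELEMENTS) + 1) + 7 + 6 + 6 + (len(_HYBRID) + 1) + 1 + 1
# order s/d/t/aromatic | conjugated | ring | virtual-edge
BOND_FEATURE_DIM = 4 + 1 + 1 + 1
# bond state within a CGR half: order one-hot + absent | conjugated | ring
_CGR_BOND_STATE = 5 + 1 + 1


def _one_hot(value, choices, other: bool = True) -> list[float]:
    v = [1.0 if value == c else 0.0 for c in choices]
    if other:
        v.append(0.0 if any(v) else 1.0)
    return v


def atom_features(atom: Chem.Atom, side: int | None = None) -> np.ndarray:
    """Atom invariants; ``side`` (0 reactant / 1 product) appends a direction bit.

    The side bit makes the disjoint-union encoders directional: swapping
    reactants and products changes the embedding.  The CGR variant omits it —
    its (reactant ∥ product) feature concatenation is directional already.
    """
    f = (
        _one_hot(atom.GetSymbol(), _ELEMENTS)
        + _one_hot(min(atom.GetTotalDegree(), 6), range(6))
        + _one_hot(atom.GetFormalCharge(), range(-2, 3))
        + _one_hot(min(atom.GetTotalNumHs(), 5), range(5))
        + _one_hot(atom.GetHybridization(), _HYBRID)
        + [1.0 if atom.GetIsAromatic() else 0.0]
        + [atom.GetMass() * 0.01]
    )
    if side is not None:
        f = f + [float(side)]
    return np.asarray(f, dtype=np.float64)


def bond_features(bond: Chem.Bond | None, virtual: bool = False) -> np.ndarray:
    if virtual:
        f = [0.0] * 6 + [1.0]
    else:
        bt = bond.GetBondType()
        f = [
            1.0 if bt == Chem.BondType.SINGLE else 0.0,
            1.0 if bt == Chem.BondType.DOUBLE else 0.0,
            1.0 if bt == Chem.BondType.TRIPLE else 0.0,
            1.0 if bt == Chem.BondType.AROMATIC else 0.0,
            1.0 if bond.GetIsConjugated() else 0.0,
            1.0 if bond.IsInRing() else 0.0,
            0.0,
        ]
    return np.asarray(f, dtype=np.float64)


def _cgr_bond_state(bond: Chem.Bond | None) -> list[float]:
    if bond is None:
        return [0.0, 0.0, 0.0, 0.0, 1.0, 0.0, 0.0]  # explicit "absent" state
    bt = bond.GetBondType()
    return [
        1.0 if bt == Chem.BondType.SINGLE else 0.0,
        1.0 if bt == Chem.BondType.DOUBLE else 0.0,
        1.0 if bt == Chem.BondType.TRIPLE else 0.0,
        1.0 if bt == Chem.BondType.AROMATIC else 0.0,
        0.0,
        1.0 if bond.GetIsConjugated() else 0.0,
        1.0 if bond.IsInRing() else 0.0,
    ]


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


def _default_m(variant: str) -> int:
    return 4 if variant == "rc_aggregated" else 6


@dataclass(frozen=True)
class EncoderConfig:
    """Encoder variant, message-passing depth and dimensions.

    Defaults: 4 message passings for the RC-aggregated encoder, 6 for the
    other graph variants; embedding dimension 300; Morgan radius 2 over 2048
    bits.  ``hidden_dim`` defaults to the embedding dimension.
    """

    variant: str = "rc_aggregated"
    message_passings: int | None = None
    embedding_dim: int = 300
    hidden_dim: int | None = None
    morgan_radius: int = 2
    morgan_nbits: int = 2048
    seed: int = 0

    def __post_init__(self):
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown encoder variant {self.variant!r}")
        if self.m < 1 or self.embedding_dim < 1 or self.h < 1:
            raise ValueError("dimensions and message passings must be positive")

    @property
    def m(self) -> int:
        return self.message_passings or _default_m(self.variant)

    @property
    def h(self) -> int:
        return self.hidden_dim or self.embedding_dim

    def atom_dim(self) -> int:
        # non-CGR variants carry an extra reactant/product side bit per node
        return 2 * ATOM_FEATURE_DIM if self.variant == "cgr" else ATOM_FEATURE_DIM + 1

    def bond_dim(self) -> int:
        return 2 * _CGR_BOND_STATE if self.variant == "cgr" else BOND_FEATURE_DIM


# ---------------------------------------------------------------------------
# graph construction
# ---------------------------------------------------------------------------


@dataclass
class ReactionGraph:
    """Directed-edge view of a reaction for message passing.

    Node sides: 0 = reactant atom, 1 = product atom, 2 = virtual node,
    3 = condensed (CGR) node.  Edge arrays hold both directions of every
    bond; ``rev[k]`` is the index of edge k's reverse.
    """

    node_features: np.ndarray  # (n, Fa); virtual node row is all zero
    side: np.ndarray  # (n,)
    rc_mask: np.ndarray  # (n,) bool
    src: np.ndarray  # (e,)
    dst: np.ndarray  # (e,)
    rev: np.ndarray  # (e,)
    edge_features: np.ndarray  # (e, Fb)
    virtual_index: int | None
    variant: str

    @property
    def n_nodes(self) -> int:
        return self.node_features.shape[0]

    def real_mask(self) -> np.ndarray:
        return self.side != 2


def _add_undirected(edges, i, j, feat):
    k = len(edges["src"])
    edges["src"] += [i, j]
    edges["dst"] += [j, i]
    edges["rev"] += [k + 1, k]
    edges["feat"] += [feat, feat]


def build_reaction_graph(r: Reaction, variant: str) -> ReactionGraph:
    """Assemble the variant-specific graph of a reaction."""
    if variant not in GNN_VARIANTS:
        raise ValueError(f"not a graph variant: {variant!r}")
    if variant == "cgr":
        return _build_cgr_graph(r)
    use_virtual = variant in ("rc_connected", "rc_aggregated")
    if use_virtual and (not r.rc_reactant_atoms or not r.rc_product_atoms):
        raise ReactionValidationError(
            f"reaction {r.id!r}: RC annotation required for variant {variant!r}"
        )
    feats, sides, rc = [], [], []
    edges = {"src": [], "dst": [], "rev": [], "feat": []}
    n_react = sum(m.GetNumAtoms() for m in r.reactants)
    for s, mols, rcset in (
        (0, r.reactants, r.rc_reactant_atoms),
        (1, r.products, r.rc_product_atoms),
    ):
        base = 0 if s == 0 else n_react
        off = base
        for m in mols:
            for a in m.GetAtoms():
                feats.append(atom_features(a, side=s))
                sides.append(s)
                rc.append((off + a.GetIdx() - base) in rcset)
            for b in m.GetBonds():
                _add_undirected(
                    edges,
                    off + b.GetBeginAtomIdx(),
                    off + b.GetEndAtomIdx(),
                    bond_features(b),
                )
            off += m.GetNumAtoms()
    virtual_index = None
    if use_virtual:
        virtual_index = len(feats)
        feats.append(np.zeros(ATOM_FEATURE_DIM + 1))
        sides.append(2)
        rc.append(False)
        vfeat = bond_features(None, virtual=True)
        for i, flag in enumerate(rc[:-1]):
            if flag:
                _add_undirected(edges, i, virtual_index, vfeat)
    return ReactionGraph(
        node_features=np.asarray(feats),
        side=np.asarray(sides),
        rc_mask=np.asarray(rc, dtype=bool),
        src=np.asarray(edges["src"], dtype=np.intp),
        dst=np.asarray(edges["dst"], dtype=np.intp),
        rev=np.asarray(edges["rev"], dtype=np.intp),
        edge_features=(
            np.asarray(edges["feat"])
            if edges["feat"]
            else np.zeros((0, BOND_FEATURE_DIM))
        ),
        virtual_index=virtual_index,
        variant=variant,
    )


def _build_cgr_graph(r: Reaction) -> ReactionGraph:
    """One node per mapped atom pair; edges carry (before, after) bond states."""
    if not r.map_is_total():
        raise ReactionValidationError(
            f"reaction {r.id!r}: CGR requires a total atom map"
        )
    nums = sorted(r.atom_map)
    node_of = {num: k for k, num in enumerate(nums)}

    def atoms_by_global(mols):
        out = []
        for m in mols:
            out.extend(m.GetAtoms())
        return out

    r_atoms = atoms_by_global(r.reactants)
    p_atoms = atoms_by_global(r.products)
    feats, rc = [], []
    rc_r = r.rc_reactant_atoms
    for num in nums:
        rg, pg = r.atom_map[num]
        feats.append(np.concatenate([atom_features(r_atoms[rg]), atom_features(p_atoms[pg])]))
        rc.append(rg in rc_r)

    def bond_lookup(mols):
        table = {}
        for m in mols:
            for b in m.GetBonds():
                n1 = b.GetBeginAtom().GetAtomMapNum()
                n2 = b.GetEndAtom().GetAtomMapNum()
                table[frozenset((n1, n2))] = b
        return table

    rb, pb = bond_lookup(r.reactants), bond_lookup(r.products)
    edges = {"src": [], "dst": [], "rev": [], "feat": []}
    for key in set(rb) | set(pb):
        n1, n2 = tuple(key)
        feat = np.asarray(
            _cgr_bond_state(rb.get(key)) + _cgr_bond_state(pb.get(key))
        )
        _add_undirected(edges, node_of[n1], node_of[n2], feat)
    return ReactionGraph(
        node_features=np.asarray(feats),
        side=np.full(len(feats), 3),
        rc_mask=np.asarray(rc, dtype=bool),
        src=np.asarray(edges["src"], dtype=np.intp),
        dst=np.asarray(edges["dst"], dtype=np.intp),
        rev=np.asarray(edges["rev"], dtype=np.intp),
        edge_features=(
            np.asarray(edges["feat"])
            if edges["feat"]
            else np.zeros((0, 2 * _CGR_BOND_STATE))
        ),
        virtual_index=None,
        variant="cgr",
    )


@dataclass
class BatchedGraphs:
    """Disjoint union of reaction graphs with per-node graph ids."""

    graph: ReactionGraph
    graph_id: np.ndarray  # (n,)
    n_graphs: int
    virtual_rows: np.ndarray | None  # (B,) virtual node row per graph, if any


def batch_graphs(graphs: list[ReactionGraph]) -> BatchedGraphs:
    variant = graphs[0].variant
    assert all(g.variant == variant for g in graphs)
    feats, sides, rc, gid = [], [], [], []
    src, dst, rev, efeat = [], [], [], []
    virtual_rows = [] if graphs[0].virtual_index is not None else None
    n_off = e_off = 0
    for b, g in enumerate(graphs):
        feats.append(g.node_features)
        sides.append(g.side)
        rc.append(g.rc_mask)
        gid.append(np.full(g.n_nodes, b))
        src.append(g.src + n_off)
        dst.append(g.dst + n_off)
        rev.append(g.rev + e_off)
        efeat.append(g.edge_features)
        if virtual_rows is not None:
            virtual_rows.append(g.virtual_index + n_off)
        n_off += g.n_nodes
        e_off += len(g.src)
    merged = ReactionGraph(
        node_features=np.concatenate(feats),
        side=np.concatenate(sides),
        rc_mask=np.concatenate(rc),
        src=np.concatenate(src),
        dst=np.concatenate(dst),
        rev=np.concatenate(rev),
        edge_features=np.concatenate(efeat),
        virtual_index=None,
        variant=variant,
    )
    return BatchedGraphs(
        graph=merged,
        graph_id=np.concatenate(gid),
        n_graphs=len(graphs),
        virtual_rows=np.asarray(virtual_rows, dtype=np.intp)
        if virtual_rows is not None
        else None,
    )


# ---------------------------------------------------------------------------
# weights
# ---------------------------------------------------------------------------


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    scale = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-scale, scale, size=(fan_in, fan_out))


def init_encoder_weights(cfg: EncoderConfig) -> dict[str, Tensor]:
    """Seeded Glorot-uniform initialization of all encoder parameters."""
    rng = np.random.default_rng(cfg.seed)
    d, h = cfg.embedding_dim, cfg.h
    if cfg.variant == "morgan":
        return {"W_proj": Tensor(_glorot(rng, cfg.morgan_nbits, d), requires_grad=True)}
    fa, fb = cfg.atom_dim(), cfg.bond_dim()
    return {
        "W_in": Tensor(_glorot(rng, fa + fb, h), requires_grad=True),
        "W_msg": Tensor(_glorot(rng, h, h), requires_grad=True),
        "W_read": Tensor(_glorot(rng, fa + h, h), requires_grad=True),
        "W_out": Tensor(_glorot(rng, h, d), requires_grad=True),
    }


# ---------------------------------------------------------------------------
# message passing and aggregation
# ---------------------------------------------------------------------------


class _GraphOps:
    """Constant per-graph operators for fast message passing.

    ``s_dst`` sums directed-edge states into their destination nodes;
    ``g_src`` broadcasts per-node sums back onto edges by source atom;
    ``rev`` (an involution) swaps each edge with its reverse; ``m0`` is the
    constant [source-node features ∥ edge features] input block.
    """

    def __init__(self, g: ReactionGraph):
        from scipy.sparse import csr_matrix

        e, n = len(g.src), g.n_nodes
        ones = np.ones(e)
        self.s_dst = csr_matrix((ones, (g.dst, np.arange(e))), shape=(n, e))
        self.s_dst_t = self.s_dst.T.tocsr()
        self.g_src = csr_matrix((ones, (np.arange(e), g.src)), shape=(e, n))
        self.g_src_t = self.g_src.T.tocsr()
        self.rev = g.rev
        self.m0 = (
            np.concatenate([g.node_features[g.src], g.edge_features], axis=1)
            if e
            else np.zeros((0, g.node_features.shape[1] + g.edge_features.shape[1]))
        )


def _graph_ops(g: ReactionGraph) -> _GraphOps:
    ops = g.__dict__.get("_ops_cache")
    if ops is None:
        ops = _GraphOps(g)
        g.__dict__["_ops_cache"] = ops
    return ops


def message_passing(
    g: ReactionGraph, weights: dict[str, Tensor], m_steps: int
) -> Tensor:
    """Directed-edge message passing; returns per-node embeddings (n, h).

    The initialization pass sets every directed edge's state from its source
    node and bond features; each of the remaining ``m_steps − 1`` updates
    aggregates states of edges entering the source atom, excluding the
    reverse edge.  Node readout combines each node's features with the sum
    of its incoming final edge states.
    """
    if m_steps < 1:
        raise ValueError("need at least one message passing")
    for w in weights.values():
        if not np.all(np.isfinite(w.data)):
            raise ValueError("non-finite encoder weights")
    X = Tensor(g.node_features)
    n = g.n_nodes
    if len(g.src) == 0:
        msgs = Tensor(np.zeros((n, weights["W_msg"].shape[0])))
    else:
        ops = _graph_ops(g)
        h0 = ad.relu(ad.matmul(Tensor(ops.m0), weights["W_in"]))
        h = h0
        for _ in range(m_steps - 1):
            node_in = ad.spmm(ops.s_dst, ops.s_dst_t, h)
            incoming = ad.spmm(ops.g_src, ops.g_src_t, node_in) - ad.permute_rows(
                h, ops.rev, ops.rev
            )
            h = ad.relu(h0 + ad.matmul(incoming, weights["W_msg"]))
        msgs = ad.spmm(ops.s_dst, ops.s_dst_t, h)
    return ad.relu(ad.matmul(ad.concat([X, msgs]), weights["W_read"]))


def aggregate(
    node_embeddings: Tensor,
    g: ReactionGraph,
    variant: str,
    weights: dict[str, Tensor],
) -> Tensor:
    """Variant aggregation followed by the learned output projection (1, d)."""
    if variant != g.variant:
        raise ValueError(f"graph built for {g.variant!r}, not {variant!r}")
    if variant == "rc_aggregated":
        agg = ad.gather_rows(node_embeddings, np.array([g.virtual_index]))
    else:
        real = np.flatnonzero(g.real_mask())
        rows = ad.gather_rows(node_embeddings, real)
        agg = ad.scatter_add(rows, np.zeros(len(real), dtype=np.intp), 1) * (
            1.0 / len(real)
        )
    return ad.matmul(agg, weights["W_out"])


# ---------------------------------------------------------------------------
# Morgan fingerprint path
# ---------------------------------------------------------------------------

_FP_GENS: dict[tuple[int, int], object] = {}


def _fp_gen(radius: int, nbits: int):
    key = (radius, nbits)
    if key not in _FP_GENS:
        _FP_GENS[key] = rdFingerprintGenerator.GetMorganGenerator(
            radius=radius, fpSize=nbits
        )
    return _FP_GENS[key]


def morgan_fingerprint(r: Reaction, radius: int = 2, nbits: int = 2048) -> np.ndarray:
    """|sum of reactant count fingerprints − sum of product count fingerprints|."""
    gen = _fp_gen(radius, nbits)

    def side_sum(mols):
        total = np.zeros(nbits)
        for m in mols:
            m2 = Chem.Mol(m)
            for a in m2.GetAtoms():
                a.SetAtomMapNum(0)
            fp = gen.GetCountFingerprint(m2)
            for bit, count in fp.GetNonzeroElements().items():
                total[bit] += count
        return total

    return np.abs(side_sum(r.reactants) - side_sum(r.products))


def morgan_encode(
    r: Reaction, weights: dict[str, Tensor], radius: int = 2, nbits: int = 2048
) -> Tensor:
    fp = Tensor(morgan_fingerprint(r, radius, nbits)[None, :])
    return ad.matmul(fp, weights["W_proj"])


# ---------------------------------------------------------------------------
# top-level encoding
# ---------------------------------------------------------------------------


def encode_batch(
    batch: BatchedGraphs | np.ndarray,
    cfg: EncoderConfig,
    weights: dict[str, Tensor],
) -> Tensor:
    """Embed a batch of reactions; returns a (B, d) Tensor on the tape.

    For graph variants ``batch`` is a :class:`BatchedGraphs`; for the Morgan
    variant it is the precomputed (B, nbits) fingerprint matrix.
    """
    if cfg.variant == "morgan":
        return ad.matmul(Tensor(batch), weights["W_proj"])
    node_emb = message_passing(batch.graph, weights, cfg.m)
    if cfg.variant == "rc_aggregated":
        return ad.matmul(
            ad.gather_rows(node_emb, batch.virtual_rows), weights["W_out"]
        )
    mean_op = batch.__dict__.get("_mean_ops")
    if mean_op is None:
        from scipy.sparse import csr_matrix

        real = np.flatnonzero(batch.graph.real_mask())
        gid = batch.graph_id[real]
        counts = np.bincount(gid, minlength=batch.n_graphs).astype(float)
        A = csr_matrix(
            (1.0 / counts[gid], (gid, real)),
            shape=(batch.n_graphs, batch.graph.n_nodes),
        )
        mean_op = (A, A.T.tocsr())
        batch.__dict__["_mean_ops"] = mean_op
    mean = ad.spmm(mean_op[0], mean_op[1], node_emb)
    return ad.matmul(mean, weights["W_out"])


def embed_reaction(
    r: Reaction, cfg: EncoderConfig, weights: dict[str, Tensor]
) -> np.ndarray:
    """Deterministic embedding vector (d,) of one reaction under fixed weights."""
    if cfg.variant == "morgan":
        return morgan_encode(r, weights, cfg.morgan_radius, cfg.morgan_nbits).data[0]
    g = build_reaction_graph(r, cfg.variant)
    node_emb = message_passing(g, weights, cfg.m)
    return aggregate(node_emb, g, cfg.variant, weights).data[0]


def embed_graph(
    g: ReactionGraph, cfg: EncoderConfig, weights: dict[str, Tensor]
) -> np.ndarray:
    """Embedding from an already-built (possibly perturbed) reaction graph."""
    node_emb = message_passing(g, weights, cfg.m)
    return aggregate(node_emb, g, cfg.variant, weights).data[0]
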
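"""Synthetic enzyme-reaction datasets with the statistical structure the model assumes.

Reactions: a small library of hand-written, chemically valid reaction-center
template reactions (ester and amide hydrolysis, ketone reduction,
decarboxylation, alcohol oxidation, alkene hydration), each decorated with
random substituent trees grafted identically onto both sides at designated
attachment atoms, preserving the atom map.  Every generated reaction is
fully mapped, RC-annotated with the template core, and standardizes cleanly.
The planted catalysis signal is therefore RC-local by construction:
substituents beyond the core never affect pair labels.

Proteins: embedding vectors drawn around C cluster centroids, and sequences
mutated from a per-cluster ancestor so that sequence identity is higher
within clusters than between them.

Positives: protein cluster c catalyzes reaction family (c mod F), with
cross-family "promiscuous" positives added at a configurable rate; the
bipartite adjacency density is tuned to a target.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from rdkit import Chem

from .reaction_core import (
    Reaction,
    _side_map_index,
    derive_rc_from_map,
    parse_reaction,
    standardize_reaction,
)
from .scoring_model import ProteinRecord

__all__ = [
    "SynthConfig",
    "TEMPLATES",
    "generate_reactions",
    "generate_proteins",
    "plant_positives",
    "generate_dataset",
]


@dataclass(frozen=True)
class ReactionTemplate:
    name: str
    smiles: str  # fully atom-mapped core reaction
    attachment_maps: tuple[int, ...]  # map numbers of substituent attachment atoms


# ≥5 chemically valid cores; attachment atoms are methyl/methylene carbons
# that give up one hydrogen for the graft
TEMPLATES: tuple[ReactionTemplate, ...] = (
    ReactionTemplate(
        "ester_hydrolysis",
        "[CH3:1][C:2](=[O:3])[O:4][CH3:5].[OH2:6]"
        ">>[CH3:1][C:2](=[O:3])[OH:6].[CH3:5][OH:4]",
        (1, 5),
    ),
    ReactionTemplate(
        "ketone_reduction",
        "[CH3:1][C:2](=[O:3])[CH3:4]>>[CH3:1][CH:2]([OH:3])[CH3:4]",
        (1, 4),
    ),
    ReactionTemplate(
        "decarboxylation",
        "[CH3:1][CH2:2][C:3](=[O:4])[OH:5]>>[CH3:1][CH3:2].[O:4]=[C:3]=[O:5]",
        (1,),
    ),
    ReactionTemplate(
        "amide_hydrolysis",
        "[CH3:1][C:2](=[O:3])[NH:4][CH3:5].[OH2:6]"
        ">>[CH3:1][C:2](=[O:3])[OH:6].[CH3:5][NH2:4]",
        (1, 5),
    ),
    ReactionTemplate(
        "alcohol_oxidation",
        "[CH3:1][CH2:2][OH:3]>>[CH3:1][CH:2]=[O:3]",
        (1,),
    ),
    ReactionTemplate(
        "alkene_hydration",
        "[CH2:1]=[C:2]([CH3:3])[CH3:4].[OH2:5]>>[CH3:1][C:2]([OH:5])([CH3:3])[CH3:4]",
        (3, 4),
    ),
)


@dataclass(frozen=True)
class SynthConfig:
    """Study conditions of the synthetic corpus.

    Defaults give 200 reactions x 200 proteins with ~400 planted positives
    (density 0.01) — large enough to train the scorer in minutes on one CPU,
    sparse like the real enzyme-reaction adjacency but dense enough that
    folds contain usable positive counts at this scale.
    """

    n_templates: int = 5
    reactions_per_template: int = 40
    max_substituent_atoms: int = 4
    substituent_vocab: tuple[str, ...] = ("C", "C", "C", "O", "N")
    n_protein_clusters: int = 5
    proteins_per_cluster: int = 40
    embedding_dim: int = 1280
    noise_scale: float = 0.25
    sequence_length: int = 120
    mutation_rate: float = 0.15
    promiscuity_rate: float = 0.05
    positive_density: float = 0.01
    seed: int = 0

    def __post_init__(self):
        if self.n_templates < 2 or self.n_protein_clusters < 2:
            raise ValueError("need at least 2 reaction families and 2 protein clusters")
        if not (2 <= self.n_templates <= len(TEMPLATES)):
            raise ValueError(f"n_templates must be in [2, {len(TEMPLATES)}]")
        if not (0 <= self.promiscuity_rate < 1):
            raise ValueError("promiscuity_rate must be in [0, 1)")
        if not (0 < self.positive_density < 1):
            raise ValueError("positive_density must be in (0, 1)")


# ---------------------------------------------------------------------------
# reactions
# ---------------------------------------------------------------------------

_MAX_VALENCE = {"C": 4, "N": 3, "O": 2}


def _random_substituent(rng: np.random.Generator, cfg: SynthConfig) -> list[tuple[str, int]]:
    """A random substituent tree as (element, parent) pairs; parent -1 = root.

    The root is carbon (it bonds to the attachment atom); heteroatoms attach
    only to carbons, keeping every graft chemically unremarkable.
    """
    size = int(rng.integers(0, cfg.max_substituent_atoms + 1))
    if size == 0:
        return []
    atoms: list[tuple[str, int]] = [("C", -1)]
    free = {0: _MAX_VALENCE["C"] - 1}  # one valence goes to the attachment bond
    for _ in range(size - 1):
        elem = str(rng.choice(cfg.substituent_vocab))
        hosts = [
            i
            for i, v in free.items()
            if v > 0 and (elem == "C" or atoms[i][0] == "C")
        ]
        if not hosts:
            break
        parent = int(hosts[rng.integers(len(hosts))])
        idx = len(atoms)
        atoms.append((elem, parent))
        free[parent] -= 1
        free[idx] = _MAX_VALENCE[elem] - 1
    return atoms


def _graft(mol: Chem.Mol, attach_map: int, tree, map_nums: list[int]) -> Chem.Mol:
    """Attach a substituent tree to the atom with the given map number."""
    rw = Chem.RWMol(mol)
    target = next(
        a.GetIdx() for a in rw.GetAtoms() if a.GetAtomMapNum() == attach_map
    )
    ta = rw.GetAtomWithIdx(target)
    if ta.GetTotalNumHs() < len([1 for _, p in tree if p == -1]):
        raise ValueError("attachment atom lacks hydrogens")
    new_idx: list[int] = []
    for (elem, parent), num in zip(tree, map_nums):
        a = Chem.Atom(elem)
        a.SetAtomMapNum(num)
        idx = rw.AddAtom(a)
        new_idx.append(idx)
        host = target if parent == -1 else new_idx[parent]
        if parent == -1 and ta.GetNoImplicit():
            ta.SetNumExplicitHs(ta.GetNumExplicitHs() - 1)
        rw.AddBond(host, idx, Chem.BondType.SINGLE)
    out = rw.GetMol()
    Chem.SanitizeMol(out)
    return out


_template_rc_maps_cache: dict[str, frozenset[int]] = {}


def template_core_maps(t: ReactionTemplate) -> frozenset[int]:
    """Map numbers of the template's own RC (derived once from its atom map)."""
    if t.name not in _template_rc_maps_cache:
        r = derive_rc_from_map(parse_reaction(t.smiles, t.name))
        num_of_rg = {rg: num for num, (rg, _) in r.atom_map.items()}
        _template_rc_maps_cache[t.name] = frozenset(
            num_of_rg[g] for g in r.rc_reactant_atoms
        )
    return _template_rc_maps_cache[t.name]


def _decorate(
    t: ReactionTemplate, rng: np.random.Generator, cfg: SynthConfig, rid: str
) -> Reaction:
    base = parse_reaction(t.smiles, rid)
    next_map = max(base.atom_map) + 1
    reactants = [Chem.Mol(m) for m in base.reactants]
    products = [Chem.Mol(m) for m in base.products]
    for attach in t.attachment_maps:
        tree = _random_substituent(rng, cfg)
        if not tree:
            continue
        nums = list(range(next_map, next_map + len(tree)))
        next_map += len(tree)

        def graft_side(mols):
            for k, m in enumerate(mols):
                if any(a.GetAtomMapNum() == attach for a in m.GetAtoms()):
                    mols[k] = _graft(m, attach, tree, nums)
                    return
            raise ValueError(f"attachment map {attach} absent")

        graft_side(reactants)
        graft_side(products)
    rmap = _side_map_index(reactants)
    pmap = _side_map_index(products)
    core = template_core_maps(t)
    return Reaction(
        id=rid,
        reactants=reactants,
        products=products,
        atom_map={n: (rmap[n], pmap[n]) for n in rmap if n in pmap},
        rc_reactant_atoms=frozenset(rmap[n] for n in core),
        rc_product_atoms=frozenset(pmap[n] for n in core),
    )


def generate_reactions(cfg: SynthConfig) -> tuple[list[Reaction], list[int]]:
    """Decorated template reactions plus each reaction's family index.

    Every output is standardized (idempotently — the generator emits neutral,
    stereo-free structures), fully mapped and RC-annotated with the template
    core.  Valence-violating decorations are resampled with bounded retries.
    """
    rng = np.random.default_rng(cfg.seed)
    reactions: list[Reaction] = []
    families: list[int] = []
    for fi in range(cfg.n_templates):
        t = TEMPLATES[fi]
        for k in range(cfg.reactions_per_template):
            rid = f"rxn_{t.name}_{k:03d}"
            for _attempt in range(20):
                try:
                    r = _decorate(t, rng, cfg, rid)
                    r, _ = standardize_reaction(r)
                    break
                except Exception:
                    continue
            else:
                raise RuntimeError(f"could not decorate template {t.name}")
            reactions.append(r)
            families.append(fi)
    return reactions, families


# ---------------------------------------------------------------------------
# proteins
# ---------------------------------------------------------------------------

_AA20 = np.array(list("ACDEFGHIKLMNPQRSTVWY"))


def generate_proteins(cfg: SynthConfig) -> tuple[list[ProteinRecord], list[int]]:
    """Clustered protein records plus each protein's cluster index.

    Embeddings: isotropic Gaussian centroids of roughly unit norm, members
    perturbed at ``noise_scale``.  Sequences: a random ancestor per cluster,
    members with point mutations at ``mutation_rate`` — so sequence identity
    is systematically higher within clusters than between them.
    """
    rng = np.random.default_rng(cfg.seed + 1)
    d = cfg.embedding_dim
    centroids = rng.normal(size=(cfg.n_protein_clusters, d)) / np.sqrt(d)
    records: list[ProteinRecord] = []
    clusters: list[int] = []
    for c in range(cfg.n_protein_clusters):
        ancestor = rng.choice(_AA20, size=cfg.sequence_length)
        for k in range(cfg.proteins_per_cluster):
            emb = centroids[c] + cfg.noise_scale * rng.normal(size=d) / np.sqrt(d)
            seq = ancestor.copy()
            mut = rng.random(cfg.sequence_length) < cfg.mutation_rate
            seq[mut] = rng.choice(_AA20, size=int(mut.sum()))
            records.append(
                ProteinRecord(
                    id=f"prot_c{c}_{k:03d}", sequence="".join(seq), embedding=emb
                )
            )
            clusters.append(c)
    return records, clusters


# ---------------------------------------------------------------------------
# planted positives
# ---------------------------------------------------------------------------


def plant_positives(
    reactions: list[Reaction],
    families: list[int],
    proteins: list[ProteinRecord],
    clusters: list[int],
    cfg: SynthConfig,
) -> tuple[list[tuple[str, str]], list[tuple[str, str]]]:
    """Sparse bipartite positives: cluster c catalyzes family c (mod F).

    A fraction ``promiscuity_rate`` of the planted positives are cross-family
    ("promiscuous") pairs; the rest are drawn uniformly from the matching
    cluster-family blocks.  Counts are sampled exactly, so the realized
    adjacency density is within 10% of the target (to rounding).  Returns
    (all positives, the promiscuous subset).
    """
    rng = np.random.default_rng(cfg.seed + 2)
    F = cfg.n_templates
    n_p, n_r = len(proteins), len(reactions)
    in_block = [
        (pi, ri)
        for pi in range(n_p)
        for ri in range(n_r)
        if families[ri] == clusters[pi] % F
    ]
    target = int(round(cfg.positive_density * n_p * n_r))
    n_out = int(round(cfg.promiscuity_rate * target))
    n_in = target - n_out
    if n_in > len(in_block):
        raise ValueError(
            f"positive density {cfg.positive_density} unreachable: "
            f"{n_in} in-block positives requested, {len(in_block)} pairs exist"
        )
    chosen = [in_block[i] for i in rng.choice(len(in_block), size=n_in, replace=False)]
    promiscuous: list[tuple[str, str]] = []
    if n_out > 0:
        out_block = [
            (pi, ri)
            for pi in range(n_p)
            for ri in range(n_r)
            if families[ri] != clusters[pi] % F
        ]
        extra = [out_block[i] for i in rng.choice(len(out_block), size=n_out, replace=False)]
        promiscuous = sorted(
            (proteins[pi].id, reactions[ri].id) for pi, ri in extra
        )
        chosen += extra
    return (
        sorted((proteins[pi].id, reactions[ri].id) for pi, ri in chosen),
        promiscuous,
    )


def generate_dataset(cfg: SynthConfig):
    """Reactions, proteins, planted positives and their hidden group labels.

    The returned dict also carries ``true_positive``, the ground-truth
    relation of the synthetic world — every matching cluster-family pair
    plus the promiscuous extras — for planted-recovery evaluation.
    """
    reactions, families = generate_reactions(cfg)
    proteins, clusters = generate_proteins(cfg)
    positives, promiscuous = plant_positives(
        reactions, families, proteins, clusters, cfg
    )
    family_of = {r.id: f for r, f in zip(reactions, families)}
    cluster_of = {p.id: c for p, c in zip(proteins, clusters)}
    prom = set(promiscuous)
    F = cfg.n_templates

    def true_positive(protein_id: str, reaction_id: str) -> bool:
        if (protein_id, reaction_id) in prom:
            return True
        return family_of[reaction_id] == cluster_of[protein_id] % F

    return {
        "reactions": reactions,
        "families": families,
        "proteins": proteins,
        "clusters": clusters,
        "positives": positives,
        "promiscuous": promiscuous,
        "true_positive": true_positive,
    }
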
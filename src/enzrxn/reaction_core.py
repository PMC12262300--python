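"""Parsing, standardization and reaction-center annotation of enzymatic reactions.

A reaction is held as lists of RDKit molecules for the reactant and product
sides together with an atom map (the partial bijection between the two sides
encoded by atom-map numbers in the reaction SMILES) and, once derived, the
reaction center (RC): the set of atoms whose bonding environment — incident
bond orders or hydrogen count — changes between the two sides.

Atom indices used throughout are *global per side*: molecule fragments on one
side are concatenated in order, and an atom is addressed by its 0-based offset
in that concatenation.  Atom-map numbers follow the reaction SMILES
convention and are 1-based.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field, replace

from rdkit import Chem
from rdkit.Chem import AllChem, rdmolops
from rdkit.Chem.MolStandardize import rdMolStandardize

logger = logging.getLogger(__name__)

__all__ = [
    "Reaction",
    "OperatorTemplate",
    "CurationRecord",
    "NormalizationConfig",
    "ReactionParseError",
    "ReactionValidationError",
    "parse_reaction",
    "standardize_reaction",
    "filter_curation",
    "derive_rc_from_map",
    "assign_rc_via_operator",
    "rc_as_reaction",
    "side_atoms",
    "reaction_smiles",
]


class ReactionParseError(ValueError):
    """Raised when a reaction SMILES cannot be parsed."""


class ReactionValidationError(ValueError):
    """Raised when a parsed reaction violates a structural invariant."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class Reaction:
    """A chemical reaction: reactant and product molecule lists plus annotations.

    Attributes
    ----------
    id:
        Free-form identifier.
    reactants, products:
        Lists of RDKit molecules.
    atom_map:
        ``{map_number: (reactant_global_index, product_global_index)}`` for
        every map number present on both sides.
    rc_reactant_atoms, rc_product_atoms:
        Global atom index sets of the reaction center on each side (empty
        until derived or supplied).
    empty_rc:
        Set by :func:`derive_rc_from_map` when the mapped reaction has no
        bonding change at all (an identity reaction); such reactions are
        rejected at dataset load.
    """

    id: str
    reactants: list[Chem.Mol]
    products: list[Chem.Mol]
    atom_map: dict[int, tuple[int, int]] = field(default_factory=dict)
    rc_reactant_atoms: frozenset[int] = frozenset()
    rc_product_atoms: frozenset[int] = frozenset()
    empty_rc: bool = False

    def n_atoms(self) -> int:
        """Total heavy-atom count over all reactants and products."""
        return sum(m.GetNumAtoms() for m in self.reactants) + sum(
            m.GetNumAtoms() for m in self.products
        )

    def map_is_total(self) -> bool:
        n_react = sum(m.GetNumAtoms() for m in self.reactants)
        n_prod = sum(m.GetNumAtoms() for m in self.products)
        return len(self.atom_map) == n_react == n_prod

    def canonical_smiles(self, keep_maps: bool = True) -> str:
        return reaction_smiles(self, keep_maps=keep_maps, canonical=True)


@dataclass(frozen=True)
class OperatorTemplate:
    """A minimal reaction operator: paired reactant/product RC substructure patterns.

    Encoded as reaction SMARTS ``reactant_pattern>>product_pattern``; the
    pattern atom correspondence is carried by the atom-map numbers of the
    SMARTS, and the bond changes are implied by the bond differences between
    the two patterns (RDKit's reaction machinery applies them).
    """

    name: str
    smarts: str

    def to_rdkit(self) -> AllChem.ChemicalReaction:
        rxn = AllChem.ReactionFromSmarts(self.smarts)
        if rxn is None:
            raise ReactionParseError(f"invalid operator SMARTS: {self.smarts!r}")
        rxn.Initialize()
        return rxn


EVIDENCE_LEVELS = ("experimental", "inferred-from-homology", "predicted", "uncertain")


@dataclass(frozen=True)
class CurationRecord:
    """One enzyme-reaction association row with curation metadata."""

    protein_id: str
    reaction_id: str
    evidence: str
    is_subunit: bool = False
    is_transport: bool = False

    def __post_init__(self):
        if self.evidence not in EVIDENCE_LEVELS:
            raise ReactionValidationError(
                f"evidence level {self.evidence!r} not one of {EVIDENCE_LEVELS}"
            )


@dataclass(frozen=True)
class NormalizationConfig:
    """Explicit charge-neutralization rule table.

    Only condition-dependent charges are touched: anionic O/S acid sites are
    protonated and protonated amines deprotonated.  Permanently charged
    centers (e.g. quaternary nitrogen) are never altered.
    """

    protonate_oxyanions: bool = True  # carboxylate / phosphate / alkoxide O-
    protonate_thiolates: bool = True
    deprotonate_ammonium: bool = True  # N+ with >=1 H, incl. [NH4+]
    drop_stereo: bool = True
    apply_normalizer: bool = True  # rdkit standard normalization transforms


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------


def side_atoms(mols: list[Chem.Mol]):
    """Yield ``(global_index, mol_index, atom)`` over a side's concatenated atoms."""
    g = 0
    for mi, m in enumerate(mols):
        for atom in m.GetAtoms():
            yield g, mi, atom
            g += 1


def _global_offsets(mols: list[Chem.Mol]) -> list[int]:
    offs, g = [], 0
    for m in mols:
        offs.append(g)
        g += m.GetNumAtoms()
    return offs


def _locate(mols: list[Chem.Mol], gidx: int) -> tuple[int, int]:
    """Map a global side index to (molecule index, local atom index)."""
    offs = _global_offsets(mols)
    for mi in reversed(range(len(mols))):
        if gidx >= offs[mi]:
            return mi, gidx - offs[mi]
    raise IndexError(gidx)


def _side_map_index(mols: list[Chem.Mol]) -> dict[int, int]:
    """map number -> global atom index for one side; checks uniqueness."""
    out: dict[int, int] = {}
    for g, _mi, atom in side_atoms(mols):
        num = atom.GetAtomMapNum()
        if num:
            if num in out:
                raise ReactionValidationError(
                    f"duplicate atom-map number {num} on one side"
                )
            out[num] = g
    return out


def _atom_by_global(mols: list[Chem.Mol], gidx: int) -> Chem.Atom:
    mi, ai = _locate(mols, gidx)
    return mols[mi].GetAtomWithIdx(ai)


def reaction_smiles(r: Reaction, keep_maps: bool = True, canonical: bool = True) -> str:
    """Serialize a Reaction back to ``reactants>>products`` SMILES."""

    def render(mols):
        parts = []
        for m in mols:
            m2 = Chem.Mol(m)
            if not keep_maps:
                for a in m2.GetAtoms():
                    a.SetAtomMapNum(0)
            parts.append(Chem.MolToSmiles(m2, canonical=canonical))
        return ".".join(sorted(parts) if canonical else parts)

    return f"{render(r.reactants)}>>{render(r.products)}"


# ---------------------------------------------------------------------------
# parsing
# ---------------------------------------------------------------------------


def parse_reaction(text: str, rid: str = "") -> Reaction:
    """Parse ``reactants>agents>products`` SMILES into a :class:`Reaction`.

    Agents (the middle field) are parsed and discarded with a warning.  The
    atom map is extracted from atom-map numbers appearing on both sides; the
    RC sets are left empty.  ``reactants>>products`` (empty agents) is the
    common case.
    """
    fields = text.strip().split(">")
    if len(fields) != 3:
        raise ReactionParseError(
            f"expected 'reactants>agents>products' with two '>' separators: {text!r}"
        )
    rtxt, atxt, ptxt = fields
    if atxt:
        warnings.warn(f"discarding agents field {atxt!r} of reaction {rid or text!r}")

    def parse_side(smi: str, which: str) -> list[Chem.Mol]:
        if not smi:
            raise ReactionParseError(f"empty {which} side in {text!r}")
        combined = Chem.MolFromSmiles(smi)
        if combined is None:
            raise ReactionParseError(f"unparseable {which} fragment: {smi!r}")
        frags = rdmolops.GetMolFrags(combined, asMols=True, sanitizeFrags=True)
        return list(frags)

    reactants = parse_side(rtxt, "reactant")
    products = parse_side(ptxt, "product")

    rmap = _side_map_index(reactants)
    pmap = _side_map_index(products)
    atom_map: dict[int, tuple[int, int]] = {}
    for num, rg in rmap.items():
        if num in pmap:
            ra = _atom_by_global(reactants, rg)
            pa = _atom_by_global(products, pmap[num])
            if ra.GetSymbol() != pa.GetSymbol():
                raise ReactionValidationError(
                    f"map number {num} pairs {ra.GetSymbol()} with {pa.GetSymbol()}"
                )
            atom_map[num] = (rg, pmap[num])
    return Reaction(id=rid, reactants=reactants, products=products, atom_map=atom_map)


# ---------------------------------------------------------------------------
# standardization
# ---------------------------------------------------------------------------

_NORMALIZER = None


def _normalizer():
    global _NORMALIZER
    if _NORMALIZER is None:
        _NORMALIZER = rdMolStandardize.Normalizer()
    return _NORMALIZER


def _neutralize_atom(atom: Chem.Atom, cfg: NormalizationConfig) -> str | None:
    """Apply the explicit neutralization rule table to one atom; returns rule name."""
    sym, chg = atom.GetSymbol(), atom.GetFormalCharge()
    if chg == -1 and sym == "O" and cfg.protonate_oxyanions:
        atom.SetFormalCharge(0)
        atom.SetNumExplicitHs(atom.GetTotalNumHs() + 1)
        return "protonate_oxyanion"
    if chg == -1 and sym == "S" and cfg.protonate_thiolates:
        atom.SetFormalCharge(0)
        atom.SetNumExplicitHs(atom.GetTotalNumHs() + 1)
        return "protonate_thiolate"
    if chg == 1 and sym == "N" and atom.GetTotalNumHs() > 0 and cfg.deprotonate_ammonium:
        atom.SetFormalCharge(0)
        atom.SetNumExplicitHs(max(atom.GetTotalNumHs() - 1, 0))
        return "deprotonate_ammonium"
    return None


def standardize_reaction(
    r: Reaction, rules: NormalizationConfig | None = None
) -> tuple[Reaction, list[str]]:
    """Remove stereochemistry, neutralize condition-dependent charges, normalize.

    Returns the standardized reaction and a report listing every transform
    that fired, as ``"<side>[<mol>]: <rule>"`` strings.  Permanently charged
    centers (quaternary N, no H to remove) are left untouched.  The atom map
    is preserved.  Idempotent.
    """
    cfg = rules or NormalizationConfig()
    report: list[str] = []

    def do_side(mols: list[Chem.Mol], tag: str) -> list[Chem.Mol]:
        out = []
        for mi, m in enumerate(mols):
            m2 = Chem.Mol(m)
            before = Chem.MolToSmiles(m2)
            if cfg.drop_stereo:
                had = any(
                    b.GetStereo() != Chem.BondStereo.STEREONONE for b in m2.GetBonds()
                ) or any(
                    a.GetChiralTag() != Chem.ChiralType.CHI_UNSPECIFIED
                    for a in m2.GetAtoms()
                )
                Chem.RemoveStereochemistry(m2)
                if had:
                    report.append(f"{tag}[{mi}]: remove_stereo")
            if cfg.apply_normalizer:
                m3 = _normalizer().normalize(m2)
                if m3 is not None and Chem.MolToSmiles(m3) != Chem.MolToSmiles(m2):
                    report.append(f"{tag}[{mi}]: normalizer")
                    m2 = m3
            rw = Chem.RWMol(m2)
            for atom in rw.GetAtoms():
                rule = _neutralize_atom(atom, cfg)
                if rule:
                    report.append(f"{tag}[{mi}]: {rule}")
            m2 = rw.GetMol()
            try:
                Chem.SanitizeMol(m2)
            except Exception as exc:  # valence violation introduced by a rule
                raise ReactionValidationError(
                    f"neutralization produced invalid molecule from {before!r}: {exc}"
                ) from exc
            out.append(m2)
        return out

    reactants = do_side(r.reactants, "reactant")
    products = do_side(r.products, "product")
    # re-derive atom map indices (atom order is preserved by the edits above)
    out = replace(r, reactants=reactants, products=products)
    rmap = _side_map_index(reactants)
    pmap = _side_map_index(products)
    out.atom_map = {n: (rmap[n], pmap[n]) for n in rmap if n in pmap}
    return out, report


# ---------------------------------------------------------------------------
# curation filter
# ---------------------------------------------------------------------------


def filter_curation(
    records: list[CurationRecord],
) -> tuple[list[CurationRecord], dict[str, int]]:
    """Retain experimentally evidenced, non-subunit, non-transport records.

    Each rejected record is tallied under the *first* matching rule in the
    fixed order transport -> subunit -> evidence.
    """
    kept: list[CurationRecord] = []
    tally = {"transport": 0, "subunit": 0, "evidence": 0}
    for rec in records:
        if rec.is_transport:
            tally["transport"] += 1
        elif rec.is_subunit:
            tally["subunit"] += 1
        elif rec.evidence != "experimental":
            tally["evidence"] += 1
        else:
            kept.append(rec)
    return kept, tally


# ---------------------------------------------------------------------------
# reaction-center derivation
# ---------------------------------------------------------------------------


def _bond_table(mols: list[Chem.Mol]) -> dict[frozenset[int], float]:
    """Map {map_num, map_num} -> bond order, over bonds whose atoms are both mapped."""
    table: dict[frozenset[int], float] = {}
    for m in mols:
        for b in m.GetBonds():
            n1 = b.GetBeginAtom().GetAtomMapNum()
            n2 = b.GetEndAtom().GetAtomMapNum()
            if n1 and n2:
                table[frozenset((n1, n2))] = b.GetBondTypeAsDouble()
    return table


def derive_rc_from_map(r: Reaction) -> Reaction:
    """Fill the RC sets of a fully atom-mapped reaction.

    RC membership: an atom incident to a bond that is formed, broken or
    changes order between the two sides, or whose total hydrogen count
    changes.  Hydrogens are implicit and never RC atoms themselves.  The two
    sides' RC sets correspond under the atom map by construction.

    Identity reactions (no change anywhere) get empty RC sets and
    ``empty_rc=True`` rather than passing silently.
    """
    if not r.map_is_total():
        raise ReactionValidationError(
            f"reaction {r.id!r}: RC derivation requires a total atom map "
            f"({len(r.atom_map)} mapped of {r.n_atoms() // 2 if r.n_atoms() % 2 == 0 else r.n_atoms()} atoms per side)"
        )
    rt = _bond_table(r.reactants)
    pt = _bond_table(r.products)
    changed_nums: set[int] = set()
    for key in set(rt) | set(pt):
        if rt.get(key) != pt.get(key):
            changed_nums.update(key)
    for num, (rg, pg) in r.atom_map.items():
        ra = _atom_by_global(r.reactants, rg)
        pa = _atom_by_global(r.products, pg)
        if ra.GetTotalNumHs() != pa.GetTotalNumHs():
            changed_nums.add(num)
    rc_r = frozenset(r.atom_map[n][0] for n in changed_nums)
    rc_p = frozenset(r.atom_map[n][1] for n in changed_nums)
    out = replace(r, rc_reactant_atoms=rc_r, rc_product_atoms=rc_p)
    if not changed_nums:
        out.empty_rc = True
        logger.warning("reaction %r has an empty RC (identity reaction)", r.id)
    return out


# ---------------------------------------------------------------------------
# operator-template RC assignment
# ---------------------------------------------------------------------------


def _canon_multiset(mols) -> tuple[str, ...]:
    out = []
    for m in mols:
        m2 = Chem.Mol(m)
        for a in m2.GetAtoms():
            a.SetAtomMapNum(0)
        try:
            Chem.SanitizeMol(m2)
        except Exception:
            return ("<invalid>",)
        out.append(Chem.MolToSmiles(m2))
    return tuple(sorted(out))


def _operator_changed_template_atoms(rxn: AllChem.ChemicalReaction) -> set[int]:
    """Map numbers of operator-template atoms whose environment the operator changes.

    An operator pattern may carry anchor atoms that constrain matching but are
    untouched by the transformation (e.g. the carbonyl oxygen of an ester
    hydrolysis template); only atoms incident to a formed/broken/order-changed
    template bond, atoms whose formal charge changes, or unmapped atoms
    (created/destroyed by the operator) count toward the reaction center.
    """
    def tables(templates):
        bonds: dict[frozenset[int], float] = {}
        charges: dict[int, int] = {}
        unmapped = False
        for t in templates:
            for a in t.GetAtoms():
                if a.GetAtomMapNum():
                    charges[a.GetAtomMapNum()] = a.GetFormalCharge()
                else:
                    unmapped = True
            for b in t.GetBonds():
                n1, n2 = b.GetBeginAtom().GetAtomMapNum(), b.GetEndAtom().GetAtomMapNum()
                if n1 and n2:
                    bonds[frozenset((n1, n2))] = b.GetBondTypeAsDouble()
        return bonds, charges, unmapped

    rb, rch, _ = tables([rxn.GetReactantTemplate(i) for i in range(rxn.GetNumReactantTemplates())])
    pb, pch, _ = tables([rxn.GetProductTemplate(i) for i in range(rxn.GetNumProductTemplates())])
    changed: set[int] = set()
    for key in set(rb) | set(pb):
        if rb.get(key) != pb.get(key):
            changed.update(key)
    for num in set(rch) | set(pch):
        if rch.get(num) != pch.get(num):
            changed.add(num)
    return changed


def assign_rc_via_operator(
    r: Reaction, op: OperatorTemplate
) -> list[frozenset[int]]:
    """Enumerate RC assignments by applying an operator template to the reactants.

    For each combination of one substructure match of the operator's
    reactant-side RC pattern per template component, all *other* matches are
    protected, the operator's bond changes are applied, and the generated
    products (plus any spectator reactant molecules) are compared to the
    reaction's actual products up to canonical-SMILES equality.  Every match
    combination that reproduces the products yields one candidate RC: the
    matched reactant atoms (global indices) restricted to the template atoms
    the operator actually changes, so the result coincides with
    :func:`derive_rc_from_map` on the same reaction.  Results are sorted by
    their atom indices; an empty list means the operator does not explain the
    reaction.
    """
    rxn = op.to_rdkit()
    changed_nums = _operator_changed_template_atoms(rxn)
    k = rxn.GetNumReactantTemplates()
    targets = _canon_multiset(r.products)
    found: set[frozenset[int]] = set()
    offs = _global_offsets(r.reactants)
    n_mols = len(r.reactants)
    if k > n_mols:
        return []

    templates = [rxn.GetReactantTemplate(i) for i in range(k)]
    # injective assignment of template components to reactant molecules
    for assign in itertools.permutations(range(n_mols), k):
        mols = [Chem.Mol(r.reactants[assign[i]]) for i in range(k)]
        spectators = [r.reactants[j] for j in range(n_mols) if j not in assign]
        per_comp_matches = []
        ok = True
        for i, tmpl in enumerate(templates):
            matches = mols[i].GetSubstructMatches(tmpl, uniquify=True)
            if not matches:
                ok = False
                break
            per_comp_matches.append(matches)
        if not ok:
            continue
        for combo in itertools.product(*per_comp_matches):
            work = [Chem.Mol(m) for m in mols]
            # protect every atom belonging to a non-selected match of the
            # same component so only the selected site reacts
            for i in range(k):
                chosen = set(combo[i])
                for match in per_comp_matches[i]:
                    if set(match) != chosen:
                        for ai in match:
                            work[i].GetAtomWithIdx(ai).SetProp("_protected", "1")
            try:
                product_sets = rxn.RunReactants(tuple(work))
            except Exception:
                continue
            reproduced = False
            for pset in product_sets:
                prods = []
                good = True
                for p in pset:
                    try:
                        Chem.SanitizeMol(p)
                    except Exception:
                        good = False
                        break
                    prods.append(p)
                if not good:
                    continue
                if _canon_multiset(list(prods) + list(spectators)) == targets:
                    reproduced = True
                    break
            if reproduced:
                rc = set()
                for i in range(k):
                    tmpl = templates[i]
                    for pa_idx, mol_ai in enumerate(combo[i]):
                        num = tmpl.GetAtomWithIdx(pa_idx).GetAtomMapNum()
                        if num == 0 or num in changed_nums:
                            rc.add(offs[assign[i]] + mol_ai)
                found.add(frozenset(rc))
    return sorted(found, key=lambda s: tuple(sorted(s)))


# ---------------------------------------------------------------------------
# RC-as-reaction
# ---------------------------------------------------------------------------


def _induced_submols(mols: list[Chem.Mol], keep: frozenset[int]) -> list[Chem.Mol]:
    """Induced subgraph molecules on a set of global atom indices.

    Each kept atom's total hydrogen count is frozen as explicit Hs so the
    fragment remains a well-defined (if hypovalent) structure after bond
    removal; map numbers are preserved.
    """
    out = []
    offs = _global_offsets(mols)
    for mi, m in enumerate(mols):
        local = sorted(
            ai for ai in range(m.GetNumAtoms()) if offs[mi] + ai in keep
        )
        if not local:
            continue
        rw = Chem.RWMol()
        idx_of = {}
        for ai in local:
            src = m.GetAtomWithIdx(ai)
            a = Chem.Atom(src.GetSymbol())
            a.SetFormalCharge(src.GetFormalCharge())
            a.SetNumExplicitHs(src.GetTotalNumHs())
            a.SetNoImplicit(True)
            a.SetAtomMapNum(src.GetAtomMapNum())
            idx_of[ai] = rw.AddAtom(a)
        for b in m.GetBonds():
            i, j = b.GetBeginAtomIdx(), b.GetEndAtomIdx()
            if i in idx_of and j in idx_of:
                rw.AddBond(idx_of[i], idx_of[j], b.GetBondType())
        sub = rw.GetMol()
        Chem.SanitizeMol(sub, Chem.SanitizeFlags.SANITIZE_ALL
                         ^ Chem.SanitizeFlags.SANITIZE_PROPERTIES)
        # a fragment cut out of an aromatic ring may no longer be a valid
        # aromatic system; fall back to kekulized single/double orders
        try:
            Chem.SanitizeMol(sub)
        except Exception:
            for a in sub.GetAtoms():
                a.SetIsAromatic(False)
            for b in sub.GetBonds():
                if b.GetBondType() == Chem.BondType.AROMATIC:
                    b.SetBondType(Chem.BondType.SINGLE)
            Chem.SanitizeMol(sub)
        out.extend(rdmolops.GetMolFrags(sub, asMols=True, sanitizeFrags=False))
    return out


def rc_as_reaction(r: Reaction) -> Reaction:
    """Extract the RC itself as a reaction: induced subgraphs on the RC atoms.

    The RC of a mapped reaction is itself a balanced transformation (its
    atoms correspond under the atom map), so the induced fragments on each
    side form a reaction in their own right; every atom of the result is in
    its RC.
    """
    if not r.rc_reactant_atoms or not r.rc_product_atoms:
        raise ReactionValidationError(f"reaction {r.id!r} has no RC to extract")
    sub_r = _induced_submols(r.reactants, r.rc_reactant_atoms)
    sub_p = _induced_submols(r.products, r.rc_product_atoms)
    rmap = _side_map_index(sub_r)
    pmap = _side_map_index(sub_p)
    atom_map = {n: (rmap[n], pmap[n]) for n in rmap if n in pmap}
    n_r = sum(m.GetNumAtoms() for m in sub_r)
    n_p = sum(m.GetNumAtoms() for m in sub_p)
    return Reaction(
        id=f"{r.id}::rc",
        reactants=sub_r,
        products=sub_p,
        atom_map=atom_map,
        rc_reactant_atoms=frozenset(range(n_r)),
        rc_product_atoms=frozenset(range(n_p)),
    )
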
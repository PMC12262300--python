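"""Parsing, standardization, curation filtering and RC derivation."""

import pytest
from rdkit import Chem

from enzrxn.reaction_core import (
    CurationRecord,
    NormalizationConfig,
    OperatorTemplate,
    Reaction,
    ReactionParseError,
    ReactionValidationError,
    assign_rc_via_operator,
    derive_rc_from_map,
    filter_curation,
    parse_reaction,
    rc_as_reaction,
    reaction_smiles,
    standardize_reaction,
)

from conftest import METHYL_ACETATE_HYDROLYSIS, PYRUVATE_TO_LACTATE, mapped

ESTER_HYDROLYSIS_OP = OperatorTemplate(
    "ester_hydrolysis",
    "[C:1](=[O:2])[O:3][C:4].[O:5]>>[C:1](=[O:2])[O:5].[C:4][O:3]",
)
KETONE_REDUCTION_OP = OperatorTemplate(
    "ketone_reduction", "[C:1][C:2](=[O:3])[C:4]>>[C:1][CH:2]([OH:3])[C:4]"
)


class TestParse:
    def test_pyruvate_reduction_fully_mapped(self):
        r = parse_reaction(PYRUVATE_TO_LACTATE, "pyr")
        assert len(r.atom_map) == 6
        assert sum(m.GetNumAtoms() for m in r.reactants) == 6
        assert sum(m.GetNumAtoms() for m in r.products) == 6

    def test_minimal_single_atom_reaction(self):
        r = parse_reaction("C>>C")
        assert len(r.reactants) == len(r.products) == 1
        assert r.atom_map == {}

    def test_two_component_hydrolysis_atom_counts(self):
        r = parse_reaction("CC(=O)OC.O>>CC(=O)O.CO")
        assert [m.GetNumAtoms() for m in r.reactants] == [5, 1]
        assert [m.GetNumAtoms() for m in r.products] == [4, 2]

    def test_agents_discarded_with_warning(self):
        with pytest.warns(UserWarning, match="agents"):
            r = parse_reaction("CC>O>CC")
        assert len(r.reactants) == 1

    def test_unparseable_fragment_raises(self):
        with pytest.raises(ReactionParseError, match="unparseable"):
            parse_reaction("C(C>>C")

    def test_duplicate_map_number_on_one_side_rejected(self):
        with pytest.raises(ReactionValidationError, match="duplicate"):
            parse_reaction("[CH3:1][CH3:1]>>[CH3:1][CH3:2]")

    def test_roundtrip_preserves_graph(self, small_reactions):
        reactions, _ = small_reactions
        for r in reactions[:60]:
            r2 = parse_reaction(reaction_smiles(r, keep_maps=True), r.id)
            assert r2.canonical_smiles() == r.canonical_smiles()


class TestStandardize:
    def test_stereo_dropped_and_carboxylate_protonated(self):
        r = parse_reaction("C[C@H](O)C(=O)[O-]>>C[C@H](O)C(=O)[O-]")
        s, report = standardize_reaction(r)
        smi = Chem.MolToSmiles(s.reactants[0])
        assert smi == "CC(O)C(=O)O"
        assert any("remove_stereo" in t for t in report)
        assert any("protonate_oxyanion" in t for t in report)

    def test_fixpoint_on_already_standard_input(self):
        r = parse_reaction("CC(=O)O>>CC(=O)O")
        s, report = standardize_reaction(r)
        assert report == []
        assert s.canonical_smiles() == r.canonical_smiles()

    def test_ammonium_behavior_follows_config_flag(self):
        r = parse_reaction("[NH4+]>>[NH4+]")
        keep, rep_keep = standardize_reaction(
            r, NormalizationConfig(deprotonate_ammonium=False)
        )
        assert Chem.MolToSmiles(keep.reactants[0]) == "[NH4+]"
        assert rep_keep == []
        neut, rep_neut = standardize_reaction(r)
        assert Chem.MolToSmiles(neut.reactants[0]) == "N"
        assert any("deprotonate_ammonium" in t for t in rep_neut)

    def test_quaternary_nitrogen_left_charged(self):
        r = parse_reaction("C[N+](C)(C)C>>C[N+](C)(C)C")
        s, report = standardize_reaction(r)
        assert Chem.MolToSmiles(s.reactants[0]) == "C[N+](C)(C)C"
        assert report == []

    def test_idempotent_on_generated_corpus(self, small_reactions):
        reactions, _ = small_reactions
        for r in reactions[:30]:
            s1, _ = standardize_reaction(r)
            s2, rep2 = standardize_reaction(s1)
            assert rep2 == []
            assert s1.canonical_smiles() == s2.canonical_smiles()


class TestCurationFilter:
    def test_one_rejection_per_rule_plus_one_clean(self):
        records = [
            CurationRecord("p1", "r1", "experimental", is_transport=True),
            CurationRecord("p2", "r2", "experimental", is_subunit=True),
            CurationRecord("p3", "r3", "inferred-from-homology"),
            CurationRecord("p4", "r4", "experimental"),
        ]
        kept, tally = filter_curation(records)
        assert [k.protein_id for k in kept] == ["p4"]
        assert tally == {"transport": 1, "subunit": 1, "evidence": 1}

    def test_clean_records_all_retained(self):
        records = [CurationRecord(f"p{i}", "r", "experimental") for i in range(5)]
        kept, tally = filter_curation(records)
        assert len(kept) == 5 and sum(tally.values()) == 0

    def test_transport_rule_wins_over_subunit(self):
        rec = CurationRecord("p", "r", "experimental", is_subunit=True, is_transport=True)
        _, tally = filter_curation([rec])
        assert tally == {"transport": 1, "subunit": 0, "evidence": 0}

    def test_empty_input_gives_empty_output(self):
        kept, tally = filter_curation([])
        assert kept == [] and sum(tally.values()) == 0

    def test_invalid_evidence_level_rejected(self):
        with pytest.raises(ReactionValidationError):
            CurationRecord("p", "r", "guessed")


class TestRCFromMap:
    def test_pyruvate_reduction_rc_is_carbonyl(self, pyruvate_reduction):
        # C2=O3 becomes C2-O3 and both gain an H; nothing else changes
        assert pyruvate_reduction.rc_reactant_atoms == frozenset({1, 2})
        assert pyruvate_reduction.rc_product_atoms == frozenset({1, 2})

    def test_identity_reaction_flagged_empty_rc(self):
        r = parse_reaction("[CH3:1][CH3:2]>>[CH3:1][CH3:2]")
        out = derive_rc_from_map(r)
        assert out.empty_rc and not out.rc_reactant_atoms

    def test_hydrolysis_rc_covers_carbonyl_ester_and_water_oxygens(self):
        r = mapped(METHYL_ACETATE_HYDROLYSIS)
        # acyl C, ester O, water O (global reactant indices 1, 3, 5)
        assert r.rc_reactant_atoms == frozenset({1, 3, 5})

    def test_partial_map_rejected(self):
        r = parse_reaction("[CH3:1]C>>[CH3:1]C")
        with pytest.raises(ReactionValidationError, match="total atom map"):
            derive_rc_from_map(r)

    def test_element_conservation_under_total_map(self, small_reactions):
        reactions, _ = small_reactions
        for r in reactions[:40]:
            counts = [{}, {}]
            for side, mols in enumerate((r.reactants, r.products)):
                for m in mols:
                    for a in m.GetAtoms():
                        counts[side][a.GetSymbol()] = (
                            counts[side].get(a.GetSymbol(), 0) + 1
                        )
            assert counts[0] == counts[1]


class TestOperatorAssignment:
    def test_mono_ester_single_assignment_matches_map_route(self):
        r = mapped(METHYL_ACETATE_HYDROLYSIS)
        assignments = assign_rc_via_operator(r, ESTER_HYDROLYSIS_OP)
        assert assignments == [r.rc_reactant_atoms]

    def test_symmetric_diester_yields_two_assignments(self):
        r = parse_reaction("COC(=O)CC(=O)OC.O>>COC(=O)CC(=O)O.CO", "diester")
        assignments = assign_rc_via_operator(r, ESTER_HYDROLYSIS_OP)
        assert len(assignments) == 2
        assert assignments[0] != assignments[1]

    def test_absent_pattern_returns_empty(self, pyruvate_reduction):
        assert assign_rc_via_operator(pyruvate_reduction, ESTER_HYDROLYSIS_OP) == []

    def test_operator_and_map_agree_on_decorated_reactions(self, small_reactions):
        reactions, families = small_reactions
        ops = {0: ESTER_HYDROLYSIS_OP, 1: KETONE_REDUCTION_OP}
        checked = 0
        for r, fam in zip(reactions, families):
            if fam not in ops:
                continue
            assignments = assign_rc_via_operator(r, ops[fam])
            assert r.rc_reactant_atoms in assignments
            checked += 1
        assert checked >= 10


class TestRCAsReaction:
    def test_pyruvate_core_is_two_atom_reduction(self, pyruvate_reduction):
        core = rc_as_reaction(pyruvate_reduction)
        assert core.canonical_smiles(keep_maps=True) == "[C:2]=[O:3]>>[CH:2][OH:3]"
        assert core.rc_reactant_atoms == frozenset(range(2))

    def test_whole_molecule_rc_returns_input_graph(self):
        r = mapped("[CH2:1]=[CH2:2]>>[CH3:1][CH3:2]")
        assert r.rc_reactant_atoms == frozenset({0, 1})
        core = rc_as_reaction(r)
        assert core.n_atoms() == r.n_atoms()

    def test_shared_template_gives_identical_cores(self, small_reactions):
        reactions, families = small_reactions
        fam0 = [r for r, f in zip(reactions, families) if f == 0]
        cores = {rc_as_reaction(r).canonical_smiles(keep_maps=False) for r in fam0}
        assert len(cores) == 1

    def test_empty_rc_is_an_error(self):
        r = parse_reaction("CC>>CC")
        with pytest.raises(ReactionValidationError, match="no RC"):
            rc_as_reaction(r)
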
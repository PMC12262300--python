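"""Parse a reaction, derive its reaction center two ways, and extract the core.

The reaction center (RC) is the set of atoms whose bonding environment —
incident bond orders or hydrogen count — changes between reactants and
products.  It can be derived directly from a full atom map, or assigned by
applying a minimal reaction operator template; on a fully mapped reaction
the two routes agree.
"""

from enzrxn import (
    OperatorTemplate,
    assign_rc_via_operator,
    derive_rc_from_map,
    parse_reaction,
    rc_as_reaction,
)

# methyl acetate + water -> acetic acid + methanol, fully atom-mapped
smiles = (
    "[CH3:1][C:2](=[O:3])[O:4][CH3:5].[OH2:6]"
    ">>[CH3:1][C:2](=[O:3])[OH:6].[CH3:5][OH:4]"
)
rxn = derive_rc_from_map(parse_reaction(smiles, "ester_hydrolysis"))
print("reaction:", smiles)
print("RC atoms (reactant side, 0-based):", sorted(rxn.rc_reactant_atoms))
# -> [1, 3, 5]: the acyl carbon, the ester oxygen, and the water oxygen

operator = OperatorTemplate(
    "ester_hydrolysis",
    "[C:1](=[O:2])[O:3][C:4].[O:5]>>[C:1](=[O:2])[O:5].[C:4][O:3]",
)
assignments = assign_rc_via_operator(rxn, operator)
print("operator-derived RC assignments:", [sorted(a) for a in assignments])
# -> the single assignment equals the map-derived RC

core = rc_as_reaction(rxn)
print("RC as its own balanced reaction:", core.canonical_smiles(keep_maps=True))
# the induced subgraph on the RC atoms: the transformation stripped of all
# substituents, itself encodable by any reaction encoder
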
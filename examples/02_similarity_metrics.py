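"""RCMCS reaction similarity and GSI protein similarity on small inputs.

RCMCS = atoms in the largest common subgraph of two reactions constrained to
contain both reaction centers, over the atom count of the larger reaction.
GSI = identical residues of the best local alignment over the longer
sequence's length.  Both lie in [0, 1] and equal 1 exactly on identical
inputs.
"""

from enzrxn import derive_rc_from_map, parse_reaction
from enzrxn.similarity import gsi, mcs_oracle, rcmcs, rcmcs_numerator

me = derive_rc_from_map(parse_reaction(
    "[CH3:1][C:2](=[O:3])[O:4][CH3:5].[OH2:6]"
    ">>[CH3:1][C:2](=[O:3])[OH:6].[CH3:5][OH:4]", "methyl_acetate"))
et = derive_rc_from_map(parse_reaction(
    "[CH3:1][C:2](=[O:3])[O:4][CH2:5][CH3:7].[OH2:6]"
    ">>[CH3:1][C:2](=[O:3])[OH:6].[CH3:7][CH2:5][OH:4]", "ethyl_acetate"))
red = derive_rc_from_map(parse_reaction(
    "[CH3:1][C:2](=[O:3])[C:4](=[O:5])[OH:6]"
    ">>[CH3:1][CH:2]([OH:3])[C:4](=[O:5])[OH:6]", "pyruvate_reduction"))

print("methyl vs ethyl acetate hydrolysis")
print("  common atoms (production):", rcmcs_numerator(me, et))
print("  common atoms (exhaustive oracle):", mcs_oracle(me, et))
print("  RCMCS score:", round(rcmcs(me, et), 4))
# 12 of max(12, 14) atoms match: the entire methyl system embeds in the
# ethyl one; score 12/14 ~ 0.857

print("hydrolysis vs ketone reduction RCMCS:", rcmcs(me, red))
# 0.0: the two RCs are not isomorphic, so no RC-containing common subgraph

print("GSI, one substitution in ten residues:",
      gsi("ACDEFGHIKL", "ACDEFGWIKL"))
# 0.9: the local alignment spans all ten positions with nine identities
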
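"""Does an encoder map reactions sharing a reaction center near the RC itself?

The RC of a mapped reaction is itself a valid, balanced reaction, so it can
be embedded like any other.  For each group of reactions sharing an RC, we
compare the mean of the members' embeddings with the embedding of the bare
RC, scored exactly like an enzyme-reaction pair (sigmoid of the dot
product).  An encoder that has learned mechanism-local patterns keeps each
family tight around its core; comparing encoders RC by RC shows which one
is more mechanism-aware.
"""

from enzrxn.encoders import EncoderConfig, init_encoder_weights
from enzrxn.evaluation import compare_encoder_proximity, rc_proximity_analysis
from enzrxn.synthetic_data import SynthConfig, generate_reactions

reactions, families = generate_reactions(
    SynthConfig(n_templates=5, reactions_per_template=10, seed=3)
)

cfg_rc = EncoderConfig(variant="rc_aggregated", embedding_dim=32,
                       hidden_dim=32, message_passings=4, seed=0)
cfg_bag = EncoderConfig(variant="bag_of_molecules", embedding_dim=32,
                        hidden_dim=32, message_passings=6, seed=0)
w_rc = init_encoder_weights(cfg_rc)
w_bag = init_encoder_weights(cfg_bag)

records, frac = rc_proximity_analysis(reactions, cfg_rc, w_rc)
print("untrained rc_aggregated encoder (baseline):")
for rec in records:
    print(f"  RC {rec.rc_key!r}: {rec.n_members} members, "
          f"similarity {rec.similarity:.3f}")
print(f"fraction of RC groups with similarity >= 0.8: {frac:.2f}")

out = compare_encoder_proximity(reactions, cfg_rc, w_rc, cfg_bag, w_bag)
print(f"\nrc_aggregated closer than bag_of_molecules in "
      f"{out['fraction_a_wins']:.0%} of RC groups (untrained weights)")
# with trained weights on planted data this comparison favors the
# RC-aggregated encoder in the majority of groups — see the test suite
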
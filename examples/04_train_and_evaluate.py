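"""Train the two-tower scorer on a planted synthetic corpus and evaluate recovery.

The synthetic world plants a sparse catalysis relation: protein cluster c
catalyzes reaction family c, with a few promiscuous cross-family positives.
A reaction-center-aggregated encoder and a linear protein projection are
trained jointly with the weighted binary cross entropy; held-out ranking
quality against the planted ground truth measures how well the relation is
recovered.  Runs in about half a minute on one CPU.
"""

import numpy as np

from enzrxn.encoders import EncoderConfig
from enzrxn.scoring_model import TrainConfig, train
from enzrxn.synthetic_data import SynthConfig, generate_dataset

data = generate_dataset(SynthConfig(
    n_templates=5, reactions_per_template=20, n_protein_clusters=5,
    proteins_per_cluster=20, positive_density=0.01, seed=0,
))
reactions = {r.id: r for r in data["reactions"]}
proteins = {p.id: p for p in data["proteins"]}
positives = data["positives"]
truth = data["true_positive"]
print(f"{len(reactions)} reactions, {len(proteins)} proteins, "
      f"{len(positives)} planted positives")

rng = np.random.default_rng(0)
perm = rng.permutation(len(positives))
cut = int(0.7 * len(positives))
pos_set = set(positives)
pids, rids = sorted(proteins), sorted(reactions)


def draw(n, seed, keep):
    r2, out = np.random.default_rng(seed), set()
    while len(out) < n:
        p, r = pids[r2.integers(len(pids))], rids[r2.integers(len(rids))]
        if keep(p, r):
            out.add((p, r))
    return sorted(out)


train_pairs = [(p, r, 1) for p, r in (positives[i] for i in perm[:cut])] + [
    (p, r, 0) for p, r in draw(3 * cut, 1, lambda p, r: (p, r) not in pos_set)
]
test_pos = [positives[i] for i in perm[cut:]]
test_pairs = [(p, r, 1) for p, r in test_pos] + [
    (p, r, 0) for p, r in draw(len(test_pos), 2, lambda p, r: not truth(p, r))
]

cfg = EncoderConfig(variant="rc_aggregated", embedding_dim=64, hidden_dim=64,
                    message_passings=4, seed=0)
params, logs = train(train_pairs, reactions, proteins, cfg,
                     TrainConfig(epochs=25, seed=0), val_pairs=test_pairs)
for log in logs[::8] + [logs[-1]]:
    print(f"epoch {log.epoch:2d}  train loss {log.train_loss:.4f}  "
          f"held-out AUC {log.val_auc:.4f}")
print("decision threshold selected on held-out F1:", round(params.threshold, 4))
# AUC near 1 means the planted cluster-family relation was recovered from
# the reaction graphs and protein embeddings alone
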
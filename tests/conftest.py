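import numpy as np
import pytest

from enzrxn.reaction_core import derive_rc_from_map, parse_reaction
from enzrxn.synthetic_data import SynthConfig, generate_dataset, generate_reactions

PYRUVATE_TO_LACTATE = (
    "[CH3:1][C:2](=[O:3])[C:4](=[O:5])[OH:6]"
    ">>[CH3:1][CH:2]([OH:3])[C:4](=[O:5])[OH:6]"
)
METHYL_ACETATE_HYDROLYSIS = (
    "[CH3:1][C:2](=[O:3])[O:4][CH3:5].[OH2:6]"
    ">>[CH3:1][C:2](=[O:3])[OH:6].[CH3:5][OH:4]"
)
ETHYL_ACETATE_HYDROLYSIS = (
    "[CH3:1][C:2](=[O:3])[O:4][CH2:5][CH3:7].[OH2:6]"
    ">>[CH3:1][C:2](=[O:3])[OH:6].[CH3:7][CH2:5][OH:4]"
)


def mapped(smi: str, rid: str = "r"):
    return derive_rc_from_map(parse_reaction(smi, rid))


@pytest.fixture(scope="session")
def pyruvate_reduction():
    return mapped(PYRUVATE_TO_LACTATE, "pyr2lac")


@pytest.fixture(scope="session")
def ester_hydrolyses():
    return (
        mapped(METHYL_ACETATE_HYDROLYSIS, "me"),
        mapped(ETHYL_ACETATE_HYDROLYSIS, "et"),
    )


@pytest.fixture(scope="session")
def small_reactions():
    """30 template-decorated reactions small enough for the exhaustive MCS oracle."""
    cfg = SynthConfig(
        n_templates=5,
        reactions_per_template=6,
        max_substituent_atoms=2,
        seed=101,
    )
    reactions, families = generate_reactions(cfg)
    return reactions, families


@pytest.fixture(scope="session")
def planted_dataset():
    """The default-scale planted corpus shared by the slower model tests."""
    return generate_dataset(SynthConfig(seed=11))


def split_planted(data, seed=0, train_frac=0.7):
    """Pipeline-style train pairs and planted-truth test pairs."""
    pos = data["positives"]
    truth = data["true_positive"]
    pos_set = set(pos)
    pids = sorted(p.id for p in data["proteins"])
    rids = sorted(r.id for r in data["reactions"])
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(pos))
    n_tr = int(train_frac * len(pos))
    tr_pos = [pos[i] for i in perm[:n_tr]]
    te_pos = [pos[i] for i in perm[n_tr:]]

    def draw(n, subseed, keep):
        r2 = np.random.default_rng((seed + 1) * 1000 + subseed)
        out = set()
        while len(out) < n:
            p = pids[r2.integers(len(pids))]
            r = rids[r2.integers(len(rids))]
            if keep(p, r):
                out.add((p, r))
        return sorted(out)

    train_pairs = [(p, r, 1) for p, r in tr_pos] + [
        (p, r, 0)
        for p, r in draw(3 * len(tr_pos), 1, lambda p, r: (p, r) not in pos_set)
    ]
    test_pairs = [(p, r, 1) for p, r in te_pos] + [
        (p, r, 0) for p, r in draw(len(te_pos), 2, lambda p, r: not truth(p, r))
    ]
    return train_pairs, test_pairs
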
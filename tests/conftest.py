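import numpy as np
import pandas as pd
import pytest

from metabofe import SimulationConfig, simulate_cohort
from metabofe.pedigree import Pedigree


@pytest.fixture(scope="session")
def small_cohort():
    """A fast 180-bird two-line cohort with two planted differential features."""
    cfg = SimulationConfig(
        n_founders_per_line=12,
        n_generations=1,
        dams_per_sire=3,
        offspring_per_dam=10,
        n_phenotyped=None,
        n_metabolites_pos=20,
        n_metabolites_neg=15,
        true_h2={"P0001": 0.5, "N0001": 0.4},
        true_rg={("P0001", "rfi"): 0.6, ("N0001", "rfi"): -0.5},
        line_effect={"P0001": 500.0, "N0001": -500.0},
        sex_effect={"P0002": 120.0},
        seed=11,
    )
    ped, phenotypes, pos, neg = simulate_cohort(cfg)
    return cfg, ped, phenotypes, pos, neg


@pytest.fixture()
def toy_pedigree():
    """Founders S, D; full sibs O1, O2; inbred P from a parent-offspring mating."""
    df = pd.DataFrame(
        {
            "animal": ["S", "D", "O1", "O2", "P"],
            "sire": ["0", "0", "S", "S", "S"],
            "dam": ["0", "0", "D", "D", "O1"],
            "generation": [0, 0, 1, 1, 2],
        }
    )
    return Pedigree(df)


def random_pedigree(rng, n_animals):
    """Random valid pedigree: each animal's parents drawn from earlier animals."""
    animals, sires, dams, gens = [], [], [], []
    for i in range(n_animals):
        animals.append(f"a{i}")
        if i < 2 or rng.random() < 0.3:
            sires.append("0")
            dams.append("0")
            gens.append(0)
        else:
            s, d = rng.choice(i, size=2, replace=True)
            sires.append(f"a{s}")
            dams.append(f"a{d}")
            gens.append(1)
    return Pedigree(
        pd.DataFrame({"animal": animals, "sire": sires, "dam": dams, "generation": gens})
    )


def kinship_oracle(pedigree):
    """Independent recursive coancestry; A = 2 * kinship.

    f(i, i) = 0.5 * (1 + f(s_i, d_i)); for i later than j,
    f(i, j) = 0.5 * (f(s_i, j) + f(d_i, j)); unknown parents contribute 0.
    """
    parents = pedigree.parent_indices()
    n = len(pedigree)
    cache = {}

    def f(i, j):
        if i < 0 or j < 0:
            return 0.0
        if i < j:
            i, j = j, i
        key = (i, j)
        if key in cache:
            return cache[key]
        s, d = parents[i]
        if i == j:
            val = 0.5 * (1.0 + f(s, d))
        else:
            val = 0.5 * (f(s, j) + f(d, j))
        cache[key] = val
        return val

    return np.array([[2.0 * f(i, j) for j in range(n)] for i in range(n)])
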
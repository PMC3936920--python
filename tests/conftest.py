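import numpy as np
import pandas as pd
import pytest

from matrisig import SimConfig, simulate_calls, simulate_population
from matrisig.simulate import Pedigree


@pytest.fixture(scope="session")
def default_population():
    """One default synthetic population (six matrilines, study-like)."""
    return simulate_population(SimConfig(seed=42))


@pytest.fixture(scope="session")
def default_calls(default_population):
    pop = default_population
    return simulate_calls(pop.pedigree, pop.config)


@pytest.fixture()
def study_pedigree():
    """A fixed pedigree with the study's kin-group sizes in individuals
    (one 4, two 3s, three 2s = 16 females), mothers omitted."""
    individuals, matriline_of = [], {}
    for m, size in enumerate([4, 3, 3, 2, 2, 2], start=1):
        for k in range(size):
            ind = f"m{m}f{k + 1}"
            individuals.append(ind)
            matriline_of[ind] = f"mat{m}"
    sex = {i: "F" for i in individuals}
    return Pedigree(individuals, {}, matriline_of, sex)


def make_call_table(rng, group_means, calls_per_ind=10, ind_sd=0.0, resid_sd=1.0):
    """Small helper: calls with one predictor per group/individual layout.

    ``group_means`` maps group label -> list of (individual id, mean).
    """
    rows = []
    for group, inds in group_means.items():
        for ind, mu in inds:
            ind_eff = rng.normal(0, ind_sd)
            for _ in range(calls_per_ind):
                rows.append(
                    {"id": ind, "group": group, "PC1": mu + ind_eff + rng.normal(0, resid_sd)}
                )
    return pd.DataFrame(rows)
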
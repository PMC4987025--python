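"""Shared fixtures: small pedigrees, a random-pedigree factory, and an
independent recursive-coancestry oracle for relationship matrices."""

from __future__ import annotations

import functools

import numpy as np
import pytest

from pedmix import (
    CohortDesign,
    Pedigree,
    SimulationTruth,
    additive_relationship_matrix,
    group_covariance_matrix,
    simulate_pedigree,
    simulate_phenotypes,
)
from pedmix.pedigree import Individual


def kinship_oracle(ped: Pedigree):
    """Naive recursive coancestry: f(i, i) = 0.5 * (1 + f(fa_i, mo_i)),
    f(i, j) = 0.5 * (f(i, fa_j) + f(i, mo_j)) recursing on the individual
    later in pedigree depth; missing parents contribute 0.  The additive
    relationship is A = 2 * kinship.  Independent of the tabular method."""
    depth: dict[str, int] = {}

    def _depth(i):
        if i in depth:
            return depth[i]
        ind = ped[i]
        d = 0
        for par in (ind.father, ind.mother):
            if par is not None:
                d = max(d, _depth(par) + 1)
        depth[i] = d
        return d

    @functools.lru_cache(maxsize=None)
    def f(i, j):
        if i is None or j is None:
            return 0.0
        if i == j:
            ind = ped[i]
            return 0.5 * (1.0 + f2(ind.father, ind.mother))
        # recurse on the individual deeper in the pedigree
        if _depth(j) < _depth(i):
            i, j = j, i
        ind = ped[j]
        if ind.father is None and ind.mother is None:
            return 0.0
        return 0.5 * (f2(i, ind.father) + f2(i, ind.mother))

    def f2(i, j):
        if i is None or j is None:
            return 0.0
        a, b = sorted((i, j))
        return f(a, b)

    n = len(ped)
    A = np.zeros((n, n))
    ids = ped.ids
    for a in range(n):
        for b in range(a, n):
            A[a, b] = A[b, a] = 2.0 * f2(ids[a], ids[b])
    return ids, A


def random_pedigree(seed: int, max_size: int = 20) -> Pedigree:
    """Random multigenerational pedigree of at most ``max_size`` members,
    allowing inbreeding (matings between relatives) and single known
    parents."""
    rng = np.random.default_rng(seed)
    n = int(rng.integers(3, max_size + 1))
    inds: list[Individual] = []
    males, females = [], []
    for k in range(n):
        sex = "male" if rng.random() < 0.5 else "female"
        father = mother = None
        if k >= 2 and rng.random() < 0.75:
            if males and rng.random() < 0.9:
                father = males[int(rng.integers(len(males)))]
            if females and rng.random() < 0.9:
                mother = females[int(rng.integers(len(females)))]
        iid = f"I{k:02d}"
        inds.append(Individual(id=iid, father=father, mother=mother, sex=sex))
        (males if sex == "male" else females).append(iid)
    return Pedigree(individuals=inds)


@pytest.fixture(scope="session")
def trio() -> Pedigree:
    return Pedigree(individuals=[
        Individual("F", None, None, "male"),
        Individual("M", None, None, "female"),
        Individual("C", "F", "M", "female"),
    ])


@pytest.fixture(scope="session")
def fullsib_mating() -> Pedigree:
    """Founder couple, two full sibs, and their (inbred) offspring K."""
    return Pedigree(individuals=[
        Individual("F", None, None, "male"),
        Individual("M", None, None, "female"),
        Individual("S1", "F", "M", "male"),
        Individual("S2", "F", "M", "female"),
        Individual("K", "S1", "S2", "male"),
    ])


@pytest.fixture(scope="session")
def small_cohort():
    """A ~350-individual cohort with spouse effects, shared by tests."""
    design = CohortDesign(n_families=40, generations=3)
    ped = simulate_pedigree(design, seed=11)
    truth = SimulationTruth()
    phe = simulate_phenotypes(ped, truth, seed=12)
    structures = {
        "additive": additive_relationship_matrix(ped),
        "spouse": group_covariance_matrix(ped, "spouse_share"),
        "sib": group_covariance_matrix(ped, "sib_share"),
        "household": group_covariance_matrix(ped, "household_share"),
    }
    return {"pedigree": ped, "truth": truth, "phenotypes": phe,
            "structures": structures}
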
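"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from nitroyield.stoich import MetabolicModel, Reaction, Species
from nitroyield.synth import ToySpec, make_loop_fixture, make_toy_autotroph


@pytest.fixture
def chain_toy() -> MetabolicModel:
    """uptake (<=10) -> A -> biomass: a single linear route."""
    return MetabolicModel(
        species=[Species("a_c"), Species("x_e", compartment="boundary")],
        reactions=[
            Reaction("UP", {"a_c": 1}, 0, 10),
            Reaction("GROW", {"a_c": -1, "x_e": 1}, 0, 1000),
        ],
        exchange_ids=["UP"],
    )


@pytest.fixture
def toy_autotroph() -> MetabolicModel:
    return make_toy_autotroph(ToySpec(atp_cost=0.10, nadh_cost=0.05, gam=25.0))


@pytest.fixture
def loop_fixture() -> MetabolicModel:
    return make_loop_fixture()


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def enumerate_vertices_optimum(
    model: MetabolicModel, objective: str, sense: str = "max",
    fixed: dict[str, float] | None = None,
) -> float | None:
    """Brute-force LP optimum by vertex enumeration.

    Projects {S v = 0, lb <= v <= ub} onto the null space of the balance
    matrix and enumerates every basic point from combinations of active
    bound constraints.  Exponential, only for toy polytopes (null-space
    dimension <= ~6).  Returns None if no feasible vertex exists.
    """
    n = len(model.reactions)
    ridx = model.reaction_index
    sidx = model.species_index
    keep = [sidx[s] for s in model.balanced_species_ids()]
    S = model.stoichiometric_matrix()[keep, :] if keep else np.zeros((0, n))
    lb = np.array([r.lower_bound for r in model.reactions], float)
    ub = np.array([r.upper_bound for r in model.reactions], float)
    for rid, val in (fixed or {}).items():
        lb[ridx[rid]] = ub[ridx[rid]] = val

    # equality rows for pinned variables keep the projection simple
    eqs = [S] if S.size else []
    rhs = [np.zeros(S.shape[0])] if S.size else []
    pinned = lb == ub
    for i in np.where(pinned)[0]:
        row = np.zeros(n)
        row[i] = 1.0
        eqs.append(row[None, :])
        rhs.append(np.array([lb[i]]))
    E = np.vstack(eqs) if eqs else np.zeros((0, n))
    b = np.concatenate(rhs) if rhs else np.zeros(0)

    # particular solution + null-space basis
    x0, *_ = np.linalg.lstsq(E, b, rcond=None)
    if E.size and np.max(np.abs(E @ x0 - b)) > 1e-8:
        return None
    from scipy.linalg import null_space

    N = null_space(E) if E.size else np.eye(n)
    d = N.shape[1]
    free = ~pinned
    # inequalities A t <= h in the reduced space (bounds of free variables)
    A = np.vstack([N[free], -N[free]])
    h = np.concatenate([(ub - x0)[free], (x0 - lb)[free]])
    c = np.zeros(n)
    c[ridx[objective]] = 1.0
    cN = c @ N
    c0 = c @ x0

    best = None
    if d == 0:
        if np.all(A @ np.zeros(0) <= h + 1e-9) if A.size else True:
            best = c0
        return best
    for combo in itertools.combinations(range(A.shape[0]), d):
        Asub = A[list(combo)]
        if np.linalg.matrix_rank(Asub) < d:
            continue
        t = np.linalg.lstsq(Asub, h[list(combo)], rcond=None)[0]
        if np.max(np.abs(Asub @ t - h[list(combo)])) > 1e-7:
            continue
        if np.all(A @ t <= h + 1e-7):
            val = c0 + cN @ t
            if best is None:
                best = val
            elif (sense == "max" and val > best) or (sense == "min" and val < best):
                best = val
    return best


def random_bounded_model(rng: np.random.Generator, n_species=4, n_reactions=6):
    """A random small network that is always feasible (0 in the box) and
    bounded (finite bounds)."""
    species = [Species(f"s{i}_c") for i in range(n_species)]
    reactions = []
    for j in range(n_reactions):
        stoich = {}
        for i in rng.choice(n_species, size=rng.integers(1, 3), replace=False):
            stoich[f"s{i}_c"] = float(rng.integers(-2, 3)) or 1.0
        lo = float(rng.choice([-10.0, -5.0, 0.0]))
        hi = float(rng.choice([5.0, 10.0]))
        reactions.append(Reaction(f"r{j}", stoich, lo, hi))
    # one boundary species so something can actually flow
    species.append(Species("out_e", compartment="boundary"))
    reactions.append(Reaction("sink", {"s0_c": -1, "out_e": 1}, 0, 10))
    return MetabolicModel(species=species, reactions=reactions)
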
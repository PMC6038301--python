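"""Flux balance analysis.

A small, deterministic LP/MILP layer over scipy's HiGHS backends:

* :func:`solve_fba` — max/min a reaction flux subject to steady state
  (S·v = 0 over non-boundary species) and bounds, with optional fixed or
  blocked reactions;
* :func:`solve_loopless` — the same optimum restricted to thermodynamically
  feasible flux patterns, using the null-space/energy-potential MILP with
  binary direction indicators for internal reactions (exchanges and the
  biomass reaction exempt);
* :func:`minimize_sources` — lexicographic minimization of an ordered list
  of source fluxes, each fixed at its optimum before the next is minimized;
* :func:`max_circulation` — the LP certificate that a flux vector carries no
  internal cycle (used by tests and by the loopless contract).

Feasibility tolerance 1e-9; reported values are meaningful to ~1e-6.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, sparse

from .errors import UnknownIdentifierError
from .stoich import MetabolicModel

FEAS_TOL = 1e-9
VALUE_TOL = 1e-6
#: big-M for loopless direction indicators; matches the flux bound sentinel
LOOPLESS_M = 1000.0


@dataclass
class FluxSolution:
    """Result of one FBA solve."""

    status: str  # optimal | infeasible | unbounded
    objective_value: float | None = None
    fluxes: dict[str, float] = field(default_factory=dict)
    #: per-source optima recorded by lexicographic minimization
    source_minima: dict[str, float] = field(default_factory=dict)

    @property
    def optimal(self) -> bool:
        return self.status == "optimal"


_LP_STATUS = {0: "optimal", 1: "iteration limit", 2: "infeasible", 3: "unbounded"}


def _effective_bounds(
    model: MetabolicModel,
    fixed: dict[str, float] | None,
    blocked: set[str] | None,
) -> tuple[np.ndarray, np.ndarray]:
    lb = np.array([r.lower_bound for r in model.reactions], dtype=float)
    ub = np.array([r.upper_bound for r in model.reactions], dtype=float)
    ridx = model.reaction_index
    for rid in blocked or ():
        if rid not in ridx:
            raise UnknownIdentifierError(rid)
        lb[ridx[rid]] = ub[ridx[rid]] = 0.0
    for rid, value in (fixed or {}).items():
        if rid not in ridx:
            raise UnknownIdentifierError(rid)
        lb[ridx[rid]] = ub[ridx[rid]] = value
    return lb, ub


def _balance_matrix(model: MetabolicModel) -> sparse.csr_matrix:
    """Rows of S restricted to balanced (non-boundary) species."""
    sidx = model.species_index
    keep = [sidx[s] for s in model.balanced_species_ids()]
    S = sparse.lil_matrix((len(model.species), len(model.reactions)))
    for j, r in enumerate(model.reactions):
        for s, c in r.stoich.items():
            S[sidx[s], j] = c
    return sparse.csr_matrix(S.tocsr()[keep, :])


def solve_fba(
    model: MetabolicModel,
    objective: str,
    sense: str = "max",
    fixed: dict[str, float] | None = None,
    blocked: set[str] | None = None,
) -> FluxSolution:
    """Optimize one reaction's flux at steady state.

    ``fixed`` pins reactions to exact values (both bounds), ``blocked`` zeroes
    them — the mechanism used to shut off an entire pathway.  Infeasible or
    unbounded problems are reported through ``status``, never raised.
    """
    ridx = model.reaction_index
    if objective not in ridx:
        raise UnknownIdentifierError(objective)
    n = len(model.reactions)
    c = np.zeros(n)
    c[ridx[objective]] = -1.0 if sense == "max" else 1.0
    lb, ub = _effective_bounds(model, fixed, blocked)
    A = _balance_matrix(model)
    res = optimize.linprog(
        c,
        A_eq=A,
        b_eq=np.zeros(A.shape[0]),
        bounds=np.column_stack([lb, ub]),
        method="highs",
        options={"presolve": True, "primal_feasibility_tolerance": FEAS_TOL,
                 "dual_feasibility_tolerance": FEAS_TOL},
    )
    status = _LP_STATUS.get(res.status, "infeasible")
    if status != "optimal":
        return FluxSolution(status=status)
    fluxes = {r.id: float(v) for r, v in zip(model.reactions, res.x)}
    return FluxSolution(
        status="optimal",
        objective_value=float(fluxes[objective]),
        fluxes=fluxes,
    )


# ---------------------------------------------------------------------------
# loopless FBA
# ---------------------------------------------------------------------------

def _internal_indices(model: MetabolicModel) -> list[int]:
    """Reactions subject to the loop law.

    Exempt: declared exchanges, the biomass reaction, and any reaction
    touching a boundary (unbalanced) species — those exchange matter with
    the environment and cannot belong to a pure internal cycle.
    """
    exempt = set(model.exchange_ids)
    if model.biomass_id:
        exempt.add(model.biomass_id)
    boundary = {s.id for s in model.species if s.compartment == "boundary"}
    return [
        i
        for i, r in enumerate(model.reactions)
        if r.id not in exempt and not set(r.stoich) & boundary
    ]


def _cycle_basis(model: MetabolicModel, internal: list[int]) -> np.ndarray:
    """Basis (rows) of the null space of S restricted to internal reactions —
    the internal cycles the loop law must exclude."""
    S = _balance_matrix(model).toarray()
    if not internal:
        return np.zeros((0, 0))
    from scipy.linalg import null_space

    N = null_space(S[:, internal])
    return N.T  # each row: one cycle over internal reactions


def solve_loopless(
    model: MetabolicModel,
    objective: str,
    sense: str = "max",
    fixed: dict[str, float] | None = None,
    blocked: set[str] | None = None,
) -> FluxSolution:
    """FBA restricted to loop-free flux patterns (ll-FBA MILP).

    For each internal reaction ``i`` a binary ``a_i`` selects the flux
    direction and an energy-like potential ``G_i`` is forced to the opposite
    sign; requiring ``G`` to be orthogonal to every internal cycle makes any
    nonzero circulation infeasible, while all acyclic patterns (and hence any
    loop-free optimum) remain attainable.
    """
    ridx = model.reaction_index
    if objective not in ridx:
        raise UnknownIdentifierError(objective)
    n = len(model.reactions)
    internal = _internal_indices(model)
    k = len(internal)
    cycles = _cycle_basis(model, internal)
    lb, ub = _effective_bounds(model, fixed, blocked)

    # variables: v (n) | a (k, binary) | G (k)
    nvar = n + 2 * k
    cvec = np.zeros(nvar)
    cvec[ridx[objective]] = -1.0 if sense == "max" else 1.0

    rows: list[sparse.spmatrix] = []
    lo: list[np.ndarray] = []
    hi: list[np.ndarray] = []

    A = _balance_matrix(model)
    rows.append(sparse.hstack([A, sparse.csr_matrix((A.shape[0], 2 * k))]))
    lo.append(np.zeros(A.shape[0]))
    hi.append(np.zeros(A.shape[0]))

    if k:
        M = LOOPLESS_M
        int_lb = np.array([lb[i] for i in internal])
        int_ub = np.array([ub[i] for i in internal])
        sel = sparse.csr_matrix(
            (np.ones(k), (range(k), internal)), shape=(k, n)
        )
        eye = sparse.eye(k, format="csr")
        zero = sparse.csr_matrix((k, k))
        # direction coupling: a=1 -> v_i in [0, ub_i]; a=0 -> v_i in [lb_i, 0]
        rows.append(sparse.hstack([sel, -sparse.diags(int_ub), zero]))
        lo.append(np.full(k, -np.inf))
        hi.append(np.zeros(k))                 # v - ub*a <= 0
        rows.append(sparse.hstack([sel, sparse.diags(int_lb), zero]))
        lo.append(int_lb)
        hi.append(np.full(k, np.inf))          # v + lb*a >= lb
        # potential sign opposite the flux: 1 <= G + (M+1)*a <= M
        rows.append(sparse.hstack([sparse.csr_matrix((k, n)), (M + 1) * eye, eye]))
        lo.append(np.ones(k))
        hi.append(np.full(k, M))
        # loop law: G orthogonal to every internal cycle
        if cycles.size:
            Crows = sparse.csr_matrix(cycles)
            rows.append(
                sparse.hstack(
                    [sparse.csr_matrix((Crows.shape[0], n + k)), Crows]
                )
            )
            lo.append(np.zeros(Crows.shape[0]))
            hi.append(np.zeros(Crows.shape[0]))

    constraints = optimize.LinearConstraint(
        sparse.vstack(rows).tocsc(),
        np.concatenate(lo),
        np.concatenate(hi),
    )
    var_lb = np.concatenate([lb, np.zeros(k), -LOOPLESS_M * np.ones(k)])
    var_ub = np.concatenate([ub, np.ones(k), LOOPLESS_M * np.ones(k)])
    integrality = np.concatenate(
        [np.zeros(n), np.ones(k), np.zeros(k)]
    )
    res = optimize.milp(
        cvec,
        constraints=constraints,
        bounds=optimize.Bounds(var_lb, var_ub),
        integrality=integrality,
    )
    if res.status == 2:
        return FluxSolution(status="infeasible")
    if res.status == 3:
        return FluxSolution(status="unbounded")
    if not res.success:
        return FluxSolution(status="infeasible")
    v = res.x[:n]
    fluxes = {r.id: float(x) for r, x in zip(model.reactions, v)}
    return FluxSolution(
        status="optimal",
        objective_value=float(fluxes[objective]),
        fluxes=fluxes,
    )


def max_circulation(
    model: MetabolicModel, fluxes: dict[str, float], tol: float = VALUE_TOL
) -> float:
    """Largest internal circulation supported by a flux vector.

    Maximizes total |w| over flux vectors w confined to the sign and support
    of the internal part of ``fluxes`` with S·w = 0 and all non-internal
    reactions at zero; 0 (within tolerance) certifies a loop-free solution.
    """
    internal = set(_internal_indices(model))
    n = len(model.reactions)
    lo = np.zeros(n)
    hi = np.zeros(n)
    c = np.zeros(n)
    for i, r in enumerate(model.reactions):
        v = fluxes.get(r.id, 0.0)
        if i in internal and abs(v) > tol:
            if v > 0:
                hi[i] = v
                c[i] = -1.0
            else:
                lo[i] = v
                c[i] = 1.0
    A = _balance_matrix(model)
    res = optimize.linprog(
        c,
        A_eq=A,
        b_eq=np.zeros(A.shape[0]),
        bounds=np.column_stack([lo, hi]),
        method="highs",
    )
    if res.status != 0:
        return 0.0
    return float(-res.fun)


# ---------------------------------------------------------------------------
# lexicographic source minimization
# ---------------------------------------------------------------------------

def minimize_sources(
    model: MetabolicModel,
    sources: list[str],
    fixed: dict[str, float] | None = None,
    blocked: set[str] | None = None,
) -> FluxSolution:
    """Minimize each source flux in order, fixing it at its optimum before
    minimizing the next; returns the final full solution.

    This makes an otherwise degenerate pair of input requirements (e.g. ATP
    then NADH) well defined: the first source's optimum is the contract, the
    later ones are conditional on it.
    """
    fixed = dict(fixed or {})
    minima: dict[str, float] = {}
    sol = FluxSolution(status="infeasible")
    for src in sources:
        sol = solve_fba(model, src, sense="min", fixed=fixed, blocked=blocked)
        if not sol.optimal:
            return FluxSolution(status=sol.status, source_minima=minima)
        minima[src] = sol.objective_value
        fixed[src] = sol.objective_value
    sol.source_minima = minima
    return sol
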
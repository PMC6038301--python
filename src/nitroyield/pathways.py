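"""The three proposed ammonia-oxidation pathways and their theoretical yields.

Each pathway is a small set of irreversible electron-transport reactions
(shipped as TSV fixtures in :mod:`nitroyield.data`).  Lumping them under a
steady-state constraint on the pathway-internal species — with ammonium
uptake fixed at 1 — gives the overall reaction the pathway performs and its
theoretical ATP (or NADH) yield per ammonium oxidized:

* pathway 1: quinol-dependent ammonia monooxygenase + hydroxylamine
  oxidoreductase (4 e- per NH2OH);
* pathway 2: NO-shuttle variant (monooxygenase electrons delivered by NO,
  nitrite reductase regenerates NO);
* pathway 3: CuP460 variant (NH2OH + NO -> 2 HNO2, 5 e-, NO cycled).

The proton bookkeeping is anchored at 4 translocated protons per ATP (F0F1
synthase) and 4 protons per NADH (reverse electron transport through
complex I), which is also why one NADH counts as one ATP-equivalent.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

from .errors import InfeasiblePathwayError, UnknownIdentifierError
from .fba import VALUE_TOL, solve_fba
from .model_io import read_table
from .stoich import MetabolicModel, Reaction, Species, net_reaction

#: species balanced inside a pathway LP (ATP-maximizing mode); NAD/NADH move
#: to the boundary set in NADH-maximizing mode
INTERNAL_SPECIES = frozenset(
    {
        "nh3_c", "nh2oh_c", "no_c",
        "q_c", "qh2_c",
        "pcym_p", "pcyme_p", "pcy_p", "pcye_p",
        "h_p",
        "nad_c", "nadh_c",
    }
)

#: species exchanged freely with the environment / rest of metabolism
BOUNDARY_SPECIES = frozenset(
    {
        "nh4_e", "o2_c", "h2o_c", "hno2_c", "n2o_c",
        "adp_c", "pi_c", "atp_c", "h_c",
    }
)

UPTAKE_REACTION = "Trans_NH4"
ATP_REACTION = "ATP_Synt"
NADH_REACTION = "NADH_Synt"
PROTONS_PER_ATP = 4.0
PROTONS_PER_NADH = 4.0


@dataclass
class PathwayDefinition:
    """One pathway's reaction set plus its internal/boundary species split."""

    id: int
    reactions: list[Reaction]
    internal_species: frozenset[str] = INTERNAL_SPECIES
    boundary_species: frozenset[str] = BOUNDARY_SPECIES

    def __post_init__(self):
        overlap = self.internal_species & self.boundary_species
        if overlap:
            raise ValueError(f"species both internal and boundary: {sorted(overlap)}")

    def reaction_ids(self) -> list[str]:
        return [r.id for r in self.reactions]


@dataclass
class YieldResult:
    """Outcome of maximizing ATP or NADH production over a pathway."""

    pathway_id: int
    maximize: str  # "atp" | "nadh"
    atp_per_nh4: float
    nadh_per_nh4: float
    net: Reaction
    fluxes: dict[str, float] = field(default_factory=dict)


def get_pathway(pathway_id: int) -> PathwayDefinition:
    """Load one of the three shipped pathway definitions."""
    if pathway_id not in (1, 2, 3):
        raise UnknownIdentifierError(f"no pathway {pathway_id!r}; choose 1, 2 or 3")
    ref = resources.files("nitroyield.data") / f"pathway{pathway_id}.tsv"
    with resources.as_file(ref) as path:
        model = read_table(path)
    return PathwayDefinition(id=pathway_id, reactions=model.reactions)


def _pathway_model(pathway: PathwayDefinition, maximize: str) -> MetabolicModel:
    internal = set(pathway.internal_species)
    boundary = set(pathway.boundary_species)
    if maximize == "nadh":
        internal -= {"nad_c", "nadh_c"}
        boundary |= {"nad_c", "nadh_c"}
    species = []
    seen: set[str] = set()
    for r in pathway.reactions:
        for sid in r.stoich:
            if sid in seen:
                continue
            seen.add(sid)
            comp = "boundary" if sid in boundary else (
                "periplasm" if sid.endswith("_p") else "cytoplasm"
            )
            species.append(Species(id=sid, compartment=comp))
    unclassified = seen - internal - boundary
    if unclassified:
        raise InfeasiblePathwayError(
            f"pathway {pathway.id}: unclassified species {sorted(unclassified)}",
            unbalanced=sorted(unclassified),
        )
    return MetabolicModel(
        species=species,
        reactions=[
            Reaction(r.id, dict(r.stoich), r.lower_bound, r.upper_bound)
            for r in pathway.reactions
        ],
        id=f"pathway{pathway.id}",
    )


def theoretical_yield(
    pathway: PathwayDefinition, maximize: str = "atp"
) -> YieldResult:
    """Maximize ATP (or NADH) production per ammonium oxidized.

    LP over nonnegative fluxes: ammonium uptake fixed at 1, every internal
    species balanced to zero, boundary species free.  The returned net
    reaction is the flux-weighted combination of the pathway reactions.
    """
    if maximize not in ("atp", "nadh"):
        raise ValueError("maximize must be 'atp' or 'nadh'")
    model = _pathway_model(pathway, maximize)
    objective = ATP_REACTION if maximize == "atp" else NADH_REACTION
    present = {r.id for r in model.reactions}
    if UPTAKE_REACTION not in present or objective not in present:
        raise InfeasiblePathwayError(
            f"pathway {pathway.id} lacks {UPTAKE_REACTION} or {objective}; "
            "nothing to combine"
        )
    sol = solve_fba(
        model, objective, sense="max", fixed={UPTAKE_REACTION: 1.0}
    )
    if not sol.optimal:
        unbalanced = _diagnose(model)
        raise InfeasiblePathwayError(
            f"pathway {pathway.id} is {sol.status} with unit ammonium uptake; "
            f"unbalanced internal species: {unbalanced}",
            unbalanced=unbalanced,
        )
    net = net_reaction(model, sol.fluxes, new_id=f"pathway{pathway.id}_{maximize}")
    atp = sum(
        v * model.get_reaction(rid).stoich.get("atp_c", 0.0)
        for rid, v in sol.fluxes.items()
    )
    nadh = sum(
        v * model.get_reaction(rid).stoich.get("nadh_c", 0.0)
        for rid, v in sol.fluxes.items()
    )
    return YieldResult(
        pathway_id=pathway.id,
        maximize=maximize,
        atp_per_nh4=atp,
        nadh_per_nh4=nadh,
        net=net,
        fluxes=sol.fluxes,
    )


def _diagnose(model: MetabolicModel) -> list[str]:
    """Internal species that cannot be balanced at unit uptake: those produced
    but never consumed, or vice versa."""
    bad = []
    for sid in model.balanced_species_ids():
        produced = any(r.stoich.get(sid, 0) > 0 for r in model.reactions)
        consumed = any(r.stoich.get(sid, 0) < 0 for r in model.reactions)
        if produced != consumed:
            bad.append(sid)
    return bad


def proton_ledger(pathway: PathwayDefinition, result: YieldResult) -> float:
    """Net protons translocated outside per ammonium, in ATP-synthase
    currency.

    Sums the outside-proton (``h_p``) production of every reaction except the
    ATP synthase, and counts each NADH made by reverse electron transport as
    the four protons it re-imports.  Dividing by 4 gives the pathway's total
    phosphorylation potential; in ATP-maximizing mode that equals the ATP
    yield itself.
    """
    ledger = 0.0
    ridx = {r.id: r for r in pathway.reactions}
    for rid, v in result.fluxes.items():
        if rid == ATP_REACTION:
            continue
        ledger += v * ridx[rid].stoich.get("h_p", 0.0)
    ledger += PROTONS_PER_NADH * result.nadh_per_nh4
    return ledger


def yield_table() -> list[YieldResult]:
    """Both yield modes for all three pathways (six LP solves)."""
    out = []
    for pid in (1, 2, 3):
        pw = get_pathway(pid)
        for mode in ("atp", "nadh"):
            out.append(theoretical_yield(pw, maximize=mode))
    return out


def check_ledger_invariant(pathway: PathwayDefinition, result: YieldResult) -> bool:
    """ATP + NADH (in 4-proton units) must equal the proton ledger / 4."""
    ledger = proton_ledger(pathway, result)
    total = result.atp_per_nh4 + (PROTONS_PER_NADH / PROTONS_PER_ATP) * result.nadh_per_nh4
    return abs(total - ledger / PROTONS_PER_ATP) < VALUE_TOL
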
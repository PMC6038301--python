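"""ATP and reducing-equivalent cost of making 1 g biomass from CO2.

The procedure mirrors how such costs are obtained from a genome-scale model
of a chemolithoautotroph when the energy-generating pathway itself is not
the question: fix the biomass reaction at 1 gDW gDW^-1 h^-1, zero out the
ammonia-oxidation reactions so no ATP/NADH can come from ammonium, introduce
artificial ATP and NADH input reactions, and minimize the ATP input flux
(then, at the ATP optimum, the NADH input) by FBA.  The minimized inputs in
mmol gDW^-1 h^-1, divided by 1000, are the mol-per-gram costs.

NADH stands in for all reducing equivalents: the model is expected to carry
NADH<->NADPH (1:1) and NADH -> 2 reduced-ferredoxin conversions so every
reductant demand can be expressed in NADH.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

from .errors import InfeasiblePathwayError
from .fba import minimize_sources
from .stoich import MetabolicModel, Reaction

ATP_SOURCE_ID = "SRC_ATP_INPUT"
NADH_SOURCE_ID = "SRC_NADH_INPUT"


@dataclass
class EnergyCost:
    """Energetic cost of 1 g dry biomass.

    ``atp`` and ``nadh`` in mol/gDW; ``nadh_atp_factor`` converts NADH to
    ATP-equivalents (default 1: both cost four translocated protons).
    ``gam_included`` records whether the growth-associated maintenance ATP
    is part of ``atp``.
    """

    atp: float
    nadh: float
    nadh_atp_factor: float = 1.0
    gam_included: bool = True
    gam: float = 25.0

    def __post_init__(self):
        if self.atp < 0 or self.nadh < 0:
            raise ValueError("energy costs must be nonnegative")

    @property
    def atp_equivalent(self) -> float:
        return atp_equivalent(self)

    def without_gam(self) -> "EnergyCost":
        """The same cost with the GAM hydrolysis (gam mmol/gDW) removed."""
        if not self.gam_included:
            return self
        return replace(self, atp=self.atp - self.gam / 1000.0, gam_included=False)


def atp_equivalent(cost: EnergyCost) -> float:
    """Overall energetic expense in mol ATP-equivalent per gDW."""
    if not cost.nadh_atp_factor > 0:
        raise ValueError("nadh_atp_factor must be > 0")
    return cost.atp + cost.nadh_atp_factor * cost.nadh


def _source_reactions(model: MetabolicModel) -> list[Reaction]:
    """Artificial input reactions, phrased with whatever bookkeeping species
    the model actually has."""
    have = {s.id for s in model.species}

    def build(rid: str, wanted: dict[str, float]) -> Reaction:
        stoich = {s: c for s, c in wanted.items() if s in have}
        return Reaction(id=rid, stoich=stoich, lower_bound=0.0, upper_bound=1e6)

    atp_src = build(
        ATP_SOURCE_ID,
        {"adp_c": -1, "pi_c": -1, "h_c": -1, "atp_c": 1, "h2o_c": 1},
    )
    nadh_src = build(NADH_SOURCE_ID, {"nad_c": -1, "h_c": -1, "nadh_c": 1})
    return [atp_src, nadh_src]


def biomass_energy_cost(
    model: MetabolicModel,
    oxidation_ids: list[str] | None = None,
    nadh_atp_factor: float = 1.0,
) -> EnergyCost:
    """Minimized ATP and NADH inputs for unit biomass flux, in mol/gDW.

    ``oxidation_ids`` — the ammonia-oxidation reactions to block (explicit id
    list; defaults to every reaction whose subsystem is tagged
    ``ammonia oxidation`` plus the electron-transport/energy reactions of the
    shipped oxidation module, if present).  ATP is minimized first, then NADH
    at the fixed ATP optimum.
    """
    if model.biomass_id is None:
        raise ValueError("model has no biomass reaction designated")
    work = model.copy()
    if oxidation_ids is None:
        oxidation_ids = [
            r.id
            for r in work.reactions
            if r.subsystem in ("ammonia oxidation", "electron transport", "energy")
        ]
    work.reactions.extend(_source_reactions(work))
    work.validate()
    sol = minimize_sources(
        work,
        sources=[ATP_SOURCE_ID, NADH_SOURCE_ID],
        fixed={model.biomass_id: 1.0},
        blocked=set(oxidation_ids) & {r.id for r in work.reactions},
    )
    if not sol.optimal:
        raise InfeasiblePathwayError(
            f"biomass flux of 1 is {sol.status} with the oxidation pathway "
            "blocked and free ATP/NADH input; a biomass precursor is likely "
            "only reachable through the blocked reactions"
        )
    return EnergyCost(
        atp=sol.source_minima[ATP_SOURCE_ID] / 1000.0,
        nadh=sol.source_minima[NADH_SOURCE_ID] / 1000.0,
        nadh_atp_factor=nadh_atp_factor,
        gam_included=True,
        gam=model.gam,
    )
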
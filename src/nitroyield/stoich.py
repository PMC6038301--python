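"""Stoichiometric algebra for small constraint-based models.

Species, reactions, net-reaction combination, and the biomass mass-balance
contract used throughout the package: a biomass equation written per gram
dry weight must satisfy

    (sum_i S_i^R M_i^R - sum_j S_j^B M_j^B) / 1000 = 1 gDW

where ``S`` are coefficients in mmol/gDW and ``M`` molar masses in g/mol,
requirements ``R`` on the consumed side and by-products ``B`` on the
produced side.

Sign convention: a single signed coefficient map per reaction, negative for
consumed species and positive for produced species.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import (
    MissingMassError,
    NormalizationError,
    UnknownIdentifierError,
)

#: Coefficients smaller than this (absolute) are treated as LP round-off
#: and dropped from net reactions.
COEF_EPS = 1e-9

#: Species participating in the growth-associated maintenance (GAM)
#: hydrolysis ATP + H2O -> ADP + Pi + H+.  They are excluded from biomass
#: mass-balance scaling because the hydrolysis is mass-neutral.
GAM_SPECIES = frozenset({"atp_c", "adp_c", "pi_c", "h2o_c", "h_c"})

COMPARTMENTS = ("cytoplasm", "periplasm", "boundary")


@dataclass(frozen=True)
class Species:
    """One chemical entity in one compartment.

    ``molar_mass`` (g/mol) is optional and only required for species that
    appear in a biomass equation or a mass-balance check.
    """

    id: str
    name: str = ""
    compartment: str = "cytoplasm"
    molar_mass: float | None = None

    def __post_init__(self):
        if self.compartment not in COMPARTMENTS:
            raise ValueError(
                f"unknown compartment {self.compartment!r} for species {self.id!r}"
            )
        if self.molar_mass is not None and not self.molar_mass > 0:
            raise ValueError(f"molar mass of {self.id!r} must be > 0")


@dataclass
class Reaction:
    """A signed stoichiometric map with flux bounds (mmol gDW^-1 h^-1).

    Zero-valued coefficients are never stored; an empty map is the
    "empty reaction" produced e.g. by an all-zero flux combination.
    """

    id: str
    stoich: dict[str, float] = field(default_factory=dict)
    lower_bound: float = 0.0
    upper_bound: float = 1000.0
    name: str = ""
    subsystem: str = ""
    genes: str = ""

    def __post_init__(self):
        if self.lower_bound > self.upper_bound:
            raise ValueError(
                f"reaction {self.id!r}: lower bound {self.lower_bound} exceeds "
                f"upper bound {self.upper_bound}"
            )
        self.stoich = {s: float(c) for s, c in self.stoich.items() if c != 0.0}

    @property
    def reversible(self) -> bool:
        return self.lower_bound < 0.0

    @property
    def reactants(self) -> dict[str, float]:
        """Consumed species, as positive magnitudes."""
        return {s: -c for s, c in self.stoich.items() if c < 0}

    @property
    def products(self) -> dict[str, float]:
        return {s: c for s, c in self.stoich.items() if c > 0}

    def scaled(self, factor: float, new_id: str | None = None) -> "Reaction":
        return replace(
            self,
            id=new_id or self.id,
            stoich={s: c * factor for s, c in self.stoich.items()},
        )


@dataclass
class BiomassEquation:
    """A biomass reaction whose coefficients are mmol per gDW.

    Negative coefficients are growth requirements R_i, positive ones
    by-products B_j.  The produced biomass pseudo-species itself (if the
    reaction carries one) and the GAM hydrolysis couple are excluded from
    the mass sums.
    """

    reaction: Reaction
    biomass_species: str | None = None
    gam_species: frozenset[str] = GAM_SPECIES

    def mass_terms(self) -> dict[str, float]:
        """Coefficients entering the mass balance (GAM couple and biomass
        pseudo-species excluded)."""
        return {
            s: c
            for s, c in self.reaction.stoich.items()
            if s != self.biomass_species and s not in self.gam_species
        }


@dataclass
class MetabolicModel:
    """Species + reactions with a designated biomass reaction and exchanges.

    ``gam`` is the growth-associated maintenance in mmol ATP/gDW embedded in
    the biomass reaction (default 25, the value adopted from the closest
    curated archaeal model).
    """

    species: list[Species] = field(default_factory=list)
    reactions: list[Reaction] = field(default_factory=list)
    biomass_id: str | None = None
    exchange_ids: list[str] = field(default_factory=list)
    gam: float = 25.0
    id: str = "model"

    def __post_init__(self):
        self.validate()

    # -- lookup ---------------------------------------------------------
    @property
    def species_index(self) -> dict[str, int]:
        return {s.id: i for i, s in enumerate(self.species)}

    @property
    def reaction_index(self) -> dict[str, int]:
        return {r.id: i for i, r in enumerate(self.reactions)}

    def get_reaction(self, rid: str) -> Reaction:
        try:
            return self.reactions[self.reaction_index[rid]]
        except KeyError:
            raise UnknownIdentifierError(rid) from None

    def get_species(self, sid: str) -> Species:
        try:
            return self.species[self.species_index[sid]]
        except KeyError:
            raise UnknownIdentifierError(sid) from None

    # -- structure ------------------------------------------------------
    def validate(self) -> None:
        ids = [s.id for s in self.species]
        if len(ids) != len(set(ids)):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate species ids: {dup}")
        rids = [r.id for r in self.reactions]
        if len(rids) != len(set(rids)):
            dup = sorted({i for i in rids if rids.count(i) > 1})
            raise ValueError(f"duplicate reaction ids: {dup}")
        known = set(ids)
        for r in self.reactions:
            missing = set(r.stoich) - known
            if missing:
                raise UnknownIdentifierError(
                    f"reaction {r.id!r} references unknown species {sorted(missing)}"
                )
        if self.biomass_id is not None and self.biomass_id not in set(rids):
            raise UnknownIdentifierError(
                f"biomass reaction {self.biomass_id!r} not in model"
            )

    def stoichiometric_matrix(self) -> np.ndarray:
        """Dense S, |species| x |reactions|."""
        sidx = self.species_index
        S = np.zeros((len(self.species), len(self.reactions)))
        for j, r in enumerate(self.reactions):
            for s, c in r.stoich.items():
                S[sidx[s], j] = c
        return S

    def balanced_species_ids(self) -> list[str]:
        """Species subject to the steady-state constraint S.v = 0: everything
        outside the boundary compartment."""
        return [s.id for s in self.species if s.compartment != "boundary"]

    def copy(self) -> "MetabolicModel":
        return MetabolicModel(
            species=list(self.species),
            reactions=[replace(r, stoich=dict(r.stoich)) for r in self.reactions],
            biomass_id=self.biomass_id,
            exchange_ids=list(self.exchange_ids),
            gam=self.gam,
            id=self.id,
        )


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def net_reaction(
    model: MetabolicModel,
    flux: dict[str, float],
    new_id: str = "net",
    eps: float = COEF_EPS,
) -> Reaction:
    """Combine reactions at the given fluxes into one overall reaction.

    The coefficient of each species in the result is the flux-weighted sum of
    its coefficients over all reactions; coefficients below ``eps`` in
    magnitude are dropped as round-off.  This is how a pathway's reaction set
    is lumped into the single overall transformation it performs.
    """
    ridx = model.reaction_index
    acc: dict[str, float] = {}
    for rid, v in flux.items():
        if rid not in ridx:
            raise UnknownIdentifierError(rid)
        for s, c in model.reactions[ridx[rid]].stoich.items():
            acc[s] = acc.get(s, 0.0) + v * c
    stoich = {s: c for s, c in acc.items() if abs(c) >= eps}
    return Reaction(id=new_id, stoich=stoich, lower_bound=0.0, upper_bound=1000.0)


def mass_balance_residual(
    biomass: BiomassEquation, masses: dict[str, float]
) -> float:
    """Signed deviation (grams) of the biomass equation from 1 gDW.

    Returns ``(sum_R S M - sum_B S M)/1000 - 1`` over the scalable mass terms;
    0 for a correctly normalized equation.
    """
    total = 0.0
    for sid, coef in biomass.mass_terms().items():
        if sid not in masses:
            raise MissingMassError(sid)
        # requirements carry negative coefficients: -coef = S_i^R
        total += -coef * masses[sid]
    return total / 1000.0 - 1.0


def normalize_biomass(
    biomass: BiomassEquation, masses: dict[str, float]
) -> BiomassEquation:
    """Uniformly rescale the biomass coefficients so they account for exactly
    1 gDW.

    Only the scalable (non-GAM, non-pseudo-species) coefficients are rescaled;
    the GAM hydrolysis couple is mass-neutral and is carried through unchanged,
    as is the unit biomass pseudo-species coefficient.  Idempotent.
    """
    net_mass = 0.0
    for sid, coef in biomass.mass_terms().items():
        if sid not in masses:
            raise MissingMassError(sid)
        net_mass += -coef * masses[sid]
    if abs(net_mass) < 1e-12:
        raise NormalizationError(
            "biomass equation has zero net scalable mass; scaling is undefined"
        )
    factor = 1000.0 / net_mass
    new_stoich = {}
    scalable = biomass.mass_terms()
    for sid, coef in biomass.reaction.stoich.items():
        new_stoich[sid] = coef * factor if sid in scalable else coef
    return BiomassEquation(
        reaction=replace(biomass.reaction, stoich=new_stoich),
        biomass_species=biomass.biomass_species,
        gam_species=biomass.gam_species,
    )
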
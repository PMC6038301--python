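"""Synthetic fixture models with analytically known ground truth.

These generators make every pipeline stage testable without any external
model file:

* :func:`make_toy_autotroph` — a minimal CO2-fixing autotroph whose single
  biomass route consumes exactly the planted ATP and NADH amounts per gram
  biomass (the reductant demand is expressed as NADPH so the NADH->NADPH
  conversion is exercised), optionally wired to the pathway-1 ammonia
  oxidation module so it grows chemolithoautotrophically;
* :func:`make_loop_fixture` — a network with an objective-neutral 3-cycle
  and an erroneous reversible kinase/phosphatase pair whose reverse
  operation, together with the ATP-maintenance reaction, forms an internal
  cycle that regenerates ATP from nothing;
* :func:`make_imbalanced_biomass` — a biomass equation whose scalable
  coefficients are off by a known factor.

All generators are deterministic: identical spec (and seed) gives
byte-identical serialized output.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

from .errors import GenerationError
from .model_io import read_table
from .stoich import BiomassEquation, MetabolicModel, Reaction, Species

#: mmol of the lumped precursor per gDW; with a 100 g/mol precursor this
#: accounts for exactly 1000 mg, so the toy biomass equation is born balanced
PRECURSOR_MMOL = 10.0
PRECURSOR_MASS = 100.0

#: masses chosen so the GAM hydrolysis is exactly mass-neutral
#: (ATP + H2O = ADP + Pi + H: 507 + 18 = 427 + 97 + 1)
TOY_MASSES = {
    "precursor_c": PRECURSOR_MASS,
    "atp_c": 507.0,
    "adp_c": 427.0,
    "pi_c": 97.0,
    "h2o_c": 18.0,
    "h_c": 1.0,
}


@dataclass(frozen=True)
class ToySpec:
    """Ground truth planted in a toy autotroph.

    ``atp_cost``/``nadh_cost`` in mol per gDW (excluding GAM), ``gam`` in
    mmol ATP per gDW, ``imbalance_factor`` scales the scalable biomass
    coefficients away from mass balance.
    """

    atp_cost: float = 0.10
    nadh_cost: float = 0.05
    gam: float = 25.0
    include_oxidation_module: bool = False
    include_futile_loop: bool = False
    imbalance_factor: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.atp_cost < 0 or self.nadh_cost < 0 or self.gam < 0:
            raise GenerationError("costs and GAM must be nonnegative")
        if (
            self.atp_cost == 0
            and self.nadh_cost == 0
            and self.gam == 0
            and not self.include_oxidation_module
        ):
            raise GenerationError(
                "contradictory spec: no energy demand and no energy module — "
                "the planted cost would be unidentifiable"
            )


def _base_species() -> list[Species]:
    sp = [
        Species("co2_c", "CO2", "cytoplasm", 44.0),
        Species("precursor_c", "lumped biomass precursor", "cytoplasm",
                PRECURSOR_MASS),
        Species("biomass_c", "biomass", "cytoplasm"),
        Species("atp_c", "ATP", "cytoplasm", TOY_MASSES["atp_c"]),
        Species("adp_c", "ADP", "cytoplasm", TOY_MASSES["adp_c"]),
        Species("pi_c", "phosphate", "cytoplasm", TOY_MASSES["pi_c"]),
        Species("h2o_c", "water", "cytoplasm", TOY_MASSES["h2o_c"]),
        Species("h_c", "proton (in)", "cytoplasm", TOY_MASSES["h_c"]),
        Species("nad_c", "NAD+", "cytoplasm"),
        Species("nadh_c", "NADH", "cytoplasm"),
        Species("nadp_c", "NADP+", "cytoplasm"),
        Species("nadph_c", "NADPH", "cytoplasm"),
        Species("fdox_c", "oxidized ferredoxin", "cytoplasm"),
        Species("fdred_c", "reduced ferredoxin", "cytoplasm"),
    ]
    return sp


def make_toy_autotroph(spec: ToySpec) -> MetabolicModel:
    """Build a toy autotroph whose unique biomass route needs exactly
    ``spec.atp_cost`` mol ATP and ``spec.nadh_cost`` mol NADH per gDW (plus
    GAM)."""
    a = 1000.0 * spec.atp_cost / PRECURSOR_MMOL   # mmol ATP per mmol precursor
    b = 1000.0 * spec.nadh_cost / PRECURSOR_MMOL  # as NADPH, via the NNT step
    g = spec.gam

    species = _base_species()
    reactions = [
        Reaction("EX_co2", {"co2_c": -1}, -1000, 1000),
        Reaction("EX_h2o", {"h2o_c": -1}, -1000, 1000),
        Reaction("EX_h", {"h_c": -1}, -1000, 1000),
        Reaction("EX_biomass", {"biomass_c": -1}, 0, 1000),
        Reaction(
            "CFIX",
            {
                "co2_c": -1.0,
                "atp_c": -a, "h2o_c": -a,
                "adp_c": a, "pi_c": a, "h_c": a,
                "nadph_c": -b, "nadp_c": b,
                "precursor_c": 1.0,
            },
            0, 1000,
            name="lumped carbon fixation",
            subsystem="carbon fixation",
        ),
        Reaction(
            "NNT",
            {"nadh_c": -1, "nadp_c": -1, "nad_c": 1, "nadph_c": 1},
            0, 1000,
            name="NADH -> NADPH transhydrogenase",
        ),
        Reaction(
            "FNR",
            {"nadh_c": -1, "fdox_c": -2, "nad_c": 1, "fdred_c": 2, "h_c": 1},
            0, 1000,
            name="NADH -> 2 reduced ferredoxin",
        ),
        Reaction(
            "BIOMASS",
            {
                "precursor_c": -PRECURSOR_MMOL * spec.imbalance_factor,
                "atp_c": -g, "h2o_c": -g,
                "adp_c": g, "pi_c": g, "h_c": g,
                "biomass_c": 1.0,
            },
            0, 1000,
            name="biomass production",
        ),
    ]
    exchange_ids = ["EX_co2", "EX_h2o", "EX_h", "EX_biomass"]

    if spec.include_oxidation_module:
        ref = resources.files("nitroyield.data") / "pathway1.tsv"
        with resources.as_file(ref) as path:
            ox = read_table(path)
        known = {s.id for s in species}
        for r in ox.reactions:
            for sid in r.stoich:
                if sid not in known:
                    known.add(sid)
                    comp = (
                        "boundary" if sid.endswith("_e")
                        else "periplasm" if sid.endswith("_p")
                        else "cytoplasm"
                    )
                    species.append(Species(sid, compartment=comp))
            reactions.append(r)
        for ex_id, sid, lb in [
            ("EX_o2", "o2_c", -1000.0),
            ("EX_hno2", "hno2_c", 0.0),
            ("EX_n2o", "n2o_c", 0.0),
        ]:
            reactions.append(Reaction(ex_id, {sid: -1}, lb, 1000))
            exchange_ids.append(ex_id)

    if spec.include_futile_loop:
        for sid in ("la_c", "lb_c", "lc_c"):
            species.append(Species(sid, compartment="cytoplasm"))
        reactions += [
            Reaction("LOOP1", {"la_c": -1, "lb_c": 1}, -1000, 1000),
            Reaction("LOOP2", {"lb_c": -1, "lc_c": 1}, -1000, 1000),
            Reaction("LOOP3", {"lc_c": -1, "la_c": 1}, -1000, 1000),
        ]

    return MetabolicModel(
        species=species,
        reactions=reactions,
        biomass_id="BIOMASS",
        exchange_ids=exchange_ids,
        gam=spec.gam,
        id=f"toy_autotroph_s{spec.seed}",
    )


def toy_biomass_equation(model: MetabolicModel) -> BiomassEquation:
    """The toy model's biomass reaction wrapped for mass-balance checks."""
    return BiomassEquation(
        reaction=model.get_reaction(model.biomass_id),
        biomass_species="biomass_c",
    )


def oxidation_module_ids(model: MetabolicModel) -> list[str]:
    """Ids of the ammonia-oxidation energy module inside a toy model."""
    module = {
        "Trans_NH4", "AMO", "HAO", "QH2_Synt", "NIR", "N2O_spon",
        "Cytbc1", "Cytaa3", "ATP_Synt", "NADH_Synt",
    }
    return [r.id for r in model.reactions if r.id in module]


def make_loop_fixture(corrected: bool = False) -> MetabolicModel:
    """Network with a legitimate ATP route, a neutral 3-cycle and an
    erroneous reversible pair.

    Maximizing the ATP maintenance reaction ``ATPM`` with glucose blocked
    exposes the error: plain FBA turns the reversed kinase/phosphatase pair
    into an internal ATP-regenerating cycle (unlimited ATP), which loopless
    FBA excludes.  With ``corrected=True`` the pair is irreversible, the
    historically applied fix.
    """
    species = [
        Species("glc_c", "glucose", "cytoplasm"),
        Species("byp_c", "byproduct", "cytoplasm"),
        Species("g_c", "substrate G", "cytoplasm"),
        Species("gp_c", "phospho-G", "cytoplasm"),
        Species("atp_c", compartment="cytoplasm"),
        Species("adp_c", compartment="cytoplasm"),
        Species("pi_c", compartment="cytoplasm"),
        Species("h2o_c", compartment="cytoplasm"),
        Species("h_c", compartment="cytoplasm"),
        Species("la_c", compartment="cytoplasm"),
        Species("lb_c", compartment="cytoplasm"),
        Species("lc_c", compartment="cytoplasm"),
    ]
    pair_lb = 0.0 if corrected else -1000.0
    reactions = [
        Reaction("EX_glc", {"glc_c": -1}, -10, 0),
        Reaction("EX_byp", {"byp_c": -1}, 0, 1000),
        Reaction("EX_h2o", {"h2o_c": -1}, -1000, 1000),
        Reaction("EX_h", {"h_c": -1}, -1000, 1000),
        Reaction(
            "CAT",
            {"glc_c": -1, "adp_c": -2, "pi_c": -2, "atp_c": 2, "h2o_c": 2,
             "byp_c": 1},
            0, 1000, name="lumped catabolism",
        ),
        Reaction(
            "ATPM",
            {"atp_c": -1, "h2o_c": -1, "adp_c": 1, "pi_c": 1, "h_c": 1},
            0, 1000, name="ATP maintenance",
        ),
        Reaction("KIN", {"g_c": -1, "atp_c": -1, "gp_c": 1, "adp_c": 1},
                 pair_lb, 1000, name="kinase (erroneously reversible)"),
        Reaction("PHOS", {"gp_c": -1, "h2o_c": -1, "g_c": 1, "pi_c": 1,
                          "h_c": 1},
                 pair_lb, 1000, name="phosphatase (erroneously reversible)"),
        Reaction("LOOP1", {"la_c": -1, "lb_c": 1}, -1000, 1000),
        Reaction("LOOP2", {"lb_c": -1, "lc_c": 1}, -1000, 1000),
        Reaction("LOOP3", {"lc_c": -1, "la_c": 1}, -1000, 1000),
    ]
    return MetabolicModel(
        species=species,
        reactions=reactions,
        exchange_ids=["EX_glc", "EX_byp", "EX_h2o", "EX_h"],
        id="loop_fixture" + ("_corrected" if corrected else ""),
    )


def make_imbalanced_biomass(factor: float, seed: int = 0) -> BiomassEquation:
    """A toy biomass equation whose scalable coefficients are scaled by
    ``factor`` away from the 1 gDW balance (factor 1 = balanced)."""
    if factor == 0:
        raise GenerationError("imbalance factor 0 gives an empty biomass")
    model = make_toy_autotroph(
        ToySpec(atp_cost=0.0, nadh_cost=0.0, gam=25.0,
                imbalance_factor=factor, seed=seed)
    )
    return toy_biomass_equation(model)
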
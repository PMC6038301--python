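"""Model input/output.

Three surfaces:

* a human-readable reaction-equation grammar
  (``coef? species (+ coef? species)* ("->"|"<=>") ...``) used both in the
  shipped pathway fixture files and in the tabular model dialect;
* a TSV model dialect with columns
  ``id  name  equation  lb  ub  subsystem  genes`` mirroring the layout of a
  curated-model spreadsheet;
* SBML (Level 3 + FBC v2 on write; plain SBML with kinetic-law or FBC bounds
  accepted on read).

Species-id convention: lowercase tokens with a compartment suffix ``_c``
(cytoplasm / "in"), ``_p`` (pseudo-periplasm / "out") or ``_e`` (boundary).
"""

from __future__ import annotations

import csv
import logging
import re
from pathlib import Path

import libsbml

from .errors import EquationParseError, ModelIOError
from .stoich import MetabolicModel, Reaction, Species

log = logging.getLogger(__name__)

#: conventional "unbounded" flux sentinel
BOUND = 1000.0

_ARROWS = ("<=>", "->")
_TOKEN_RE = re.compile(r"[A-Za-z_][A-Za-z0-9_]*$")
_NUM_RE = re.compile(r"\d+(\.\d+)?([eE][+-]?\d+)?$")


# ---------------------------------------------------------------------------
# equation strings
# ---------------------------------------------------------------------------

def _parse_side(side: str, offset: int) -> list[tuple[str, float]]:
    terms: list[tuple[str, float]] = []
    side_stripped = side.strip()
    if not side_stripped:
        return terms
    pos = offset
    for chunk in side.split("+"):
        token = chunk.strip()
        if not token:
            raise EquationParseError("empty term", column=pos)
        parts = token.split()
        if len(parts) == 1:
            coef, sid = 1.0, parts[0]
        elif len(parts) == 2:
            if not _NUM_RE.match(parts[0]):
                raise EquationParseError(
                    f"bad coefficient {parts[0]!r}", column=pos
                )
            coef, sid = float(parts[0]), parts[1]
        else:
            raise EquationParseError(f"bad term {token!r}", column=pos)
        if not _TOKEN_RE.match(sid):
            raise EquationParseError(f"bad species token {sid!r}", column=pos)
        terms.append((sid, coef))
        pos += len(chunk) + 1
    return terms


def parse_equation(
    text: str, rid: str = "rxn", bound: float = BOUND
) -> Reaction:
    """Parse a reaction-equation string into a Reaction.

    ``->`` yields an irreversible reaction (bounds ``[0, bound]``), ``<=>`` a
    reversible one (``[-bound, bound]``).  A species occurring on both sides
    with equal coefficients (a pure self-loop such as ``a <=> a``) is
    rejected, since it denotes no transformation.
    """
    arrow = next((a for a in _ARROWS if a in text), None)
    if arrow is None:
        raise EquationParseError(f"no arrow in {text!r}", column=0)
    left, right = text.split(arrow, 1)
    if not left.strip() and not right.strip():
        raise EquationParseError(f"equation {text!r} has no species", column=0)
    stoich: dict[str, float] = {}
    for sid, coef in _parse_side(left, 0):
        stoich[sid] = stoich.get(sid, 0.0) - coef
    for sid, coef in _parse_side(right, len(left) + len(arrow)):
        stoich[sid] = stoich.get(sid, 0.0) + coef
    stoich = {s: c for s, c in stoich.items() if c != 0.0}
    if not stoich and text.strip(" ->=<"):
        raise EquationParseError(
            f"equation {text!r} nets to nothing (self-loop)", column=0
        )
    lb = -bound if arrow == "<=>" else 0.0
    return Reaction(id=rid, stoich=stoich, lower_bound=lb, upper_bound=bound)


def _fmt_coef(c: float) -> str:
    return f"{c:.10g}"


def render_equation(reaction: Reaction) -> str:
    """Inverse of :func:`parse_equation` (up to whitespace)."""
    def side(terms: dict[str, float]) -> str:
        parts = []
        for sid in sorted(terms):
            c = terms[sid]
            parts.append(sid if c == 1.0 else f"{_fmt_coef(c)} {sid}")
        return " + ".join(parts)

    arrow = "<=>" if reaction.reversible else "->"
    return f"{side(reaction.reactants)} {arrow} {side(reaction.products)}".strip()


# ---------------------------------------------------------------------------
# TSV dialect
# ---------------------------------------------------------------------------

_TSV_COLUMNS = ["id", "name", "equation", "lb", "ub", "subsystem", "genes"]


def _infer_compartment(sid: str) -> str:
    if sid.endswith("_p"):
        return "periplasm"
    if sid.endswith("_e"):
        return "boundary"
    return "cytoplasm"


def _species_from_reactions(
    reactions: list[Reaction], known: dict[str, Species] | None = None
) -> list[Species]:
    known = known or {}
    out: dict[str, Species] = {}
    for r in reactions:
        for sid in r.stoich:
            if sid not in out:
                out[sid] = known.get(
                    sid, Species(id=sid, compartment=_infer_compartment(sid))
                )
    return list(out.values())


def read_table(path: str | Path, model_id: str | None = None) -> MetabolicModel:
    """Read a model from the TSV dialect.

    Rows beginning with ``#`` are comments.  ``lb``/``ub`` may be blank, in
    which case the arrow in the equation column decides the default bounds.
    A row with id ``@biomass <rid>`` / ``@gam <value>`` in the ``#!`` header
    comment area sets model metadata.
    """
    path = Path(path)
    if not path.exists():
        raise ModelIOError(f"no such model file: {path}")
    reactions: list[Reaction] = []
    biomass_id = None
    gam = 25.0
    masses: dict[str, float] = {}
    with open(path, newline="") as fh:
        for raw in fh:
            line = raw.rstrip("\n")
            if line.startswith("#!"):
                directive = line[2:].strip().split()
                if directive and directive[0] == "biomass":
                    biomass_id = directive[1]
                elif directive and directive[0] == "gam":
                    gam = float(directive[1])
                elif directive and directive[0] == "mass":
                    masses[directive[1]] = float(directive[2])
                continue
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if fields[0] == "id":  # header
                continue
            fields += [""] * (len(_TSV_COLUMNS) - len(fields))
            rid, name, eq, lb, ub, subsystem, genes = fields[: len(_TSV_COLUMNS)]
            r = parse_equation(eq, rid=rid)
            if lb.strip():
                r.lower_bound = float(lb)
            if ub.strip():
                r.upper_bound = float(ub)
            r.name, r.subsystem, r.genes = name, subsystem, genes
            reactions.append(r)
    species = _species_from_reactions(reactions)
    if masses:
        species = [
            Species(s.id, s.name, s.compartment, masses.get(s.id, s.molar_mass))
            for s in species
        ]
    exchange_ids = [r.id for r in reactions if len(r.stoich) == 1]
    model = MetabolicModel(
        species=species,
        reactions=reactions,
        biomass_id=biomass_id,
        exchange_ids=exchange_ids,
        gam=gam,
        id=model_id or path.stem,
    )
    log.info("read %d reactions / %d species from %s", len(reactions),
             len(species), path)
    return model


def write_table(model: MetabolicModel, path: str | Path) -> None:
    path = Path(path)
    with open(path, "w", newline="") as fh:
        if model.biomass_id:
            fh.write(f"#! biomass {model.biomass_id}\n")
        fh.write(f"#! gam {model.gam:.10g}\n")
        for s in model.species:
            if s.molar_mass is not None:
                fh.write(f"#! mass {s.id} {s.molar_mass:.10g}\n")
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(_TSV_COLUMNS)
        for r in model.reactions:
            w.writerow(
                [
                    r.id,
                    r.name,
                    render_equation(r),
                    _fmt_coef(r.lower_bound),
                    _fmt_coef(r.upper_bound),
                    r.subsystem,
                    r.genes,
                ]
            )
    log.info("wrote %d reactions to %s", len(model.reactions), path)


# ---------------------------------------------------------------------------
# SBML
# ---------------------------------------------------------------------------

_COMP_CODES = {"cytoplasm": "c", "periplasm": "p", "boundary": "e"}
_COMP_NAMES = {v: k for k, v in _COMP_CODES.items()}


def read_sbml(path: str | Path) -> MetabolicModel:
    """Read an SBML model (any level the libsbml reader can sniff).

    Bounds are taken from the FBC package when present, else from
    ``LOWER_BOUND``/``UPPER_BOUND`` kinetic-law parameters (the pre-FBC
    convention); reactions with neither get the documented defaults
    (-1000, 1000) if marked reversible, (0, 1000) otherwise, with a warning.
    """
    path = Path(path)
    if not path.exists():
        raise ModelIOError(f"no such SBML file: {path}")
    doc = libsbml.readSBMLFromFile(str(path))
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR) > 0:
        raise ModelIOError(
            f"SBML parse errors in {path}: "
            f"{doc.getErrorLog().toString()[:500]}"
        )
    sbml_model = doc.getModel()
    if sbml_model is None:
        raise ModelIOError(f"{path} contains no model")
    fbc = sbml_model.getPlugin("fbc")

    species: list[Species] = []
    boundary_ids: set[str] = set()
    for i in range(sbml_model.getNumSpecies()):
        sp = sbml_model.getSpecies(i)
        comp = _COMP_NAMES.get(sp.getCompartment(), "cytoplasm")
        if sp.getBoundaryCondition():
            comp = "boundary"
            boundary_ids.add(sp.getId())
        species.append(Species(id=sp.getId(), name=sp.getName(), compartment=comp))

    def _fbc_bound(rxn, which: str) -> float | None:
        plug = rxn.getPlugin("fbc")
        if plug is None:
            return None
        pid = (
            plug.getLowerFluxBound() if which == "lb" else plug.getUpperFluxBound()
        )
        if not pid:
            return None
        param = sbml_model.getParameter(pid)
        return param.getValue() if param is not None else None

    def _kinetic_bound(rxn, which: str) -> float | None:
        kl = rxn.getKineticLaw()
        if kl is None:
            return None
        name = "LOWER_BOUND" if which == "lb" else "UPPER_BOUND"
        p = kl.getParameter(name)
        return p.getValue() if p is not None else None

    reactions: list[Reaction] = []
    for i in range(sbml_model.getNumReactions()):
        rxn = sbml_model.getReaction(i)
        stoich: dict[str, float] = {}
        for j in range(rxn.getNumReactants()):
            ref = rxn.getReactant(j)
            stoich[ref.getSpecies()] = (
                stoich.get(ref.getSpecies(), 0.0) - ref.getStoichiometry()
            )
        for j in range(rxn.getNumProducts()):
            ref = rxn.getProduct(j)
            stoich[ref.getSpecies()] = (
                stoich.get(ref.getSpecies(), 0.0) + ref.getStoichiometry()
            )
        lb = _fbc_bound(rxn, "lb")
        if lb is None:
            lb = _kinetic_bound(rxn, "lb")
        ub = _fbc_bound(rxn, "ub")
        if ub is None:
            ub = _kinetic_bound(rxn, "ub")
        if lb is None or ub is None:
            rev = rxn.getReversible()
            log.warning(
                "reaction %s has no explicit bounds; defaulting to %s",
                rxn.getId(), "(-1000, 1000)" if rev else "(0, 1000)",
            )
            lb = -BOUND if rev else 0.0 if lb is None else lb
            ub = BOUND if ub is None else ub
        reactions.append(
            Reaction(
                id=rxn.getId(),
                stoich=stoich,
                lower_bound=lb,
                upper_bound=ub,
                name=rxn.getName(),
            )
        )

    biomass_id = None
    if fbc is not None and fbc.getNumObjectives() > 0:
        obj = fbc.getActiveObjective() or fbc.getObjective(0)
        if obj is not None and obj.getNumFluxObjectives() > 0:
            biomass_id = obj.getFluxObjective(0).getReaction()
    if biomass_id is None:
        for r in reactions:
            if "biomass" in r.id.lower():
                biomass_id = r.id
                break
    exchange_ids = [
        r.id
        for r in reactions
        if len(r.stoich) == 1 or set(r.stoich) & boundary_ids
        or r.id.upper().startswith("EX_")
    ]
    model = MetabolicModel(
        species=species,
        reactions=reactions,
        biomass_id=biomass_id,
        exchange_ids=sorted(set(exchange_ids)),
        id=sbml_model.getId() or path.stem,
    )
    log.info(
        "read SBML %s: %d reactions, %d species",
        path, len(reactions), len(species),
    )
    return model


def write_sbml(model: MetabolicModel, path: str | Path) -> None:
    """Write the model as SBML Level 3 Version 1 with FBC v2 bounds."""
    ns = libsbml.SBMLNamespaces(3, 1, "fbc", 2)
    doc = libsbml.SBMLDocument(ns)
    doc.setPackageRequired("fbc", False)
    m = doc.createModel()
    m.setId(model.id)
    mplug = m.getPlugin("fbc")
    mplug.setStrict(False)

    for code, name in _COMP_NAMES.items():
        comp = m.createCompartment()
        comp.setId(code)
        comp.setName(name)
        comp.setConstant(True)

    for s in model.species:
        sp = m.createSpecies()
        sp.setId(s.id)
        sp.setName(s.name)
        sp.setCompartment(_COMP_CODES[s.compartment])
        sp.setBoundaryCondition(s.compartment == "boundary")
        sp.setHasOnlySubstanceUnits(False)
        sp.setConstant(False)

    bound_params: dict[float, str] = {}

    def _param_for(value: float) -> str:
        if value not in bound_params:
            pid = f"fb_{len(bound_params)}"
            p = m.createParameter()
            p.setId(pid)
            p.setValue(value)
            p.setConstant(True)
            bound_params[value] = pid
        return bound_params[value]

    for r in model.reactions:
        rxn = m.createReaction()
        rxn.setId(r.id)
        rxn.setName(r.name)
        rxn.setReversible(r.reversible)
        rxn.setFast(False)
        for sid, coef in sorted(r.stoich.items()):
            ref = rxn.createReactant() if coef < 0 else rxn.createProduct()
            ref.setSpecies(sid)
            ref.setStoichiometry(abs(coef))
            ref.setConstant(True)
        rplug = rxn.getPlugin("fbc")
        rplug.setLowerFluxBound(_param_for(r.lower_bound))
        rplug.setUpperFluxBound(_param_for(r.upper_bound))

    if model.biomass_id:
        obj = mplug.createObjective()
        obj.setId("obj")
        obj.setType("maximize")
        fo = obj.createFluxObjective()
        fo.setReaction(model.biomass_id)
        fo.setCoefficient(1.0)
        mplug.setActiveObjectiveId("obj")

    if libsbml.writeSBMLToFile(doc, str(path)) != 1:
        raise ModelIOError(f"could not write SBML to {path}")
    log.info("wrote SBML model %s to %s", model.id, path)
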
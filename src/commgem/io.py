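"""Model readers/writers: a JSON dialect and SBML Level 3 with fbc bounds.

Round-tripping either format preserves reactions, bounds, compartment tags,
the transport flag, the objective/biomass designation and provenance at the
document-model level.
"""

from __future__ import annotations

import json
import re
from pathlib import Path
from typing import Optional

import libsbml

from .draftgem import ModelReaction, OrganismModel

__all__ = [
    "model_to_json",
    "model_from_json",
    "write_json_model",
    "read_json_model",
    "write_sbml_model",
    "read_sbml_model",
    "write_sbml_community",
    "read_id_map_tsv",
]

SBO_TRANSPORT = 185
SBO_BIOCHEMICAL = 176


def _key_to_str(key) -> str:
    cid, comp = key
    return f"{cid}@{comp}"


def _str_to_key(s: str):
    cid, comp = s.rsplit("@", 1)
    return (cid, comp)


def model_to_json(model: OrganismModel) -> str:
    doc = {
        "model_id": model.model_id,
        "member_label": model.member_label,
        "provenance": model.provenance,
        "biomass_reaction": model.biomass_reaction,
        "objective": model.objective,
        "reactions": [
            {
                "id": r.id,
                "stoichiometry": {_key_to_str(k): v for k, v in sorted(r.stoichiometry.items())},
                "lower": r.lower,
                "upper": r.upper,
                "transport": r.transport,
            }
            for r in sorted(model.reactions.values(), key=lambda r: r.id)
        ],
    }
    return json.dumps(doc, indent=1, sort_keys=True)


def model_from_json(text: str) -> OrganismModel:
    doc = json.loads(text)
    reactions = {
        r["id"]: ModelReaction(
            id=r["id"],
            stoichiometry={_str_to_key(k): float(v) for k, v in r["stoichiometry"].items()},
            lower=float(r["lower"]),
            upper=float(r["upper"]),
            transport=bool(r["transport"]),
        )
        for r in doc["reactions"]
    }
    return OrganismModel(
        model_id=doc["model_id"],
        member_label=doc["member_label"],
        reactions=reactions,
        biomass_reaction=doc["biomass_reaction"],
        objective=doc["objective"],
        provenance=doc["provenance"],
    )


def write_json_model(model: OrganismModel, path) -> None:
    Path(path).write_text(model_to_json(model))


def read_json_model(path) -> OrganismModel:
    return model_from_json(Path(path).read_text())


# ---------------------------------------------------------------------------
# SBML Level 3 + fbc
# ---------------------------------------------------------------------------


def _check(value, message: str):
    if value is None:
        raise RuntimeError(f"libsbml returned None: {message}")
    if isinstance(value, int) and value != libsbml.LIBSBML_OPERATION_SUCCESS:
        raise RuntimeError(f"libsbml error {value}: {message}")
    return value


def _species_id(cid: str, comp: str) -> str:
    return f"M_{cid}_{comp}"


_SPECIES_RE = re.compile(r"^M_(.+)_([^_]+)$")


def write_sbml_model(model: OrganismModel, path) -> None:
    ns = libsbml.SBMLNamespaces(3, 1, "fbc", 2)
    doc = libsbml.SBMLDocument(ns)
    doc.setPackageRequired("fbc", False)
    sbml_model = doc.createModel()
    _check(sbml_model.setId(model.model_id), "model id")
    _check(sbml_model.setName(model.member_label), "model name")
    mplug = sbml_model.getPlugin("fbc")
    mplug.setStrict(True)

    notes = (
        '<notes><body xmlns="http://www.w3.org/1999/xhtml">'
        f"<p>provenance: {model.provenance}</p>"
        f"<p>biomass: {model.biomass_reaction}</p>"
        "</body></notes>"
    )
    _check(sbml_model.setNotes(notes), "model notes")

    comps = sorted({comp for _, comp in model.compounds})
    for comp in comps:
        c = sbml_model.createCompartment()
        c.setId(comp)
        c.setConstant(True)
        c.setSize(1.0)

    for cid, comp in sorted(model.compounds):
        s = sbml_model.createSpecies()
        s.setId(_species_id(cid, comp))
        s.setName(cid)
        s.setCompartment(comp)
        s.setConstant(False)
        s.setBoundaryCondition(False)
        s.setHasOnlySubstanceUnits(False)

    bound_params = {}

    def bound_param(value: float) -> str:
        key = repr(float(value))
        if key not in bound_params:
            pid = f"fb_{len(bound_params)}"
            p = sbml_model.createParameter()
            p.setId(pid)
            p.setValue(float(value))
            p.setConstant(True)
            bound_params[key] = pid
        return bound_params[key]

    for rid in sorted(model.reactions):
        r = model.reactions[rid]
        rxn = sbml_model.createReaction()
        rxn.setId(rid)
        rxn.setFast(False)
        rxn.setReversible(r.lower < 0)
        rxn.setSBOTerm(SBO_TRANSPORT if r.transport else SBO_BIOCHEMICAL)
        for (cid, comp), coeff in sorted(r.stoichiometry.items()):
            if coeff < 0:
                ref = rxn.createReactant()
                ref.setStoichiometry(-float(coeff))
            else:
                ref = rxn.createProduct()
                ref.setStoichiometry(float(coeff))
            ref.setSpecies(_species_id(cid, comp))
            ref.setConstant(True)
        rplug = rxn.getPlugin("fbc")
        rplug.setLowerFluxBound(bound_param(r.lower))
        rplug.setUpperFluxBound(bound_param(r.upper))

    obj = mplug.createObjective()
    obj.setId("obj")
    obj.setType("maximize")
    fo = obj.createFluxObjective()
    fo.setReaction(model.objective)
    fo.setCoefficient(1.0)
    mplug.setActiveObjectiveId("obj")

    writer = libsbml.SBMLWriter()
    if not writer.writeSBMLToFile(doc, str(path)):
        raise RuntimeError(f"could not write SBML to {path}")


def read_sbml_model(path) -> OrganismModel:
    doc = libsbml.readSBMLFromFile(str(path))
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR):
        raise RuntimeError(doc.getErrorLog().toString())
    sbml_model = doc.getModel()
    mplug = sbml_model.getPlugin("fbc")

    species = {}
    for i in range(sbml_model.getNumSpecies()):
        s = sbml_model.getSpecies(i)
        comp = s.getCompartment()
        m = _SPECIES_RE.match(s.getId())
        if not m:
            raise RuntimeError(f"unparseable species id {s.getId()}")
        cid = s.getId()[len("M_"):-(len(comp) + 1)]
        species[s.getId()] = (cid, comp)

    params = {
        sbml_model.getParameter(i).getId(): sbml_model.getParameter(i).getValue()
        for i in range(sbml_model.getNumParameters())
    }

    reactions = {}
    for i in range(sbml_model.getNumReactions()):
        rxn = sbml_model.getReaction(i)
        stoich = {}
        for j in range(rxn.getNumReactants()):
            ref = rxn.getReactant(j)
            key = species[ref.getSpecies()]
            stoich[key] = stoich.get(key, 0.0) - ref.getStoichiometry()
        for j in range(rxn.getNumProducts()):
            ref = rxn.getProduct(j)
            key = species[ref.getSpecies()]
            stoich[key] = stoich.get(key, 0.0) + ref.getStoichiometry()
        rplug = rxn.getPlugin("fbc")
        lower = params[rplug.getLowerFluxBound()]
        upper = params[rplug.getUpperFluxBound()]
        reactions[rxn.getId()] = ModelReaction(
            id=rxn.getId(),
            stoichiometry=stoich,
            lower=lower,
            upper=upper,
            transport=rxn.getSBOTerm() == SBO_TRANSPORT,
        )

    notes = sbml_model.getNotesString() if sbml_model.isSetNotes() else ""
    prov_m = re.search(r"provenance:\s*(\w+)", notes)
    bio_m = re.search(r"biomass:\s*([\w]+)", notes)
    objective = None
    active = mplug.getActiveObjective() if mplug is not None else None
    if active is not None and active.getNumFluxObjectives():
        objective = active.getFluxObjective(0).getReaction()
    biomass = bio_m.group(1) if bio_m else objective
    return OrganismModel(
        model_id=sbml_model.getId(),
        member_label=sbml_model.getName(),
        reactions=reactions,
        biomass_reaction=biomass,
        objective=objective if objective is not None else biomass,
        provenance=prov_m.group(1) if prov_m else "reference",
    )


def write_sbml_community(community, path) -> None:
    """Write a merged community model as SBML Level 3 + fbc.

    Compartments are the member-specific internals (``c1``..``cn``) plus the
    shared extracellular pool (``e0``); the objective sums the member
    biomass fluxes.
    """
    ns = libsbml.SBMLNamespaces(3, 1, "fbc", 2)
    doc = libsbml.SBMLDocument(ns)
    doc.setPackageRequired("fbc", False)
    sbml_model = doc.createModel()
    _check(sbml_model.setId("community"), "model id")
    mplug = sbml_model.getPlugin("fbc")
    mplug.setStrict(True)

    comps = sorted({comp for _, comp in community.compounds})
    for comp in comps:
        c = sbml_model.createCompartment()
        c.setId(comp)
        c.setConstant(True)
        c.setSize(1.0)

    for cid, comp in sorted(community.compounds):
        s = sbml_model.createSpecies()
        s.setId(_species_id(cid, comp))
        s.setName(cid)
        s.setCompartment(comp)
        s.setConstant(False)
        s.setBoundaryCondition(False)
        s.setHasOnlySubstanceUnits(False)

    bound_params = {}

    def bound_param(value: float) -> str:
        key = repr(float(value))
        if key not in bound_params:
            pid = f"fb_{len(bound_params)}"
            p = sbml_model.createParameter()
            p.setId(pid)
            p.setValue(float(value))
            p.setConstant(True)
            bound_params[key] = pid
        return bound_params[key]

    for rid in sorted(community.reactions):
        r = community.reactions[rid]
        rxn = sbml_model.createReaction()
        rxn.setId(rid)
        rxn.setFast(False)
        rxn.setReversible(r.lower < 0)
        rxn.setSBOTerm(SBO_TRANSPORT if r.transport else SBO_BIOCHEMICAL)
        for (cid, comp), coeff in sorted(r.stoichiometry.items()):
            if coeff < 0:
                ref = rxn.createReactant()
                ref.setStoichiometry(-float(coeff))
            else:
                ref = rxn.createProduct()
                ref.setStoichiometry(float(coeff))
            ref.setSpecies(_species_id(cid, comp))
            ref.setConstant(True)
        rplug = rxn.getPlugin("fbc")
        rplug.setLowerFluxBound(bound_param(r.lower))
        rplug.setUpperFluxBound(bound_param(r.upper))

    obj = mplug.createObjective()
    obj.setId("obj")
    obj.setType("maximize")
    for rid in community.objective_reactions:
        fo = obj.createFluxObjective()
        fo.setReaction(rid)
        fo.setCoefficient(1.0)
    mplug.setActiveObjectiveId("obj")

    writer = libsbml.SBMLWriter()
    if not writer.writeSBMLToFile(doc, str(path)):
        raise RuntimeError(f"could not write SBML to {path}")


def read_id_map_tsv(path) -> dict:
    """Read a two-column metabolite-ID mapping TSV (compound id -> external
    id; empty or missing external id means unmappable)."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    cols = list(df.columns)
    if len(cols) < 2:
        raise ValueError("id map TSV needs two columns: compound id, external id")
    return {
        str(row[cols[0]]): (str(row[cols[1]]) or None)
        for _, row in df.iterrows()
    }
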
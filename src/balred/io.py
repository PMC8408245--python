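"""Reading and writing models, kinetics tables and reports.

Canonical ingestion paths: SBML Level 3 (fbc bounds and objective honoured)
or a plain-text reaction table (TSV with columns ``reaction_id``,
``substrate_side``, ``product_side``, ``lb``, ``ub``, ``reversible`` and an
optional ``rate_constant``; sides are written like ``"2 A + 1 E"`` and an
empty side denotes the empty complex).  Mass-action rate constants can also
come from a two-column TSV keyed by reaction id.
"""

from __future__ import annotations

import json
import logging
import math
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .network import (
    NetworkModel,
    ReactionSpec,
    SpeciesRecord,
    complex_label,
    parse_side,
)
from .reduction import MassActionKinetics, ReductionResult

__all__ = [
    "read_reaction_table",
    "write_reaction_table",
    "read_kinetics",
    "write_kinetics",
    "read_sbml",
    "write_sbml",
    "write_balanced_report",
    "write_reduction_report",
]

logger = logging.getLogger(__name__)

_FLOAT_FMT = "%.17g"


def _fmt(x: float) -> str:
    return _FLOAT_FMT % x


# ---------------------------------------------------------------------------
# reaction tables
# ---------------------------------------------------------------------------

def read_reaction_table(path) -> list[ReactionSpec]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"reaction_id", "substrate_side", "product_side", "lb", "ub", "reversible"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"reaction table misses columns: {sorted(missing)}")
    specs = []
    for _, row in df.iterrows():
        k = row.get("rate_constant", "")
        specs.append(
            ReactionSpec(
                id=row["reaction_id"],
                substrates=parse_side(row["substrate_side"]),
                products=parse_side(row["product_side"]),
                lower_bound=float(row["lb"]),
                upper_bound=float(row["ub"]),
                reversible=row["reversible"].strip() in ("1", "true", "True"),
                rate_constant=float(k) if k not in ("", None) else None,
            )
        )
    return specs


def write_reaction_table(model: NetworkModel, path, kinetics: MassActionKinetics | None = None):
    rows = []
    for r in model.reactions:
        sub = model.complexes[r.substrate_complex].composition
        prod = model.complexes[r.product_complex].composition
        rows.append(
            {
                "reaction_id": r.id,
                "substrate_side": _side_string(sub),
                "product_side": _side_string(prod),
                "lb": _fmt(r.lower_bound),
                "ub": _fmt(r.upper_bound),
                "reversible": 0,
                "rate_constant": ""
                if kinetics is None or r.id not in kinetics
                else str(kinetics[r.id]),
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def _side_string(composition: Mapping[str, float]) -> str:
    if not composition:
        return ""
    parts = []
    for sp in sorted(composition):
        c = composition[sp]
        c = int(c) if float(c).is_integer() else c
        parts.append(f"{c} {sp}")
    return " + ".join(parts)


# ---------------------------------------------------------------------------
# kinetics tables
# ---------------------------------------------------------------------------

def read_kinetics(path, model: NetworkModel | None = None) -> MassActionKinetics:
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    if df.shape[1] < 2:
        raise ValueError("kinetics table needs columns (reaction_id, k)")
    rid_col, k_col = df.columns[:2]
    entries = {}
    for _, row in df.iterrows():
        k = float(row[k_col])
        if not k > 0:
            raise ValueError(f"non-positive rate constant for {row[rid_col]!r}: {k}")
        entries[str(row[rid_col])] = k
    kin = MassActionKinetics(entries)
    if model is not None:
        unmatched = [rid for rid in entries if rid not in set(model.reaction_ids())]
        if unmatched:
            raise KeyError(f"kinetics ids not in model: {unmatched}")
        kin.validate_against(model)
    return kin


def write_kinetics(kinetics: MassActionKinetics, path):
    rows = [
        {"reaction_id": rid, "k": _fmt(k) if isinstance(k, (int, float)) else str(k)}
        for rid, k in kinetics.constants.items()
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# SBML
# ---------------------------------------------------------------------------

def read_sbml(path) -> tuple[list[ReactionSpec], dict[str, SpeciesRecord], str | None]:
    """Read SBML; returns (reaction specs, species metadata, objective id).

    fbc flux bounds and objective are honoured; without bounds the defaults
    are [0, inf) for irreversible and (-inf, inf) for reversible reactions
    (logged).  Species flagged as boundary conditions are excluded from the
    stoichiometry, which turns pure exchange reactions into edges incident
    to the empty complex.
    """
    import libsbml

    doc = libsbml.readSBMLFromFile(str(path))
    if doc.getModel() is None or doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR) > 0:
        raise IOError(f"cannot read SBML file {path}")
    sbml_model = doc.getModel()

    species_meta = {}
    boundary = set()
    for s in sbml_model.getListOfSpecies():
        species_meta[s.getId()] = SpeciesRecord(
            id=s.getId(), name=s.getName() or "", compartment=s.getCompartment() or ""
        )
        if s.getBoundaryCondition():
            boundary.add(s.getId())

    fbc = sbml_model.getPlugin("fbc")
    objective = None
    if fbc is not None and fbc.getNumObjectives() > 0:
        active = fbc.getActiveObjective() or fbc.getObjective(0)
        if active is not None and active.getNumFluxObjectives() > 0:
            objective = active.getFluxObjective(0).getReaction()

    def parameter_value(pid):
        p = sbml_model.getParameter(pid)
        return p.getValue() if p is not None else None

    specs = []
    for rxn in sbml_model.getListOfReactions():
        subs: dict[str, float] = {}
        prods: dict[str, float] = {}
        for ref, side in [(r, subs) for r in rxn.getListOfReactants()] + [
            (p, prods) for p in rxn.getListOfProducts()
        ]:
            sid = ref.getSpecies()
            if sid in boundary:
                continue
            side[sid] = side.get(sid, 0.0) + (ref.getStoichiometry() or 1.0)
        reversible = rxn.getReversible()
        lb = ub = None
        rfbc = rxn.getPlugin("fbc")
        if rfbc is not None:
            if rfbc.isSetLowerFluxBound():
                lb = parameter_value(rfbc.getLowerFluxBound())
            if rfbc.isSetUpperFluxBound():
                ub = parameter_value(rfbc.getUpperFluxBound())
        rate = None
        kl = rxn.getKineticLaw()
        if kl is not None:
            for param in list(kl.getListOfParameters()) + list(kl.getListOfLocalParameters()):
                if param.getId() == "k":
                    rate = param.getValue()
                elif param.getId() == "LOWER_BOUND" and lb is None:
                    lb = param.getValue()
                elif param.getId() == "UPPER_BOUND" and ub is None:
                    ub = param.getValue()
        if lb is None:
            lb = -math.inf if reversible else 0.0
            logger.warning("reaction %s: missing lower bound, default %s", rxn.getId(), lb)
        if ub is None:
            ub = math.inf
            logger.warning("reaction %s: missing upper bound, default inf", rxn.getId())
        prov = _provenance_from_notes(rxn)
        specs.append(
            ReactionSpec(
                id=rxn.getId(),
                substrates=subs,
                products=prods,
                lower_bound=float(lb),
                upper_bound=float(ub),
                reversible=bool(reversible),
                rate_constant=rate,
                provenance=prov,
            )
        )
    return specs, species_meta, objective


def _provenance_from_notes(rxn) -> tuple:
    notes = rxn.getNotesString() if rxn.isSetNotes() else ""
    marker = "provenance:"
    if marker in notes:
        after = notes.split(marker, 1)[1]
        payload = after.split("<", 1)[0].strip()
        if payload:
            return tuple(payload.split(";"))
    return ()


def write_sbml(
    model: NetworkModel,
    path,
    kinetics: MassActionKinetics | None = None,
) -> None:
    """Write SBML L3v1 + fbc v2; provenance goes to reaction notes and
    numeric mass-action constants become kinetic laws."""
    import libsbml

    ns = libsbml.SBMLNamespaces(3, 1)
    ns.addPackageNamespace("fbc", 2)
    doc = libsbml.SBMLDocument(ns)
    doc.setPackageRequired("fbc", False)
    sm = doc.createModel()
    sm.setId("balred_model")
    mplug = sm.getPlugin("fbc")
    mplug.setStrict(False)

    compartments = sorted({s.compartment or "default" for s in model.species}) or ["default"]
    for cid in compartments:
        c = sm.createCompartment()
        c.setId(cid)
        c.setConstant(True)
        c.setSize(1.0)

    for s in model.species:
        sp = sm.createSpecies()
        sp.setId(s.id)
        if s.name:
            sp.setName(s.name)
        sp.setCompartment(s.compartment or "default")
        sp.setHasOnlySubstanceUnits(False)
        sp.setBoundaryCondition(False)
        sp.setConstant(False)
        sp.setInitialConcentration(1.0)

    def bound_parameter(value: float, tag: str) -> str:
        pid = f"bound_{tag}"
        if sm.getParameter(pid) is None:
            p = sm.createParameter()
            p.setId(pid)
            p.setValue(value)
            p.setConstant(True)
        return pid

    for r in model.reactions:
        rxn = sm.createReaction()
        rxn.setId(r.id)
        rxn.setReversible(False)
        rxn.setFast(False)
        sub = model.complexes[r.substrate_complex].composition
        prod = model.complexes[r.product_complex].composition
        for sid, coeff in sub.items():
            ref = rxn.createReactant()
            ref.setSpecies(sid)
            ref.setStoichiometry(float(coeff))
            ref.setConstant(True)
        for sid, coeff in prod.items():
            ref = rxn.createProduct()
            ref.setSpecies(sid)
            ref.setStoichiometry(float(coeff))
            ref.setConstant(True)
        rplug = rxn.getPlugin("fbc")
        lb_tag = _bound_tag(r.lower_bound)
        ub_tag = _bound_tag(r.upper_bound)
        rplug.setLowerFluxBound(bound_parameter(r.lower_bound, lb_tag))
        rplug.setUpperFluxBound(bound_parameter(r.upper_bound, ub_tag))
        if r.provenance:
            rxn.setNotes(
                f'<body xmlns="http://www.w3.org/1999/xhtml"><p>provenance: '
                f'{";".join(map(str, r.provenance))}</p></body>'
            )
        if kinetics is not None and r.id in kinetics and isinstance(kinetics[r.id], (int, float)):
            kl = rxn.createKineticLaw()
            terms = ["k"] + [
                f"{sid}^{coeff}" if coeff != 1 else sid for sid, coeff in sub.items()
            ]
            math_ast = libsbml.parseL3Formula(" * ".join(terms))
            kl.setMath(math_ast)
            param = kl.createLocalParameter()
            param.setId("k")
            param.setValue(float(kinetics[r.id]))

    if model.objective_reaction is not None:
        obj = mplug.createObjective()
        obj.setId("obj")
        obj.setType("maximize")
        fo = obj.createFluxObjective()
        fo.setReaction(model.objective_reaction)
        fo.setCoefficient(1.0)
        mplug.setActiveObjectiveId("obj")

    if libsbml.writeSBMLToFile(doc, str(path)) != 1:
        raise IOError(f"failed to write SBML to {path}")


def _bound_tag(value: float) -> str:
    if math.isinf(value):
        return "inf" if value > 0 else "minus_inf"
    return ("m" if value < 0 else "") + _fmt(abs(value)).replace(".", "_").replace("+", "").replace("-", "m")


# ---------------------------------------------------------------------------
# reports
# ---------------------------------------------------------------------------

def write_balanced_report(report, path) -> None:
    report.to_frame().to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def write_reduction_report(result: ReductionResult, path) -> None:
    payload = {
        "removed_complexes": result.removed_complexes,
        "removed_species": result.removed_species,
        "rounds": result.rounds,
        "substitutions": [s.to_dict() for s in result.substitutions],
        "flux_map": {
            rid: [[c if isinstance(c, (int, float)) else str(c), orig] for c, orig in terms]
            for rid, terms in result.flux_map.items()
        },
        "reduced": {
            "n_species": result.reduced_model.n_species,
            "n_complexes": result.reduced_model.n_complexes,
            "n_reactions": result.reduced_model.n_reactions,
        },
    }
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
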
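"""Removal of balanced complexes by graph rewiring.

Two removal motifs are implemented for a balanced complex with ``l``
incoming and ``m`` outgoing reactions:

* **single outgoing** (``m = 1``, any kinetics): the ``l + 1`` incident
  reactions are deleted and ``l`` reactions are inserted, one from each
  incoming-neighbour complex to the outgoing-neighbour complex.  The
  outgoing flux is the sum of the incoming fluxes, so every steady-state
  flux distribution of the original network maps onto one of the reduced
  network.

* **mass action** (``m >= 1``): the ``l + m`` incident reactions are
  deleted and ``m * l`` reactions are inserted, one per (incoming source,
  outgoing target) pair, with rate constant ``k_ip * k_jq / sum_q k_jq``.
  The monomial of the removed complex is substituted by a positive linear
  combination of the incoming sources' monomials, so every steady state of
  the mass-action dynamics restricts to a steady state of the reduced
  dynamics.  Rate constants may be opaque symbols; the rescaling then
  builds expression trees.

Loop insertions (incoming neighbour equal to the outgoing neighbour) are
discarded since they do not contribute to the stoichiometric matrix;
parallel duplicates are merged (constants summed) under mass action and
kept as parallel edges under arbitrary kinetics, where merging would
destroy the flux identity map.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import sympy

from .balancing import classify_trivially_balanced, fully_coupled, identify_balanced
from .network import (
    NetworkModel,
    ReactionSpec,
    build_complexes,
    complex_label,
    composition_key,
)
from .preprocess import FluxSpace, flux_space_of

__all__ = [
    "MassActionKinetics",
    "SubstitutionRecord",
    "RemovalStep",
    "ReductionResult",
    "rescale_rate_constant",
    "remove_single_outgoing",
    "remove_mass_action",
    "reduce_network",
]

logger = logging.getLogger(__name__)


class MassActionKinetics:
    """Mass-action rate constants keyed by reaction id.

    The flux of reaction ``i`` with substrate complex ``y(i)`` is
    ``v_i = k_i * x^y(i)`` with ``x^y = prod_j x_j^(y_ji)``.  Constants are
    positive numbers or sympy expressions (symbolic mode).
    """

    def __init__(self, constants: Mapping[str, object]) -> None:
        self.constants = dict(constants)
        for rid, k in self.constants.items():
            if isinstance(k, (int, float)):
                if not k > 0:
                    raise ValueError(f"rate constant of {rid!r} must be positive, got {k}")

    def __getitem__(self, reaction_id: str):
        return self.constants[reaction_id]

    def __contains__(self, reaction_id: str) -> bool:
        return reaction_id in self.constants

    @property
    def is_numeric(self) -> bool:
        return all(isinstance(k, (int, float)) for k in self.constants.values())

    def validate_against(self, model: NetworkModel) -> None:
        missing = [r.id for r in model.reactions if r.id not in self.constants]
        if missing:
            raise KeyError(f"kinetics missing for reactions: {missing}")

    def K(self, model: NetworkModel) -> np.ndarray:
        """Reactions x complexes matrix with k_i at the substrate complex."""
        self.validate_against(model)
        numeric = self.is_numeric
        K = np.zeros((model.n_reactions, model.n_complexes), dtype=float if numeric else object)
        for i, r in enumerate(model.reactions):
            K[i, r.substrate_complex] = self.constants[r.id]
        return K

    @staticmethod
    def phi(model: NetworkModel, x: Mapping[str, float]) -> np.ndarray:
        """Monomial vector over complexes: ``phi_j(x) = prod_s x_s^(y_sj)``."""
        out = np.empty(model.n_complexes)
        for c in model.complexes:
            val = 1.0
            for sp, coeff in c.composition.items():
                val *= x[sp] ** coeff
            out[c.index] = val
        return out

    def rates(self, model: NetworkModel, x: Mapping[str, float]) -> np.ndarray:
        phi = self.phi(model, x)
        return np.array(
            [self.constants[r.id] * phi[r.substrate_complex] for r in model.reactions]
        )


@dataclass(frozen=True)
class SubstitutionRecord:
    """One variable substitution performed by a removal.

    ``kind="flux"``: the removed symbol is the outgoing reaction's flux and
    the expression is the (coefficient-1) sum of incoming fluxes.
    ``kind="monomial"``: the removed symbol is the complex monomial ``x^y``
    and the expression is a positive combination of the incoming sources'
    monomials with coefficients ``k_ip / sum_q k_jq``.
    """

    kind: str
    removed_symbol: str
    expression: tuple[tuple[object, str], ...]

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "removed": self.removed_symbol,
            "expression": [[str(c) if isinstance(c, sympy.Basic) else c, s] for c, s in self.expression],
        }


@dataclass
class RemovalStep:
    """Outcome of removing one balanced complex."""

    model: NetworkModel
    substitution: SubstitutionRecord
    removed_complex: str
    deleted_reactions: list[str]
    #: inserted (or merged-into) reaction id -> [(coefficient, prior reaction id)]
    inserted: dict[str, list[tuple[object, str]]]
    kinetics: MassActionKinetics | None = None


@dataclass
class ReductionResult:
    reduced_model: NetworkModel
    reduced_kinetics: MassActionKinetics | None
    removed_complexes: list[str]
    removed_species: list[str]
    substitutions: list[SubstitutionRecord]
    rounds: list[dict]
    #: reduced reaction id -> [(coefficient, original reaction id)]; maps any
    #: steady-state flux vector of the original model onto the reduced model
    flux_map: dict[str, list[tuple[object, str]]]

    def map_flux(self, v: Mapping[str, float]) -> dict[str, float]:
        """Push a flux vector (by original reaction id) through the reduction."""
        return {
            rid: float(sum(c * v[orig] for c, orig in terms))
            for rid, terms in self.flux_map.items()
        }


def rescale_rate_constant(k_ip, outgoing_constants: Sequence, q: int):
    """Rate constant ``k_ip * k_jq / sum_q k_jq`` of a rewired reaction."""
    if len(outgoing_constants) == 0:
        raise ValueError("no outgoing rate constants")
    total = outgoing_constants[0]
    for k in outgoing_constants[1:]:
        total = total + k
    if isinstance(total, (int, float)) and total == 0:
        raise ZeroDivisionError("outgoing rate constants sum to zero")
    value = k_ip * outgoing_constants[q] / total
    return sympy.simplify(value) if isinstance(value, sympy.Basic) else value


def _incident(model: NetworkModel, j: int):
    incoming = [model.reactions[i] for i in model.incoming(j)]
    outgoing = [model.reactions[i] for i in model.outgoing(j)]
    return incoming, outgoing


def _rebuild(model: NetworkModel, specs: list[ReactionSpec]) -> NetworkModel:
    surviving = {s.id for s in specs}
    objective = model.objective_reaction if model.objective_reaction in surviving else None
    return build_complexes(specs, species_meta=model.species_meta(), objective_reaction=objective)


def _unique_id(base: str, taken: set[str]) -> str:
    rid = base
    n = 1
    while rid in taken:
        n += 1
        rid = f"{base}_{n}"
    return rid


def remove_single_outgoing(model: NetworkModel, complex_index: int) -> RemovalStep:
    """Remove a balanced complex with exactly one outgoing reaction.

    The caller is responsible for having established balancedness; this
    function checks the structural motif only.
    """
    incoming, outgoing = _incident(model, complex_index)
    if len(outgoing) != 1:
        raise ValueError(
            f"complex {model.complexes[complex_index].label!r} has "
            f"{len(outgoing)} outgoing reactions; single-outgoing removal needs exactly 1"
        )
    if not incoming:
        raise ValueError("cannot remove a source complex")
    out = outgoing[0]
    target = out.product_complex
    target_comp = dict(model.complexes[target].composition)
    single_in = len(incoming) == 1

    deleted = [r.id for r in incoming] + [out.id]
    taken = set(model.reaction_ids())
    inserted: dict[str, list[tuple[object, str]]] = {}
    new_specs: list[ReactionSpec] = []
    for r in incoming:
        if r.substrate_complex == target:
            continue  # loop: does not contribute to the stoichiometric matrix
        rid = _unique_id(f"{r.id}__{out.id}", taken)
        taken.add(rid)
        ub = min(r.upper_bound, out.upper_bound) if single_in else r.upper_bound
        new_specs.append(
            ReactionSpec(
                id=rid,
                substrates=dict(model.complexes[r.substrate_complex].composition),
                products=target_comp,
                lower_bound=r.lower_bound,
                upper_bound=ub,
                provenance=r.provenance + out.provenance,
            )
        )
        inserted[rid] = [(1.0, r.id)]

    specs = [s for s in model.reaction_specs() if s.id not in deleted] + new_specs
    record = SubstitutionRecord(
        kind="flux",
        removed_symbol=out.id,
        expression=tuple((1.0, r.id) for r in incoming),
    )
    return RemovalStep(
        model=_rebuild(model, specs),
        substitution=record,
        removed_complex=model.complexes[complex_index].label,
        deleted_reactions=deleted,
        inserted=inserted,
    )


def remove_mass_action(
    model: NetworkModel, kinetics: MassActionKinetics, complex_index: int
) -> RemovalStep:
    """Remove a balanced complex under mass-action kinetics (any ``m >= 1``)."""
    incoming, outgoing = _incident(model, complex_index)
    if not incoming or not outgoing:
        raise ValueError("cannot remove a sink or source complex")
    for r in incoming + outgoing:
        if r.id not in kinetics:
            raise KeyError(f"kinetics missing for incident reaction {r.id!r}")

    out_constants = [kinetics[r.id] for r in outgoing]
    total = out_constants[0]
    for k in out_constants[1:]:
        total = total + k

    deleted = [r.id for r in incoming] + [r.id for r in outgoing]
    constants = {rid: k for rid, k in kinetics.constants.items() if rid not in deleted}

    # merge key -> spec under construction
    surviving = [s for s in model.reaction_specs() if s.id not in deleted]
    by_pair: dict[tuple, str] = {}
    spec_of: dict[str, ReactionSpec] = {}
    inserted: dict[str, list[tuple[object, str]]] = {}
    for s in surviving:
        pair = (composition_key(s.substrates), composition_key(s.products))
        by_pair.setdefault(pair, s.id)
        spec_of[s.id] = s
    taken = set(spec_of)

    for r_in in incoming:
        k_in = kinetics[r_in.id]
        src = r_in.substrate_complex
        src_comp = dict(model.complexes[src].composition)
        for q, r_out in enumerate(outgoing):
            tgt = r_out.product_complex
            if src == tgt:
                continue  # loop insertion discarded
            k_new = rescale_rate_constant(k_in, out_constants, q)
            share = out_constants[q] / total
            pair = (
                composition_key(src_comp),
                composition_key(model.complexes[tgt].composition),
            )
            if pair in by_pair:
                # parallel duplicate: merge by summing constants
                rid = by_pair[pair]
                old = spec_of[rid]
                constants[rid] = constants[rid] + k_new
                spec_of[rid] = ReactionSpec(
                    id=rid,
                    substrates=old.substrates,
                    products=old.products,
                    lower_bound=old.lower_bound,
                    upper_bound=old.upper_bound
                    if math.isinf(old.upper_bound)
                    else old.upper_bound + r_in.upper_bound,
                    provenance=tuple(dict.fromkeys(old.provenance + r_in.provenance + r_out.provenance)),
                )
                inserted.setdefault(rid, []).append((share, r_in.id))
            else:
                rid = _unique_id(f"{r_in.id}__{r_out.id}", taken)
                taken.add(rid)
                by_pair[pair] = rid
                spec_of[rid] = ReactionSpec(
                    id=rid,
                    substrates=src_comp,
                    products=dict(model.complexes[tgt].composition),
                    lower_bound=0.0,
                    upper_bound=r_in.upper_bound,
                    provenance=r_in.provenance + r_out.provenance,
                )
                constants[rid] = k_new
                inserted[rid] = [(share, r_in.id)]

    order = [s.id for s in surviving] + [rid for rid in spec_of if rid not in {s.id for s in surviving}]
    specs = [spec_of[rid] for rid in order]
    label = model.complexes[complex_index].label
    record = SubstitutionRecord(
        kind="monomial",
        removed_symbol=f"x^[{label}]",
        expression=tuple(
            (
                kinetics[r.id] / total
                if isinstance(kinetics[r.id] / total, sympy.Basic)
                else kinetics[r.id] / total,
                f"x^[{model.complexes[r.substrate_complex].label}]",
            )
            for r in incoming
        ),
    )
    return RemovalStep(
        model=_rebuild(model, specs),
        substitution=record,
        removed_complex=label,
        deleted_reactions=deleted,
        inserted=inserted,
        kinetics=MassActionKinetics(constants),
    )


def reduce_network(
    model: NetworkModel,
    kinetics: MassActionKinetics | None = None,
    *,
    mode: str = "arbitrary",
    protect: Iterable[str] = (),
    protect_reactions: Iterable[str] = (),
    tol: float = 1e-9,
    space_factory: Callable[[NetworkModel], FluxSpace] | None = None,
    allow_coupled_outgoing: bool = False,
    max_rounds: int | None = None,
) -> ReductionResult:
    """Iteratively remove balanced complexes until a fixpoint.

    Each round identifies balanced complexes over the current model's flux
    space (``space_factory`` lets callers impose scenario constraints such
    as a biomass floor), then removes the removable ones in deterministic
    order: trivially balanced complexes first, then ascending complex
    index.  No complex containing a protected species, and no complex
    incident to a protected reaction (e.g. the biomass reaction whose flux
    is optimized during FBA), is ever removed.  Under ``mode="arbitrary"``
    only single-outgoing balanced
    complexes are removable (optionally also complexes whose outgoing
    reactions are pairwise fully coupled, an experimental extension);
    under ``mode="massaction"`` any balanced complex with at least one
    incoming and one outgoing reaction is removable.
    """
    if mode not in ("arbitrary", "massaction"):
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "massaction":
        if kinetics is None:
            raise ValueError("mass-action reduction requires kinetics")
        kinetics.validate_against(model)
    protect = set(protect)
    protect_reactions = set(protect_reactions)
    space_factory = space_factory or flux_space_of

    current = model
    current_kin = kinetics
    flux_expr: dict[str, list[tuple[object, str]]] = {
        r.id: [(1.0, r.id)] for r in model.reactions
    }
    substitutions: list[SubstitutionRecord] = []
    removed_complexes: list[str] = []
    rounds: list[dict] = []

    round_no = 0
    while max_rounds is None or round_no < max_rounds:
        round_no += 1
        report = identify_balanced(current, space_factory(current), tol=tol)
        trivial = classify_trivially_balanced(current)
        balanced = sorted(report.balanced_indices)
        order = [j for j in balanced if j in trivial] + [j for j in balanced if j not in trivial]
        keys = [current.complexes[j].key() for j in order]

        removed_this_round: list[str] = []
        for key in keys:
            lookup = {c.key(): c.index for c in current.complexes}
            j = lookup.get(key)
            if j is None:
                continue
            comp = current.complexes[j].composition
            if protect & set(comp):
                continue
            n_in = len(current.incoming(j))
            n_out = len(current.outgoing(j))
            if protect_reactions and any(
                current.reactions[i].id in protect_reactions
                for i in current.incoming(j) + current.outgoing(j)
            ):
                continue
            if n_in == 0 or n_out == 0:
                continue  # became a sink/source through an earlier removal
            if mode == "massaction":
                step = remove_mass_action(current, current_kin, j)
                current_kin = step.kinetics
            else:
                if n_out != 1:
                    if not allow_coupled_outgoing:
                        continue
                    if not _outgoing_fully_coupled(current, space_factory(current), j):
                        continue
                    step = _remove_coupled_outgoing(current, space_factory(current), j)
                else:
                    step = remove_single_outgoing(current, j)
            current = step.model
            substitutions.append(step.substitution)
            removed_complexes.append(step.removed_complex)
            removed_this_round.append(step.removed_complex)
            _compose_flux_map(flux_expr, step)
        rounds.append(
            {
                "round": round_no,
                "removed_complexes": removed_this_round,
                "n_complexes": current.n_complexes,
                "n_species": current.n_species,
                "n_reactions": current.n_reactions,
            }
        )
        if not removed_this_round:
            break

    surviving_species = {s.id for s in current.species}
    removed_species = [s.id for s in model.species if s.id not in surviving_species]
    return ReductionResult(
        reduced_model=current,
        reduced_kinetics=current_kin if mode == "massaction" else None,
        removed_complexes=removed_complexes,
        removed_species=removed_species,
        substitutions=substitutions,
        rounds=rounds,
        flux_map={r.id: flux_expr[r.id] for r in current.reactions},
    )


def _compose_flux_map(flux_expr: dict, step: RemovalStep) -> None:
    """Express inserted reactions' fluxes in original-model coordinates."""
    for rid, terms in step.inserted.items():
        combined: dict[str, object] = {}
        # a merged-into reaction keeps its own prior flux contribution
        for c, orig in flux_expr.get(rid, []):
            combined[orig] = combined.get(orig, 0) + c
        for coef, prior in terms:
            for c, orig in flux_expr[prior]:
                combined[orig] = combined.get(orig, 0) + coef * c
        flux_expr[rid] = [(c, orig) for orig, c in combined.items()]
    for rid in step.deleted_reactions:
        flux_expr.pop(rid, None)


def _outgoing_fully_coupled(model: NetworkModel, space: FluxSpace, j: int) -> bool:
    out = [model.reactions[i].id for i in model.outgoing(j)]
    ref = out[0]
    for other in out[1:]:
        try:
            coupled, _ = fully_coupled(model, space, other, ref)
        except Exception:
            return False
        if not coupled:
            return False
    return True


def _remove_coupled_outgoing(model: NetworkModel, space: FluxSpace, j: int) -> RemovalStep:
    """Experimental: remove a multi-outgoing balanced complex whose outgoing
    reactions are fully coupled, splitting flux by the coupling ratios."""
    incoming, outgoing = _incident(model, j)
    ref = outgoing[0].id
    ratios = []
    for r in outgoing:
        coupled, ratio = fully_coupled(model, space, r.id, ref)
        if not coupled:
            raise ValueError("outgoing reactions are not fully coupled")
        ratios.append(ratio)
    total = sum(ratios)
    shares = [r / total for r in ratios]
    if any(s <= 0 for s in shares):
        raise ValueError("an outgoing reaction carries no flux; cannot split by ratio")
    pseudo = MassActionKinetics(
        {r.id: 1.0 for r in incoming} | {r.id: s for r, s in zip(outgoing, shares)}
    )
    # reuse the mass-action rewiring with the coupling shares as constants
    step = remove_mass_action(model, _pad_kinetics(model, pseudo), j)
    step.kinetics = None
    step.substitution = SubstitutionRecord(
        kind="flux",
        removed_symbol=ref,
        expression=tuple((shares[0], r.id) for r in incoming),
    )
    return step


def _pad_kinetics(model: NetworkModel, kin: MassActionKinetics) -> MassActionKinetics:
    constants = {r.id: kin.constants.get(r.id, 1.0) for r in model.reactions}
    return MassActionKinetics(constants)
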
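"""Model preparation: flux spaces, blocked reactions, FBA, biomass floors.

The central object is the steady-state flux polytope
``S = {v | N v = 0, vmin <= v <= vmax}``, optionally intersected with extra
linear constraints (e.g. the biomass flux pinned near its optimum).  All
linear programs in the package run over such a space.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np

from ._lp import LPResult, clean_bounds, solve_lp
from .network import (
    NetworkModel,
    ReactionSpec,
    SpeciesRecord,
    build_complexes,
    drop_reactions,
    split_reversible,
)

__all__ = [
    "FluxSpace",
    "InfeasibleFluxSpace",
    "UnboundedObjective",
    "flux_space_of",
    "fva",
    "find_blocked_reactions",
    "remove_blocked_reactions",
    "fba_optimum",
    "biomass_floor",
    "PreparedModel",
    "prepare_model",
]

SCENARIOS = ("irreversible", "reversible", "biomass-optimal")

logger = logging.getLogger(__name__)

#: blocked-reaction flux threshold (mmol/gDW/h for metabolic models)
BLOCKED_TOL = 1e-9


class InfeasibleFluxSpace(RuntimeError):
    pass


class UnboundedObjective(RuntimeError):
    pass


@dataclass(frozen=True)
class FluxSpace:
    """The polytope ``{v | N v = 0, vmin <= v <= vmax}`` plus extra constraints.

    ``extra`` is a tuple of ``(coefficients, relation, rhs)`` with relation in
    ``{"=", "<=", ">="}``; coefficients are vectors over reactions.
    """

    N: np.ndarray
    vmin: np.ndarray
    vmax: np.ndarray
    reaction_ids: tuple[str, ...]
    extra: tuple[tuple[np.ndarray, str, float], ...] = ()

    def __post_init__(self):
        if np.any(self.vmin > self.vmax):
            raise ValueError("vmin must be <= vmax element-wise")

    @property
    def n_reactions(self) -> int:
        return self.N.shape[1]

    def with_constraint(self, coeffs: np.ndarray, relation: str, rhs: float) -> "FluxSpace":
        if relation not in ("=", "<=", ">="):
            raise ValueError(f"unknown relation {relation!r}")
        new = self.extra + ((np.asarray(coeffs, dtype=float), relation, float(rhs)),)
        return replace(self, extra=new)

    def _constraint_matrices(self):
        A_eq = [self.N]
        b_eq = [np.zeros(self.N.shape[0])]
        A_ub, b_ub = [], []
        for coeffs, rel, rhs in self.extra:
            if rel == "=":
                A_eq.append(coeffs[None, :])
                b_eq.append([rhs])
            elif rel == "<=":
                A_ub.append(coeffs[None, :])
                b_ub.append([rhs])
            else:  # >=
                A_ub.append(-coeffs[None, :])
                b_ub.append([-rhs])
        A_eq = np.vstack(A_eq)
        b_eq = np.concatenate([np.atleast_1d(b) for b in b_eq])
        if A_ub:
            return A_eq, b_eq, np.vstack(A_ub), np.concatenate([np.atleast_1d(b) for b in b_ub])
        return A_eq, b_eq, None, None

    def optimize(self, c: np.ndarray, sense: str = "min") -> LPResult:
        A_eq, b_eq, A_ub, b_ub = self._constraint_matrices()
        return solve_lp(c, A_eq, b_eq, clean_bounds(self.vmin, self.vmax), A_ub, b_ub, sense)

    def optimize_reaction(self, index: int, sense: str = "min") -> LPResult:
        c = np.zeros(self.n_reactions)
        c[index] = 1.0
        return self.optimize(c, sense)

    def is_feasible(self) -> bool:
        return self.optimize(np.zeros(self.n_reactions), "min").status == "optimal"


def flux_space_of(model: NetworkModel) -> FluxSpace:
    """The steady-state flux space of a model under its own bounds."""
    lo, hi = model.bounds()
    return FluxSpace(N=model.N, vmin=lo, vmax=hi, reaction_ids=tuple(model.reaction_ids()))


def fva(
    space: FluxSpace, indices: list[int] | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Flux variability analysis: per-reaction flux min/max (two LPs each)."""
    idx = list(range(space.n_reactions)) if indices is None else list(indices)
    mins = np.empty(len(idx))
    maxs = np.empty(len(idx))
    for k, i in enumerate(idx):
        for sense, out in (("min", mins), ("max", maxs)):
            res = space.optimize_reaction(i, sense)
            if res.status == "infeasible":
                raise InfeasibleFluxSpace("flux space is infeasible")
            out[k] = math.inf if res.status == "unbounded" else res.objective
            if res.status == "unbounded" and sense == "min":
                out[k] = -math.inf
    return mins, maxs


def find_blocked_reactions(
    model: NetworkModel, space: FluxSpace | None = None, tol: float = BLOCKED_TOL
) -> set[str]:
    """Reactions whose flux magnitude stays below ``tol`` in every steady state."""
    if tol <= 0:
        raise ValueError("tol must be positive")
    space = flux_space_of(model) if space is None else space
    mins, maxs = fva(space)
    ids = model.reaction_ids()
    return {
        ids[i]
        for i in range(space.n_reactions)
        if max(abs(mins[i]), abs(maxs[i])) < tol
    }


def remove_blocked_reactions(
    model: NetworkModel, tol: float = BLOCKED_TOL
) -> tuple[NetworkModel, set[str]]:
    """Drop blocked reactions (and any orphaned complexes/species)."""
    blocked = find_blocked_reactions(model, tol=tol)
    if not blocked:
        return model, blocked
    reduced = drop_reactions(model, blocked)
    logger.info(
        "removed %d blocked reactions (%d complexes, %d species dropped)",
        len(blocked),
        model.n_complexes - reduced.n_complexes,
        model.n_species - reduced.n_species,
    )
    return reduced, blocked


def fba_optimum(
    model: NetworkModel,
    space: FluxSpace | None = None,
    objective_reaction: str | None = None,
) -> float:
    """Flux balance analysis: the LP maximum of the objective flux over S."""
    objective = objective_reaction or model.objective_reaction
    if objective is None:
        raise ValueError("no objective reaction given")
    space = flux_space_of(model) if space is None else space
    res = space.optimize_reaction(model.reaction_position(objective), "max")
    if res.status == "infeasible":
        raise InfeasibleFluxSpace("flux space is infeasible")
    if res.status == "unbounded":
        raise UnboundedObjective(f"objective {objective!r} is unbounded")
    return res.objective


def biomass_floor(
    model: NetworkModel,
    space: FluxSpace | None = None,
    fraction: float = 0.05,
    objective_reaction: str | None = None,
    optimum: float | None = None,
) -> FluxSpace:
    """Constrain the objective flux to at least ``fraction`` of its FBA optimum."""
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must lie in [0, 1]")
    objective = objective_reaction or model.objective_reaction
    if objective is None:
        raise ValueError("no objective reaction given")
    space = flux_space_of(model) if space is None else space
    if optimum is None:
        optimum = fba_optimum(model, space, objective)
    if fraction == 0.0:
        return space
    c = np.zeros(space.n_reactions)
    c[model.reaction_position(objective)] = 1.0
    floored = space.with_constraint(c, ">=", fraction * optimum)
    if not floored.is_feasible():
        raise InfeasibleFluxSpace(
            f"biomass floor {fraction} x {optimum} makes the flux space infeasible"
        )
    return floored


@dataclass
class PreparedModel:
    """A model made ready for balancing analysis.

    ``space_factory`` builds the scenario's flux space for any (possibly
    further reduced) model, so reduction rounds can re-impose scenario
    constraints after rewiring.
    """

    model: NetworkModel
    scenario: str
    blocked: set[str]
    objective: str | None
    optimum: float | None

    def space_factory(self, model: NetworkModel | None = None) -> FluxSpace:
        model = self.model if model is None else model
        space = flux_space_of(model)
        if self.scenario == "biomass-optimal":
            if self.objective is None or self.optimum is None:
                raise ValueError("biomass-optimal scenario needs an objective")
            c = np.zeros(space.n_reactions)
            c[model.reaction_position(self.objective)] = 1.0
            # equality up to a relative slack, so solver noise cannot empty S
            space = space.with_constraint(c, ">=", self.optimum * (1 - 1e-6))
        return space


def prepare_model(
    specs: list[ReactionSpec],
    species_meta: dict[str, SpeciesRecord] | None = None,
    objective: str | None = None,
    scenario: str = "irreversible",
    blocked_tol: float = BLOCKED_TOL,
    normalize_bounds: bool = True,
) -> PreparedModel:
    """Split reversible reactions, drop blocked reactions, fix the scenario.

    Scenarios: ``irreversible`` keeps declared irreversibilities,
    ``reversible`` treats every reaction as reversible (splitting all), and
    ``biomass-optimal`` additionally pins the objective flux at its FBA
    optimum (computed before blocked-reaction removal).
    """
    if scenario not in SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}; choose from {SCENARIOS}")
    mode = "all" if scenario == "reversible" else "keep"
    split = split_reversible(specs, mode=mode, normalize_bounds=normalize_bounds)
    ids = {s.id for s in split}
    if objective is not None and objective not in ids:
        if f"{objective}__fwd" in ids:
            objective = f"{objective}__fwd"
        else:
            raise KeyError(f"objective reaction {objective!r} not found after splitting")
    model = build_complexes(split, species_meta=species_meta, objective_reaction=objective)
    optimum = fba_optimum(model) if objective is not None else None
    model, blocked = remove_blocked_reactions(model, tol=blocked_tol)
    if objective is not None and objective in blocked:
        raise InfeasibleFluxSpace("objective reaction is blocked")
    return PreparedModel(
        model=model, scenario=scenario, blocked=blocked, objective=objective, optimum=optimum
    )
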
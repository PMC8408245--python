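"""Identification and classification of balanced complexes.

A complex ``i`` is *balanced* in a set of steady-state flux distributions
``S`` when its net incident flux ``[A v]_i`` (incoming fluxes count +1,
outgoing -1) is zero for every ``v`` in ``S``.  That holds exactly when
both LPs

    min / max  [A v]_i   s.t.  N v = 0,  vmin <= v <= vmax

attain 0.  Two screening rules avoid LPs: a sink or source complex can
never be balanced in a blocked-free network, and a complex containing a
species that occurs in no other complex is *trivially balanced* (species
balance at steady state forces the complex balance).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .network import NetworkModel
from .preprocess import FluxSpace, flux_space_of

__all__ = [
    "ComplexBalance",
    "BalancedComplexReport",
    "net_flux_bounds",
    "classify_trivially_balanced",
    "identify_balanced",
    "fully_coupled",
    "CoupledUndefined",
]

BALANCE_TOL = 1e-9


class CoupledUndefined(RuntimeError):
    """Reference flux forced to zero in the cone: coupling ratio undefined."""


@dataclass
class ComplexBalance:
    index: int
    label: str
    net_flux_min: float
    net_flux_max: float
    balanced: bool
    labels: set[str] = field(default_factory=set)


@dataclass
class BalancedComplexReport:
    entries: list[ComplexBalance]
    tol: float

    @property
    def balanced_indices(self) -> set[int]:
        return {e.index for e in self.entries if e.balanced}

    @property
    def balanced_labels(self) -> set[str]:
        return {e.label for e in self.entries if e.balanced}

    def entry(self, index: int) -> ComplexBalance:
        return self.entries[index]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "complex_id": [e.index for e in self.entries],
                "composition": [e.label for e in self.entries],
                "net_flux_min": [e.net_flux_min for e in self.entries],
                "net_flux_max": [e.net_flux_max for e in self.entries],
                "balanced": [e.balanced for e in self.entries],
                "labels": [";".join(sorted(e.labels)) for e in self.entries],
            }
        )


def net_flux_bounds(
    model: NetworkModel, space: FluxSpace | None = None, complex_index: int = 0
) -> tuple[float, float]:
    """Min and max of the net flux ``[A v]_i`` over the flux space (two LPs)."""
    space = flux_space_of(model) if space is None else space
    c = model.A[complex_index, :]
    lo = space.optimize(c, "min")
    hi = space.optimize(c, "max")
    for res in (lo, hi):
        if res.status == "infeasible":
            raise RuntimeError("flux space is infeasible")
    lo_val = -math.inf if lo.status == "unbounded" else lo.objective
    hi_val = math.inf if hi.status == "unbounded" else hi.objective
    return lo_val, hi_val


def classify_trivially_balanced(model: NetworkModel) -> set[int]:
    """Complexes containing a species unique to them, with >=1 in and >=1 out reaction."""
    occurrence: dict[str, int] = {}
    for c in model.complexes:
        for sp in c.composition:
            occurrence[sp] = occurrence.get(sp, 0) + 1
    has_in = {r.product_complex for r in model.reactions}
    has_out = {r.substrate_complex for r in model.reactions}
    trivial = set()
    for c in model.complexes:
        if c.index in has_in and c.index in has_out:
            if any(occurrence[sp] == 1 for sp in c.composition):
                trivial.add(c.index)
    return trivial


def identify_balanced(
    model: NetworkModel,
    space: FluxSpace | None = None,
    tol: float = BALANCE_TOL,
    verify_trivial: bool = False,
) -> BalancedComplexReport:
    """Per-complex balance report over the flux space.

    Sink and source complexes are screened out without LPs (they cannot be
    balanced on blocked-free models); trivially balanced complexes are
    flagged without LPs unless ``verify_trivial`` is set.
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    space = flux_space_of(model) if space is None else space
    trivial = classify_trivially_balanced(model)
    has_in = {r.product_complex for r in model.reactions}
    has_out = {r.substrate_complex for r in model.reactions}

    entries = []
    for c in model.complexes:
        labels: set[str] = set()
        j = c.index
        if j not in has_in:
            labels.add("source")
        if j not in has_out:
            labels.add("sink")
        if len(model.outgoing(j)) == 1:
            labels.add("single_outgoing")
        if labels & {"sink", "source"}:
            entries.append(
                ComplexBalance(j, c.label, math.nan, math.nan, balanced=False, labels=labels)
            )
            continue
        if j in trivial and not verify_trivial:
            labels.add("trivially_balanced")
            entries.append(ComplexBalance(j, c.label, 0.0, 0.0, balanced=True, labels=labels))
            continue
        lo, hi = net_flux_bounds(model, space, j)
        balanced = abs(lo) <= tol and abs(hi) <= tol
        if balanced:
            labels.add("trivially_balanced" if j in trivial else "non_trivially_balanced")
        entries.append(ComplexBalance(j, c.label, lo, hi, balanced=balanced, labels=labels))
    return BalancedComplexReport(entries=entries, tol=tol)


def fully_coupled(
    model: NetworkModel,
    space: FluxSpace | None = None,
    reaction_a: str = "",
    reaction_b: str = "",
    tol: float = 1e-9,
) -> tuple[bool, float | None]:
    """Flux coupling of ``reaction_a`` to ``reaction_b`` on the homogenized cone.

    Bounds are relaxed to ``[0, inf)`` and ``v_b`` is fixed to 1; the pair is
    fully coupled when min and max of ``v_a`` coincide, in which case the
    constant ratio ``v_a / v_b`` is returned.
    """
    space = flux_space_of(model) if space is None else space
    a = model.reaction_position(reaction_a)
    b = model.reaction_position(reaction_b)
    cone = FluxSpace(
        N=space.N,
        vmin=np.zeros(space.n_reactions),
        vmax=np.full(space.n_reactions, math.inf),
        reaction_ids=space.reaction_ids,
    )
    fix = np.zeros(space.n_reactions)
    fix[b] = 1.0
    cone = cone.with_constraint(fix, "=", 1.0)
    c = np.zeros(space.n_reactions)
    c[a] = 1.0
    lo = cone.optimize(c, "min")
    if lo.status == "infeasible":
        raise CoupledUndefined(f"reaction {reaction_b!r} carries no flux in the cone")
    hi = cone.optimize(c, "max")
    if hi.status == "unbounded" or lo.status == "unbounded":
        return False, None
    ratio = 0.5 * (lo.objective + hi.objective)
    coupled = (hi.objective - lo.objective) <= tol * max(1.0, abs(ratio))
    return (coupled, ratio if coupled else None)
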
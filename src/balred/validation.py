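"""Preservation checks and evaluation protocols for reduced models.

The reduction is only useful if it provably keeps the steady-state
phenotypes of the original model: every steady-state flux distribution
must map onto the reduced network, every conservation law (left-null
vector of N) must restrict to one of the reduced network, biomass optima
must match under biomass-protected reduction, and essentiality of shared
reactions must carry over.  This module turns those claims into testable
operations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import null_space

from .network import NetworkModel
from .preprocess import FluxSpace, fba_optimum, flux_space_of, fva
from .reduction import ReductionResult

__all__ = [
    "check_conservation_inclusion",
    "check_steady_state_preserved",
    "compare_fva",
    "compare_essentiality",
    "jaccard",
    "compartment_reduction_stats",
]


def check_conservation_inclusion(
    original: NetworkModel, reduced: NetworkModel, tol: float = 1e-9
) -> tuple[bool, float, np.ndarray | None]:
    """Verify ker(N^T) restricted to surviving species lies in ker(reduced N^T).

    Every conservation law lambda^T x = theta of the original network must
    be a conservation law of the reduced one (removed species occur only in
    removed complexes, so their rows contribute nothing to the reduced
    stoichiometry).  Returns (holds, max residual, witness vector or None).
    """
    basis = null_space(original.N.T)  # columns: left-null vectors of N
    if basis.size == 0 or reduced.N.size == 0:
        return True, 0.0, None
    rows = [original.species_position(s.id) for s in reduced.species]
    restricted = basis[rows, :]
    scale = max(1.0, float(np.max(np.abs(reduced.N)))) * max(
        1.0, float(np.max(np.abs(basis)))
    )
    residuals = np.abs(reduced.N.T @ restricted)
    worst = float(residuals.max()) if residuals.size else 0.0
    if worst <= tol * scale:
        return True, worst, None
    col = int(np.unravel_index(np.argmax(residuals), residuals.shape)[1])
    return False, worst, basis[:, col]


def check_steady_state_preserved(
    model: NetworkModel,
    result: ReductionResult,
    n_samples: int = 50,
    seed: int = 0,
    space: FluxSpace | None = None,
) -> tuple[bool, float]:
    """Map sampled steady-state fluxes through the reduction; check N_red v_red = 0.

    Samples vertices of the original flux space by minimizing random
    objectives (seeded), pushes each flux vector through the reduction's
    flux map and measures the steady-state residual of the reduced model.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    space = flux_space_of(model) if space is None else space
    rng = np.random.default_rng(seed)
    reduced = result.reduced_model
    ids = model.reaction_ids()
    worst = 0.0
    for _ in range(n_samples):
        res = space.optimize(rng.standard_normal(space.n_reactions), "min")
        if res.status == "infeasible":
            raise RuntimeError("original flux space is infeasible")
        if res.status != "optimal":  # random objective unbounded on open polytope
            continue
        v = dict(zip(ids, res.x))
        mapped = result.map_flux(v)
        v_red = np.array([mapped[r.id] for r in reduced.reactions])
        worst = max(worst, float(np.max(np.abs(reduced.N @ v_red))) if v_red.size else 0.0)
    return worst < 1e-9 * max(1.0, float(np.max(np.abs(space.vmax)))), worst


def _fva_at_fraction(model: NetworkModel, fraction: float, indices: list[int]):
    space = flux_space_of(model)
    opt = fba_optimum(model, space)
    c = np.zeros(space.n_reactions)
    c[model.reaction_position(model.objective_reaction)] = 1.0
    space = space.with_constraint(c, ">=", fraction * opt)
    return fva(space, indices), opt


def compare_fva(
    original: NetworkModel,
    reduced: NetworkModel,
    fraction: float = 0.99,
    tol: float = 1e-6,
) -> pd.DataFrame:
    """Per-shared-reaction flux ranges at >= ``fraction`` of optimal biomass.

    Classifies each reaction present in both models as ``same_range``,
    ``wider``, ``narrower`` or ``mixed`` in the reduced model.
    """
    if original.objective_reaction is None or reduced.objective_reaction is None:
        raise ValueError("both models need an objective reaction (use protected reduction)")
    shared = [rid for rid in original.reaction_ids() if rid in set(reduced.reaction_ids())]
    io = [original.reaction_position(r) for r in shared]
    ir = [reduced.reaction_position(r) for r in shared]
    (mins_o, maxs_o), opt_o = _fva_at_fraction(original, fraction, io)
    (mins_r, maxs_r), _ = _fva_at_fraction(reduced, fraction, ir)
    scale = tol * max(1.0, abs(opt_o))
    rows = []
    for k, rid in enumerate(shared):
        lo_same = abs(mins_r[k] - mins_o[k]) <= scale
        hi_same = abs(maxs_r[k] - maxs_o[k]) <= scale
        wider = mins_r[k] <= mins_o[k] + scale and maxs_r[k] >= maxs_o[k] - scale
        narrower = mins_r[k] >= mins_o[k] - scale and maxs_r[k] <= maxs_o[k] + scale
        if lo_same and hi_same:
            cls = "same_range"
        elif wider and not narrower:
            cls = "wider"
        elif narrower and not wider:
            cls = "narrower"
        else:
            cls = "mixed"
        rows.append(
            {
                "reaction": rid,
                "orig_min": mins_o[k],
                "orig_max": maxs_o[k],
                "red_min": mins_r[k],
                "red_max": maxs_r[k],
                "classification": cls,
            }
        )
    return pd.DataFrame(rows)


def _knockout_optimum(model: NetworkModel, reaction_id: str) -> float:
    space = flux_space_of(model)
    i = model.reaction_position(reaction_id)
    vmin = space.vmin.copy()
    vmax = space.vmax.copy()
    vmin[i] = 0.0
    vmax[i] = 0.0
    ko = FluxSpace(N=space.N, vmin=vmin, vmax=vmax, reaction_ids=space.reaction_ids)
    return fba_optimum(model, ko)


def compare_essentiality(
    original: NetworkModel,
    reduced: NetworkModel,
    threshold: float = 0.01,
) -> pd.DataFrame:
    """Single-reaction knockouts in both models.

    A reaction is essential when its knockout drops the FBA optimum below
    ``threshold`` times the wild-type optimum.  Shared reactions are
    compared side by side; reactions introduced by the reduction are
    evaluated in the reduced model only.
    """
    if original.objective_reaction is None or reduced.objective_reaction is None:
        raise ValueError("both models need an objective reaction")
    wt_o = fba_optimum(original)
    wt_r = fba_optimum(reduced)
    shared = [rid for rid in original.reaction_ids() if rid in set(reduced.reaction_ids())]
    introduced = [rid for rid in reduced.reaction_ids() if rid not in set(original.reaction_ids())]
    rows = []
    for rid in shared:
        ko_o = _knockout_optimum(original, rid)
        ko_r = _knockout_optimum(reduced, rid)
        rows.append(
            {
                "reaction": rid,
                "shared": True,
                "essential_original": ko_o < threshold * wt_o,
                "essential_reduced": ko_r < threshold * wt_r,
            }
        )
    for rid in introduced:
        ko_r = _knockout_optimum(reduced, rid)
        rows.append(
            {
                "reaction": rid,
                "shared": False,
                "essential_original": None,
                "essential_reduced": ko_r < threshold * wt_r,
            }
        )
    return pd.DataFrame(rows)


def jaccard(set_a, set_b) -> float:
    """Jaccard similarity |A n B| / |A u B|; two empty sets compare as 1."""
    a, b = set(set_a), set(set_b)
    if not a and not b:
        return 1.0
    return len(a & b) / len(a | b)


def compartment_reduction_stats(
    original: NetworkModel, reduced: NetworkModel
) -> pd.DataFrame:
    """Species counts before/after reduction, per compartment label."""
    surviving = {s.id for s in reduced.species}

    def comp(s):
        return s.compartment or "unassigned"

    labels = sorted({comp(s) for s in original.species})
    rows = []
    for lab in labels:
        before = [s.id for s in original.species if comp(s) == lab]
        after = [sid for sid in before if sid in surviving]
        rows.append(
            {
                "compartment": lab,
                "species_before": len(before),
                "species_after": len(after),
                "percent_removed": 100.0 * (1 - len(after) / len(before)) if before else 0.0,
            }
        )
    return pd.DataFrame(rows)
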
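"""Reference networks, synthetic generators and independent oracles.

Everything here is generated programmatically; the module provides

* a six-species toy network on eight complexes and ten reactions whose
  balanced complexes are {2A, A+E, F, D}, with D the only balanced complex
  having more than one outgoing reaction;
* a seeded generator of random mass-action networks with planted
  trivially balanced complexes and a known positive steady state;
* a brute-force balanced-complex oracle based on vertex enumeration of
  the flux polytope (independent of the LP route);
* a stiff ODE integrator that drives mass-action dynamics to steady state.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp

from .network import NetworkModel, ReactionSpec, build_complexes
from .preprocess import FluxSpace, flux_space_of
from .reduction import MassActionKinetics

__all__ = [
    "toy_network",
    "toy_kinetics",
    "PlantedNetworkSpec",
    "random_mass_action_network",
    "enumerate_vertices",
    "brute_force_balanced",
    "simulate_to_steady_state",
    "SteadyStateNotReached",
]

TOY_UPPER_BOUND = 1000.0

# Edge list of the toy network (substrate side, product side).  The species
# are A-F; complexes 2A, A+E, F and D are balanced, of which D, A+E and F
# are trivially balanced (species D, E, F occur only in them) and 2A is
# non-trivially balanced (A also occurs in A+E).  The incoming neighbourhood
# of 2B is {D, F} and its outgoing neighbourhood is {A+E, F}; C is a sink.
_TOY_EDGES = [
    ("A + E", "2 A"),  # v1
    ("B", "2 A"),      # v2
    ("2 A", "D"),      # v3
    ("D", "2 B"),      # v4
    ("D", "B"),        # v5
    ("B", "D"),        # v6
    ("2 B", "A + E"),  # v7
    ("2 B", "F"),      # v8
    ("F", "2 B"),      # v9
    ("B + C", "C"),    # v10
]


def toy_network() -> NetworkModel:
    """The six-species / eight-complex / ten-reaction worked example."""
    from .network import parse_side

    specs = [
        ReactionSpec(
            id=f"v{k}",
            substrates=parse_side(sub),
            products=parse_side(prod),
            lower_bound=0.0,
            upper_bound=TOY_UPPER_BOUND,
        )
        for k, (sub, prod) in enumerate(_TOY_EDGES, start=1)
    ]
    return build_complexes(specs)


def toy_kinetics(symbolic: bool = True, seed: int | None = None) -> MassActionKinetics:
    """Mass-action constants for the toy network.

    ``symbolic=True`` returns opaque symbols k1..k10.  With a seed, numeric
    constants are planted so that the all-ones concentration vector is a
    steady state of the dynamics (constants equal a strictly positive
    steady-state circulation of the graph).
    """
    if symbolic:
        import sympy

        return MassActionKinetics({f"v{k}": sympy.Symbol(f"k{k}") for k in range(1, 11)})
    rng = np.random.default_rng(0 if seed is None else seed)
    model = toy_network()
    v = _positive_circulation(model, rng)
    # phi(1) = 1 for every complex, so k = v makes x = 1 a steady state
    return MassActionKinetics({r.id: float(v[i]) for i, r in enumerate(model.reactions)})


@dataclass(frozen=True)
class PlantedNetworkSpec:
    """Parameters of the random mass-action generator."""

    n_species: int = 6
    n_complexes: int = 6
    n_reactions: int = 10
    n_planted_trivial: int = 2
    max_stoichiometry: int = 2
    rate_constant_range: tuple[float, float] = (0.1, 10.0)
    include_exchange: bool = True
    upper_bound: float = 1000.0
    seed: int = 0

    def __post_init__(self):
        if self.n_reactions < self.n_complexes:
            raise ValueError("need n_reactions >= n_complexes (cycle construction)")
        if self.n_planted_trivial > self.n_complexes:
            raise ValueError("more planted complexes than complexes")
        if self.max_stoichiometry < 1:
            raise ValueError("max_stoichiometry must be >= 1")
        lo, hi = self.rate_constant_range
        if not (0 < lo <= hi):
            raise ValueError("rate_constant_range must be a positive interval")


def random_mass_action_network(
    spec: PlantedNetworkSpec,
) -> tuple[NetworkModel, MassActionKinetics, dict]:
    """Random network built as a union of directed cycles over random complexes.

    Every reaction lies on a directed cycle of the complex graph, so a
    strictly positive circulation exists (no blocked reactions) and every
    complex has both incoming and outgoing reactions.  Planted complexes
    each receive a private species, making them trivially balanced by
    construction.  Rate constants are planted so that the all-ones
    concentration vector is a steady state (``k = v*`` for a positive
    circulation ``v*`` with log-uniform cycle weights).
    """
    rng = np.random.default_rng(spec.seed)
    base_species = [f"S{i}" for i in range(spec.n_species)]

    compositions: list[dict[str, float]] = []
    seen = set()
    if spec.include_exchange:
        compositions.append({})
        seen.add(())
    guard = 0
    while len(compositions) < spec.n_complexes:
        guard += 1
        if guard > 1000 * spec.n_complexes:
            raise ValueError("cannot build enough distinct complexes; spec impossible")
        size = int(rng.integers(1, 3))
        chosen = rng.choice(spec.n_species, size=size, replace=False)
        comp = {
            base_species[i]: float(rng.integers(1, spec.max_stoichiometry + 1))
            for i in sorted(chosen)
        }
        key = tuple(sorted(comp.items()))
        if key not in seen:
            seen.add(key)
            compositions.append(comp)

    planted = sorted(
        rng.choice(
            [i for i in range(len(compositions)) if compositions[i]],
            size=spec.n_planted_trivial,
            replace=False,
        ).tolist()
    )
    for rank, idx in enumerate(planted):
        compositions[idx][f"U{rank}"] = 1.0  # private species: trivially balanced

    # first cycle visits every complex once (connected, all have in+out edges)
    order = rng.permutation(len(compositions)).tolist()
    edges: list[tuple[int, int]] = [
        (order[i], order[(i + 1) % len(order)]) for i in range(len(order))
    ]
    cycle_weights = [_log_uniform(rng, spec.rate_constant_range)]
    cycle_edges = [list(range(len(edges)))]
    while len(edges) < spec.n_reactions:
        remaining = spec.n_reactions - len(edges)
        if remaining < 2:
            break  # a directed cycle needs >= 2 edges; settle for one reaction fewer
        k_max = min(4, len(compositions), remaining)
        k = int(rng.integers(2, k_max + 1))
        nodes = rng.choice(len(compositions), size=k, replace=False).tolist()
        new = [(nodes[i], nodes[(i + 1) % k]) for i in range(k)]
        cycle_edges.append(list(range(len(edges), len(edges) + len(new))))
        edges.extend(new)
        cycle_weights.append(_log_uniform(rng, spec.rate_constant_range))

    v_star = np.zeros(len(edges))
    for weight, members in zip(cycle_weights, cycle_edges):
        for e in members:
            v_star[e] += weight

    specs = []
    for k, (s, t) in enumerate(edges):
        specs.append(
            ReactionSpec(
                id=f"r{k}",
                substrates=compositions[s],
                products=compositions[t],
                lower_bound=0.0,
                upper_bound=spec.upper_bound,
            )
        )
    model = build_complexes(specs)
    # phi(1) = 1, so constants equal to the circulation plant x = 1 as steady state
    kinetics = MassActionKinetics({f"r{k}": float(v_star[k]) for k in range(len(edges))})
    planted_keys = {tuple(sorted(compositions[i].items())) for i in planted}
    planted_indices = {c.index for c in model.complexes if tuple(sorted(c.composition.items())) in planted_keys}
    info = {
        "planted_trivial": planted_indices,
        "steady_state": {sp.id: 1.0 for sp in model.species},
        "circulation": {f"r{k}": float(v_star[k]) for k in range(len(edges))},
    }
    return model, kinetics, info


def _log_uniform(rng: np.random.Generator, interval: tuple[float, float]) -> float:
    lo, hi = interval
    return float(np.exp(rng.uniform(np.log(lo), np.log(hi))))


def _positive_circulation(model: NetworkModel, rng: np.random.Generator) -> np.ndarray:
    """A strictly positive steady-state flux vector (all fluxes >= 1)."""
    n = model.n_reactions
    _, hi = model.bounds()
    space = FluxSpace(
        N=model.N, vmin=np.ones(n), vmax=hi, reaction_ids=tuple(model.reaction_ids())
    )
    res = space.optimize(rng.uniform(0.5, 1.5, n), "min")
    if res.status != "optimal":
        raise RuntimeError("model admits no strictly positive steady flux")
    return res.x


def enumerate_vertices(space: FluxSpace, max_reactions: int = 14, tol: float = 1e-9) -> np.ndarray:
    """All vertices of the bounded polytope ``{Nv = 0, vmin <= v <= vmax}``.

    Basic-solution enumeration: fix a set of coordinates at their bounds and
    solve the equality system for the rest; a solution within bounds is a
    vertex.  Exponential in the polytope dimension, hence the size guard.
    """
    n = space.n_reactions
    if n > max_reactions:
        raise ValueError(f"vertex enumeration guarded at {max_reactions} reactions (got {n})")
    if not np.all(np.isfinite(space.vmin)) or not np.all(np.isfinite(space.vmax)):
        raise ValueError("vertex enumeration needs finite bounds")
    N = space.N
    r = np.linalg.matrix_rank(N, tol=1e-10)
    d = n - r  # polytope dimension upper bound
    scale = max(1.0, float(np.max(np.abs(space.vmax))), float(np.max(np.abs(space.vmin))))
    vertices: list[np.ndarray] = []
    for free in itertools.combinations(range(n), d):
        basic = [i for i in range(n) if i not in free]
        NB = N[:, basic]
        if basic and np.linalg.matrix_rank(NB, tol=1e-10) < len(basic):
            continue
        for pattern in itertools.product((0, 1), repeat=d):
            v = np.empty(n)
            for i, side in zip(free, pattern):
                v[i] = space.vmin[i] if side == 0 else space.vmax[i]
            rhs = -N[:, list(free)] @ v[list(free)] if d else np.zeros(N.shape[0])
            if basic:
                sol, *_ = np.linalg.lstsq(NB, rhs, rcond=None)
                if np.max(np.abs(NB @ sol - rhs)) > tol * scale:
                    continue
                v[basic] = sol
            if np.any(v < space.vmin - tol * scale) or np.any(v > space.vmax + tol * scale):
                continue
            if np.max(np.abs(N @ v)) > tol * scale:
                continue
            if not any(np.max(np.abs(v - w)) <= 1e-7 * scale for w in vertices):
                vertices.append(v)
    if not vertices:
        raise RuntimeError("polytope appears empty")
    return np.array(vertices)


def brute_force_balanced(
    model: NetworkModel, space: FluxSpace | None = None, tol: float = 1e-6
) -> set[int]:
    """Balanced complexes by exhaustive vertex enumeration (LP-free oracle).

    A complex is balanced iff its net flux ``[Av]_i`` vanishes at every
    vertex of the polytope (linear functionals attain extremes at vertices).
    """
    space = flux_space_of(model) if space is None else space
    V = enumerate_vertices(space)
    net = V @ model.A.T  # vertices x complexes
    scale = max(1.0, float(np.max(np.abs(space.vmax))))
    return {j for j in range(model.n_complexes) if np.max(np.abs(net[:, j])) <= tol * scale}


class SteadyStateNotReached(RuntimeError):
    def __init__(self, residual: float):
        super().__init__(f"no steady state reached; final residual {residual:.3e}")
        self.residual = residual


def simulate_to_steady_state(
    model: NetworkModel,
    kinetics: MassActionKinetics,
    x0: dict[str, float] | np.ndarray,
    tol: float = 1e-10,
    t_max: float = 1e7,
) -> tuple[dict[str, float], float]:
    """Integrate ``dx/dt = N K phi(x)`` until ``||N K phi(x)||_inf < tol``.

    Uses a stiff-capable implicit scheme (BDF) with steady-state detection.
    Returns the steady concentrations keyed by species id and the residual.
    """
    if not kinetics.is_numeric:
        raise ValueError("numeric kinetics required for simulation")
    kinetics.validate_against(model)
    ids = [s.id for s in model.species]
    if isinstance(x0, dict):
        x0 = np.array([x0[i] for i in ids], dtype=float)
    else:
        x0 = np.asarray(x0, dtype=float)
    if np.any(x0 <= 0):
        raise ValueError("initial concentrations must be positive")
    N = model.N

    def rhs(_t, x):
        xv = {i: max(val, 0.0) for i, val in zip(ids, x)}
        return N @ kinetics.rates(model, xv)

    def settled(_t, x):
        # trigger below tol so the returned point passes the strict check
        return float(np.max(np.abs(rhs(_t, x))) - 0.5 * tol)

    settled.terminal = True
    settled.direction = -1

    sol = solve_ivp(
        rhs, (0.0, t_max), x0, method="BDF", events=settled, rtol=1e-10, atol=1e-12
    )
    x = sol.y[:, -1]
    residual = float(np.max(np.abs(rhs(0.0, x))))
    if residual >= tol:
        raise SteadyStateNotReached(residual)
    return {i: float(val) for i, val in zip(ids, x)}, residual


def growth_network() -> NetworkModel:
    """A small growth model with a biomass objective.

    Nutrient A enters via an exchange reaction (capacity 10), is converted
    to biomass precursor C through two parallel two-step routes (via B and
    via P), and can also leak out through a side branch (via D).  The
    biomass reaction consumes C.  Complexes B, P, C and D are trivially
    balanced with a single outgoing reaction; the empty complex is
    non-trivially balanced.
    """
    specs = [
        ReactionSpec(id="uptake", substrates={}, products={"A": 1}, lower_bound=0.0, upper_bound=10.0),
        ReactionSpec(id="r1", substrates={"A": 1}, products={"B": 1}, lower_bound=0.0, upper_bound=1000.0),
        ReactionSpec(id="r2", substrates={"B": 1}, products={"C": 1}, lower_bound=0.0, upper_bound=1000.0),
        ReactionSpec(id="r3", substrates={"A": 1}, products={"P": 1}, lower_bound=0.0, upper_bound=1000.0),
        ReactionSpec(id="r4", substrates={"P": 1}, products={"C": 1}, lower_bound=0.0, upper_bound=1000.0),
        ReactionSpec(id="side", substrates={"A": 1}, products={"D": 1}, lower_bound=0.0, upper_bound=1000.0),
        ReactionSpec(id="export_d", substrates={"D": 1}, products={}, lower_bound=0.0, upper_bound=1000.0),
        ReactionSpec(id="biomass", substrates={"C": 1}, products={}, lower_bound=0.0, upper_bound=1000.0),
    ]
    return build_complexes(specs, objective_reaction="biomass")
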
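"""Reaction networks as directed graphs on complexes.

A biochemical network is represented by three matrices: the composition
matrix ``Y`` (species x complexes, with ``Y[i, j]`` the stoichiometry of
species ``i`` in complex ``j``), the incidence matrix ``A`` (complexes x
reactions, one -1 at the substrate complex and one +1 at the product
complex per column) and the stoichiometric matrix ``N = Y @ A``.

Complexes are the left- and right-hand sides of reactions, deduplicated
by exact composition; the empty complex (all-zero column of ``Y``) is a
first-class node so that exchange reactions fit the one-(-1)-one-(+1)
incidence contract.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "SpeciesRecord",
    "ComplexRecord",
    "ReactionSpec",
    "ReactionRecord",
    "NetworkModel",
    "LoopReactionError",
    "build_complexes",
    "split_reversible",
    "stoichiometric_matrix",
    "drop_reactions",
    "complex_label",
    "parse_side",
    "canonical_signature",
]

#: default upper bound used when a model has no finite upper bound at all
DEFAULT_UPPER_BOUND = 1000.0


class LoopReactionError(ValueError):
    """A reaction whose substrate side equals its product side."""


@dataclass(frozen=True)
class SpeciesRecord:
    id: str
    name: str = ""
    compartment: str = ""


@dataclass(frozen=True)
class ComplexRecord:
    """A complex: a (possibly empty) multiset of species.

    ``composition`` maps species id -> stoichiometric coefficient (> 0);
    the empty complex has an empty map.
    """

    index: int
    composition: Mapping[str, float]

    @property
    def label(self) -> str:
        return complex_label(self.composition)

    def key(self) -> tuple:
        return composition_key(self.composition)


@dataclass(frozen=True)
class ReactionSpec:
    """An input reaction, before complex deduplication and splitting."""

    id: str
    substrates: Mapping[str, float]
    products: Mapping[str, float]
    lower_bound: float = 0.0
    upper_bound: float = math.inf
    reversible: bool = False
    rate_constant: object = None
    provenance: tuple = ()


@dataclass(frozen=True)
class ReactionRecord:
    """An edge of the complex graph: substrate complex -> product complex."""

    id: str
    substrate_complex: int
    product_complex: int
    lower_bound: float = 0.0
    upper_bound: float = math.inf
    provenance: tuple = ()


def complex_label(composition: Mapping[str, float]) -> str:
    if not composition:
        return "0"
    parts = []
    for sp in sorted(composition):
        c = composition[sp]
        c = int(c) if float(c).is_integer() else c
        parts.append(f"{sp}" if c == 1 else f"{c} {sp}")
    return " + ".join(parts)


def composition_key(composition: Mapping[str, float]) -> tuple:
    """Hashable identity of a complex.

    Integer coefficients compare exactly; non-integer ones are rounded to 12
    significant digits so that deduplication stays deterministic.
    """
    items = []
    for sp in sorted(composition):
        c = float(composition[sp])
        if c <= 0:
            raise ValueError(f"non-positive coefficient for {sp!r} in complex")
        items.append((sp, int(c) if c.is_integer() else float(f"{c:.12g}")))
    return tuple(items)


def parse_side(text: str) -> dict[str, float]:
    """Parse a reaction side like ``"2 A + 1 E"`` (empty string = empty complex)."""
    text = text.strip()
    if not text:
        return {}
    side: dict[str, float] = {}
    for term in text.split("+"):
        tokens = term.split()
        if not tokens:
            raise ValueError(f"empty term in side {text!r}")
        if len(tokens) == 1:
            coeff, sp = 1.0, tokens[0]
        elif len(tokens) == 2:
            coeff, sp = float(tokens[0]), tokens[1]
        else:
            raise ValueError(f"cannot parse term {term!r}")
        side[sp] = side.get(sp, 0.0) + coeff
    return side


class NetworkModel:
    """Species, complexes (Y), reactions (A) and the factorization N = YA."""

    def __init__(
        self,
        species: Sequence[SpeciesRecord],
        complexes: Sequence[ComplexRecord],
        reactions: Sequence[ReactionRecord],
        objective_reaction: str | None = None,
    ) -> None:
        self.species = list(species)
        self.complexes = list(complexes)
        self.reactions = list(reactions)
        self.objective_reaction = objective_reaction
        self._species_pos = {s.id: i for i, s in enumerate(self.species)}
        self._reaction_pos = {r.id: i for i, r in enumerate(self.reactions)}
        self._Y = None
        self._A = None
        self._N = None
        self.validate()

    # -- basic accessors -------------------------------------------------
    @property
    def n_species(self) -> int:
        return len(self.species)

    @property
    def n_complexes(self) -> int:
        return len(self.complexes)

    @property
    def n_reactions(self) -> int:
        return len(self.reactions)

    def species_position(self, species_id: str) -> int:
        return self._species_pos[species_id]

    def reaction_position(self, reaction_id: str) -> int:
        return self._reaction_pos[reaction_id]

    def reaction(self, reaction_id: str) -> ReactionRecord:
        return self.reactions[self._reaction_pos[reaction_id]]

    def incoming(self, complex_index: int) -> list[int]:
        """Positions of reactions whose product complex is ``complex_index``."""
        return [i for i, r in enumerate(self.reactions) if r.product_complex == complex_index]

    def outgoing(self, complex_index: int) -> list[int]:
        return [i for i, r in enumerate(self.reactions) if r.substrate_complex == complex_index]

    def reaction_ids(self) -> list[str]:
        return [r.id for r in self.reactions]

    def bounds(self) -> tuple[np.ndarray, np.ndarray]:
        lo = np.array([r.lower_bound for r in self.reactions], dtype=float)
        hi = np.array([r.upper_bound for r in self.reactions], dtype=float)
        return lo, hi

    # -- matrices --------------------------------------------------------
    @property
    def Y(self) -> np.ndarray:
        if self._Y is None:
            Y = np.zeros((self.n_species, self.n_complexes))
            for c in self.complexes:
                for sp, coeff in c.composition.items():
                    Y[self._species_pos[sp], c.index] = coeff
            self._Y = Y
        return self._Y

    @property
    def A(self) -> np.ndarray:
        if self._A is None:
            A = np.zeros((self.n_complexes, self.n_reactions))
            for j, r in enumerate(self.reactions):
                A[r.substrate_complex, j] = -1.0
                A[r.product_complex, j] = 1.0
            self._A = A
        return self._A

    @property
    def N(self) -> np.ndarray:
        if self._N is None:
            self._N = self.Y @ self.A
        return self._N

    # -- integrity -------------------------------------------------------
    def validate(self) -> None:
        if len({s.id for s in self.species}) != self.n_species:
            raise ValueError("duplicate species ids")
        if len(self._reaction_pos) != self.n_reactions:
            raise ValueError("duplicate reaction ids")
        keys = {c.key() for c in self.complexes}
        if len(keys) != self.n_complexes:
            raise ValueError("duplicate complex compositions")
        for i, c in enumerate(self.complexes):
            if c.index != i:
                raise ValueError("complex indices must match list positions")
        used_complexes = set()
        for r in self.reactions:
            if r.substrate_complex == r.product_complex:
                raise LoopReactionError(f"reaction {r.id!r} is a loop")
            if r.lower_bound > r.upper_bound:
                raise ValueError(f"reaction {r.id!r}: lower bound exceeds upper bound")
            used_complexes.update((r.substrate_complex, r.product_complex))
        if self.reactions and used_complexes != set(range(self.n_complexes)):
            raise ValueError("every complex must appear in at least one reaction")
        in_complexes = {sp for c in self.complexes for sp in c.composition}
        if in_complexes != {s.id for s in self.species}:
            raise ValueError("every species must appear in at least one complex")

    # -- structure-returning helpers -------------------------------------
    def reaction_specs(self) -> list[ReactionSpec]:
        """Expand reactions back to substrate/product stoichiometry maps."""
        specs = []
        for r in self.reactions:
            specs.append(
                ReactionSpec(
                    id=r.id,
                    substrates=dict(self.complexes[r.substrate_complex].composition),
                    products=dict(self.complexes[r.product_complex].composition),
                    lower_bound=r.lower_bound,
                    upper_bound=r.upper_bound,
                    provenance=r.provenance,
                )
            )
        return specs

    def species_meta(self) -> dict[str, SpeciesRecord]:
        return {s.id: s for s in self.species}

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"NetworkModel({self.n_species} species, {self.n_complexes} complexes, "
            f"{self.n_reactions} reactions)"
        )


def build_complexes(
    reactions: Iterable[ReactionSpec],
    species_meta: Mapping[str, SpeciesRecord] | None = None,
    objective_reaction: str | None = None,
) -> NetworkModel:
    """Assemble a :class:`NetworkModel` from reaction specifications.

    Complexes are deduplicated by exact composition and indexed in
    first-appearance order over the reaction list.  A reaction whose two
    sides are identical is a loop and is rejected.
    """
    species_meta = dict(species_meta or {})
    complex_of: dict[tuple, int] = {}
    complexes: list[ComplexRecord] = []
    records: list[ReactionRecord] = []
    seen_species: list[str] = []

    def intern(side: Mapping[str, float]) -> int:
        key = composition_key(side)
        if key not in complex_of:
            complex_of[key] = len(complexes)
            complexes.append(ComplexRecord(index=len(complexes), composition=dict(side)))
            for sp in side:
                if sp not in species_meta:
                    species_meta[sp] = SpeciesRecord(id=sp)
                if sp not in seen_species:
                    seen_species.append(sp)
        return complex_of[key]

    for spec in reactions:
        sub = intern(spec.substrates)
        prod = intern(spec.products)
        if sub == prod:
            raise LoopReactionError(
                f"reaction {spec.id!r}: substrate side equals product side "
                f"({complex_label(spec.substrates)})"
            )
        records.append(
            ReactionRecord(
                id=spec.id,
                substrate_complex=sub,
                product_complex=prod,
                lower_bound=spec.lower_bound,
                upper_bound=spec.upper_bound,
                provenance=spec.provenance or (spec.id,),
            )
        )

    species = [species_meta[sp] for sp in seen_species]
    return NetworkModel(species, complexes, records, objective_reaction=objective_reaction)


def split_reversible(
    reactions: Sequence[ReactionSpec],
    mode: str = "keep",
    normalize_bounds: bool = True,
) -> list[ReactionSpec]:
    """Split reversible reactions into irreversible forward/backward pairs.

    ``mode="keep"`` respects the reversibility flags; ``mode="all"`` treats
    every reaction as reversible and splits all of them.  After splitting,
    all lower bounds are set to zero and all upper bounds to the maximum
    finite upper bound of the input model (falling back to
    ``DEFAULT_UPPER_BOUND`` when the model has none).
    """
    if mode not in ("keep", "all"):
        raise ValueError(f"unknown mode {mode!r}")
    finite_ubs = [r.upper_bound for r in reactions if math.isfinite(r.upper_bound) and r.upper_bound > 0]
    big = max(finite_ubs) if finite_ubs else DEFAULT_UPPER_BOUND

    out: list[ReactionSpec] = []
    for r in reactions:
        split = mode == "all" or r.reversible
        if r.reversible and r.lower_bound > 0:
            raise ValueError(
                f"reaction {r.id!r} is flagged reversible but has lower bound "
                f"{r.lower_bound} > 0"
            )
        if not split:
            lb = 0.0 if normalize_bounds else max(r.lower_bound, 0.0)
            ub = big if normalize_bounds else r.upper_bound
            out.append(replace(r, lower_bound=lb, upper_bound=ub, reversible=False))
            continue
        prov = r.provenance or (r.id,)
        out.append(
            ReactionSpec(
                id=f"{r.id}__fwd",
                substrates=dict(r.substrates),
                products=dict(r.products),
                lower_bound=0.0,
                upper_bound=big if normalize_bounds else r.upper_bound,
                reversible=False,
                rate_constant=r.rate_constant,
                provenance=prov + ("fwd",),
            )
        )
        out.append(
            ReactionSpec(
                id=f"{r.id}__bwd",
                substrates=dict(r.products),
                products=dict(r.substrates),
                lower_bound=0.0,
                upper_bound=big if normalize_bounds else abs(r.lower_bound),
                reversible=False,
                rate_constant=None,
                provenance=prov + ("bwd",),
            )
        )
    return out


def stoichiometric_matrix(model: NetworkModel) -> np.ndarray:
    """The stoichiometric matrix ``N = Y @ A`` (species x reactions)."""
    return model.N


def canonical_signature(model: NetworkModel, include_bounds: bool = True) -> tuple:
    """A relabeling-invariant signature: complex compositions plus the edge
    multiset between compositions (optionally with bounds).  Two models with
    equal signatures are isomorphic as complex multigraphs."""
    comps = tuple(sorted(c.key() for c in model.complexes))
    edges = tuple(
        sorted(
            (
                model.complexes[r.substrate_complex].key(),
                model.complexes[r.product_complex].key(),
                (r.lower_bound, r.upper_bound) if include_bounds else (),
            )
            for r in model.reactions
        )
    )
    return comps, edges


def drop_reactions(model: NetworkModel, reaction_ids: Iterable[str]) -> NetworkModel:
    """Remove reactions by id; orphaned complexes and species are dropped."""
    doomed = set(reaction_ids)
    unknown = doomed - set(model.reaction_ids())
    if unknown:
        raise KeyError(f"unknown reaction ids: {sorted(unknown)}")
    specs = [s for s in model.reaction_specs() if s.id not in doomed]
    objective = model.objective_reaction
    if objective in doomed:
        objective = None
    return build_complexes(specs, species_meta=model.species_meta(), objective_reaction=objective)
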
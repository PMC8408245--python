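# Methods

## Model and assumptions

A network is a directed multigraph on *complexes* (multisets of species,
including the empty complex for exchange reactions), with reactions as
edges. With `Y` the species-by-complexes composition matrix and `A` the
complexes-by-reactions incidence matrix (one −1, one +1 per column), the
stoichiometric matrix factors as `N = Y A`. All analyses run after
reversible reactions are split into irreversible pairs (`<id>__fwd` /
`<id>__bwd`), so flux vectors are non-negative. Following standard
constraint-based practice for this pipeline, splitting sets every lower
bound to zero and every upper bound to the maximum finite upper bound of
the input model (falling back to 1000, the common COBRA convention, if the
model has none); reactions whose flux magnitude stays below the blocked
threshold (default 1e-9, the usual numerical-zero for fluxes in
mmol/gDW/h) in every steady state are deleted, together with any orphaned
complexes and species.

Three scenarios fix the flux space `S = {v | Nv = 0, vmin <= v <= vmax}`:
`irreversible` (bounds as declared), `reversible` (every reaction split,
so the space is the full reversible cone within bounds), and
`biomass-optimal`, which adds `v_biomass >= (1 - 1e-6) * optimum`. The
relative slack keeps the constrained polytope numerically non-empty; the
FBA optimum is computed before blocked-reaction removal so that numerical
blocking cannot silently change the optimum. Blocked-reaction analysis
runs after splitting; the ordering is a package choice since both steps
commute for the quantities reported here.

## Balanced complexes

Complex `i` is balanced in `S` iff `min` and `max` of `[Av]_i` over `S`
are both zero; each test is two LPs (HiGHS via scipy). The objective row
is row `i` of `A`, so incoming fluxes count +1 and outgoing −1. The
balance tolerance defaults to 1e-9, symmetric with the blocked threshold;
both |min| and |max| must pass. Screening rules avoid LPs: sinks and
sources are never balanced on blocked-free models, and a complex with at
least one incoming and one outgoing reaction containing a species unique
to it is trivially balanced (the species' steady-state balance *is* the
complex balance). `identify_balanced(..., verify_trivial=True)` re-derives
the screened results by LP; a unit test asserts both routes agree.

Flux coupling (used by the experimental multi-outgoing removal under
arbitrary kinetics) is tested on the homogenized cone — bounds relaxed to
[0, inf), reference flux fixed to 1 — matching standard flux-coupling
practice, rather than on the bounded polytope.

## Removal motifs

*Single outgoing (any kinetics).* For a balanced complex with incoming
reactions `i_1..i_l` and one outgoing reaction to target `t`: delete the
`l + 1` incident reactions, insert one reaction per incoming source
`s_p -> t`. Insertions with `s_p = t` are loops and are dropped (they do
not contribute to `N`). The flux of each inserted reaction equals the flux
of the incoming reaction it replaces, and the deleted outgoing flux is
their sum; the package tracks this as a linear `flux_map` from reduced to
original reaction ids, composed across rounds, so any original
steady-state flux vector can be pushed through the whole reduction and
checked against `N_reduced`. Inserted bounds inherit the incoming
reaction's bounds; when `l = 1` the upper bound is additionally capped by
the outgoing reaction's upper bound. For `l > 1` the outgoing cap cannot
be attributed to a single inserted reaction and is dropped — the reduced
space may admit extra steady states, which is inherent to the method (all
original steady states are preserved; the converse is not claimed).

*Mass action (any `m >= 1`).* With rates `v_i = k_i x^{y(i)}`, balancing
pins the outgoing flux split to the rate-constant ratios, so the complex
is removable even with `m > 1`: delete the `l + m` incident reactions,
insert `m * l` reactions with constants `k_ip * k_jq / sum_q k_jq`, drop
loops, and merge parallel duplicates by summing constants (exactly
preserves the dynamics; under arbitrary kinetics parallel edges are kept
instead, because merging would destroy the flux identity map). The
monomial of the removed complex satisfies
`x^y = sum_p (k_ip / sum_q k_jq) x^{y(i_p)}`, recorded as a substitution;
consequently any steady state of the original dynamics restricts to one of
the reduced dynamics. Constants may be sympy symbols; rescaling then
produces expression trees, and a test checks that substituting numbers
into the symbolic reduction reproduces the numeric reduction.

*Driver.* `reduce_network` iterates rounds: identify balanced complexes on
the current model's scenario flux space, then remove eligible ones in a
deterministic order (trivially balanced first, then ascending index),
re-checking the structural motif before each removal since earlier
removals in the round can change incidence. Balancedness is re-certified
only per round, not per removal — the LPs are the cost driver and the
single-outgoing substitution makes the result order-independent anyway
(verified on fixtures over all removal orders). Complexes containing
protected species, or incident to protected reactions, are never removed;
the biomass-protected experiments protect the objective reaction and the
species of its two complexes.

## Preservation guarantees as checks

* *Flux preservation* (arbitrary-kinetics reductions): sampled vertices of
  the original flux space (LPs with seeded random objectives — cheaper
  than hit-and-run and sufficient for a linear assertion) are pushed
  through `flux_map`; `||N_red v_red||_inf` must stay below 1e-9 times the
  bound scale. Multi-outgoing mass-action removals preserve monomials
  rather than arbitrary polytope fluxes, so for mass-action reductions the
  check is the monomial one below.
* *Monomial preservation* (mass action): at a steady state `x*` of the
  original ODE, the reduced model must satisfy
  `N_red K_red phi_red(x*) = 0` on the surviving species (residual 1e-8).
* *Conservation laws*: every left-null vector of `N`, restricted to
  surviving species, must be a left-null vector of the reduced `N`
  (removed species occur only in removed complexes, so the restriction is
  exact). Null spaces come from SVD with scipy's default rank tolerance;
  residuals are compared at 1e-9 times the matrix scale. The reduced model
  may own additional laws; inclusion is one-way.
* *Growth, FVA, essentiality*: biomass-protected reductions must match the
  original FBA optimum to relative 1e-6; FVA ranges at 99% of the optimum
  are classified per shared reaction (same/wider/narrower/mixed); a
  knockout is essential when it drops the optimum below 1% of wild type —
  the cutoff is a package choice, configurable, since "no growth" needs a
  numerical definition. Knockouts act per reaction id; a split reversible
  direction is knocked out alone.

## Synthetic data

The random generator emulates small mass-action networks with a
non-trivial steady-state flux cone: complexes are random multisets
(stoichiometries up to 2, plus one empty complex for exchange), and the
edge set is a union of directed cycles — the first cycle visits every
complex, so the graph is connected, every complex has in- and out-edges,
and a strictly positive circulation exists (hence no blocked reactions).
Planted complexes receive a private species, making them trivially
balanced by construction, and serve as ground truth. Rate constants are
the circulation itself with log-uniform cycle weights on [0.1, 10] (a
range that spans magnitudes without making the ODEs stiff); since
`phi(1) = 1`, the all-ones concentration vector is then an exact positive
steady state. What the generator does *not* emulate: genome-scale sparsity
patterns, compartments, cofactor coupling, thermodynamic constraints, or
kinetics beyond mass action — passing tests show correctness of the
identification/reduction machinery, not biological realism. The
brute-force oracle enumerates polytope vertices by basic-solution
enumeration (guarded at 14 reactions) and declares a complex balanced iff
its net flux vanishes at every vertex; it shares no code with the LP
route.

The ODE oracle integrates `dx/dt = N K phi(x)` with BDF (rtol 1e-10,
atol 1e-12) and a terminal event at half the requested residual tolerance;
non-convergence by `t_max` raises with the final residual. Trajectories
may legitimately approach boundary steady states (species extinction);
those are still steady states and are accepted.

## Problem sizes and numerics

The test suite and the acceptance script run on the worked example
(10 reactions), a small growth fixture (8 reactions), and batches of
random networks with 8–12 reactions — 100 networks for the LP-vs-oracle
equivalence and 20 for the ODE-based mass-action check, sizes at which the
vertex-enumeration oracle is exact and fast. LP tolerances are HiGHS
defaults; comparisons use absolute thresholds scaled by the bound
magnitude (bounds default to 1000, so a 1e-9 relative criterion becomes
1e-6 absolute in the worst case). Complex identity uses exact comparison
for integer stoichiometries and 12 significant digits otherwise, keeping
deduplication deterministic for fractional biomass coefficients.

## Known limitations

* Bound bookkeeping for inserted reactions is heuristic beyond the
  single-incoming case (see above); the reduced flux space can be a strict
  superset of the image of the original one.
* The multi-outgoing removal under arbitrary kinetics (fully coupled
  outgoing reactions, flux split by coupling ratios) is feature-flagged
  experimental: the flux substitution is well-defined only because full
  coupling pins the ratios, and it is exercised far less than the two main
  motifs.
* Balanced complexes depend on the flux bounds; results are reported per
  scenario and no attempt is made to characterize bound dependence.
* Genome-scale models are supported through SBML + dense linear algebra;
  memory grows with species x reactions, which is acceptable up to a few
  thousand species but not tuned beyond that.
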
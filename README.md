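# balred — network reduction by balanced complexes

`balred` shrinks biochemical reaction networks — from toy mass-action
systems to genome-scale metabolic reconstructions — by detecting and
removing *balanced complexes*, while provably preserving the steady-state
behaviour of the original model. It is aimed at modellers working with
constraint-based (FBA-style) models or mass-action kinetic models who need
smaller models without giving up the flux phenotypes of the original.

## The idea

Write the stoichiometric matrix as `N = Y A`, where `Y` (species x
complexes) holds the composition of each complex — a complex is the
left- or right-hand side of a reaction, e.g. `2 A` or `A + E` — and `A`
(complexes x reactions) is the incidence matrix of the directed graph
whose nodes are complexes and whose edges are reactions.

Given the flux space `S = {v | N v = 0, vmin <= v <= vmax}`, a complex
`i` is **balanced** when its net incident flux `[A v]_i` is zero for every
`v` in `S`. This is decided by two linear programs per complex
(`min`/`max [A v]_i` over `S`); complexes containing a species that occurs
nowhere else are *trivially balanced* and need no LP, and sink/source
complexes can never be balanced in a blocked-free network.

A balanced complex can then be removed by rewiring:

* **arbitrary kinetics** — if the complex has one outgoing and `l`
  incoming reactions, delete the `l + 1` incident reactions and connect
  each incoming neighbour directly to the outgoing neighbour. The deleted
  outgoing flux equals the sum of the incoming fluxes, so every
  steady-state flux distribution of the original maps onto the reduced
  network.
* **mass-action kinetics** — for `l` incoming and `m` outgoing reactions,
  insert the `m * l` bipartite reactions with rescaled rate constants
  `k_ip * k_jq / (k_j1 + ... + k_jm)`. The removed complex's monomial
  `x^y` becomes a positive combination of the incoming sources' monomials,
  so every steady state of the original dynamics restricts to one of the
  reduced dynamics. Rate constants may stay symbolic.

Loop edges created by the rewiring are dropped (they do not affect `N`),
removals iterate in rounds until no balanced complex is removable, and a
protected-species/reaction list keeps, e.g., the biomass reaction and its
metabolites intact so growth predictions are unchanged.

## Worked example

The bundled example network has six species A–F, eight complexes and ten
reactions. Write it out and analyse it from the shell:

```sh
python -c "from balred import fixtures, io; m = fixtures.toy_network(); \
    io.write_reaction_table(m, 'toy.tsv'); \
    io.write_kinetics(fixtures.toy_kinetics(symbolic=False, seed=1), 'toy_k.tsv')"
balred balanced toy.tsv --outdir out
```

which prints `4 balanced complexes of 8` and writes `out/balanced.tsv`:

```text
complex_id  composition  net_flux_min  net_flux_max  balanced  labels
0           A + E        0             0             True      single_outgoing;trivially_balanced
1           2 A          0             -0            True      non_trivially_balanced;single_outgoing
2           B            -1000         -0            False
3           D            0             0             True      trivially_balanced
4           2 B          0             1000          False
5           F            0             0             True      single_outgoing;trivially_balanced
6           B + C                                    False     single_outgoing;source
7           C                                        False     sink
```

The balanced complexes are `2 A`, `A + E`, `F` and `D`; the first three
have a single outgoing reaction, while `D` has two. Under arbitrary
kinetics only the single-outgoing ones are removable:

```sh
balred reduce toy.tsv --outdir arb
# removed 3 complexes, 3 species; reduced model: 3 species, 5 complexes, 6 reactions
```

Under mass action, `D` goes too, because the flux ratio of its outgoing
reactions is pinned to the ratio of their rate constants:

```sh
balred reduce toy.tsv --kinetics massaction --kinetics-table toy_k.tsv --outdir ma
# removed 4 complexes, 4 species; reduced model: 2 species, 4 complexes, 3 reactions
```

Each run writes `reduction.json` with the per-round log, the removed
complexes and species, and the substitution maps that express deleted
fluxes (or concentration monomials) in terms of surviving ones.
`balred validate` re-derives the preservation guarantees for a model and
exits non-zero if any fails; `balred simulate` integrates mass-action
dynamics to steady state as an independent check.

The same pipeline runs on SBML files (Level 3 with fbc bounds and
objective): `balred reduce model.xml --scenario biomass-optimal
--protect-biomass --out-model reduced.xml`.

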
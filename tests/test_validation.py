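import numpy as np
import pytest

from balred.fixtures import growth_network
from balred.network import ReactionSpec, SpeciesRecord, build_complexes
from balred.reduction import reduce_network
from balred.validation import (
    check_conservation_inclusion,
    check_steady_state_preserved,
    compare_essentiality,
    compare_fva,
    compartment_reduction_stats,
    jaccard,
)


@pytest.fixture(scope="module")
def protected_growth():
    growth = growth_network()
    res = reduce_network(
        growth, mode="arbitrary", protect={"C"}, protect_reactions={"biomass"}
    )
    return growth, res


class TestJaccard:
    @pytest.mark.parametrize(
        "a, b, expected",
        [
            ({"x", "y"}, {"x", "y"}, 1.0),
            ({"x"}, {"y"}, 0.0),
            ({"a", "b", "c"}, {"b", "c", "d"}, 0.5),
            (set(), set(), 1.0),
        ],
    )
    def test_values(self, a, b, expected):
        assert jaccard(a, b) == pytest.approx(expected)


class TestConservationInclusion:
    def test_zero_removals_identical_null_spaces(self, toy):
        ok, worst, _ = check_conservation_inclusion(toy, toy)
        assert ok and worst == pytest.approx(0.0, abs=1e-12)

    def test_toy_reduction_inclusion(self, toy):
        res = reduce_network(toy, mode="arbitrary")
        ok, worst, witness = check_conservation_inclusion(toy, res.reduced_model)
        assert ok, (worst, witness)

    def test_closed_cycle_collapses_with_inclusion(self):
        # in A -> X -> B -> A every complex is balanced and single-outgoing,
        # so the whole cycle collapses; inclusion holds vacuously at the end
        # and non-vacuously when X alone is removed under protection
        m = build_complexes(
            [
                ReactionSpec(id="ax", substrates={"A": 1}, products={"X": 1}, upper_bound=10),
                ReactionSpec(id="xb", substrates={"X": 1}, products={"B": 1}, upper_bound=10),
                ReactionSpec(id="ba", substrates={"B": 1}, products={"A": 1}, upper_bound=10),
            ]
        )
        full = reduce_network(m, mode="arbitrary")
        assert "X" in full.removed_complexes
        assert check_conservation_inclusion(m, full.reduced_model)[0]

        partial = reduce_network(m, mode="arbitrary", protect={"A", "B"})
        assert partial.removed_complexes == ["X"]
        ok, worst, witness = check_conservation_inclusion(m, partial.reduced_model)
        assert ok, (worst, witness)
        # the conserved total A + X + B restricts to A + B in the reduced model
        assert partial.reduced_model.n_species == 2


class TestSteadyStatePreservation:
    def test_zero_flux_maps_to_zero(self, toy):
        res = reduce_network(toy, mode="arbitrary")
        v0 = {rid: 0.0 for rid in toy.reaction_ids()}
        mapped = res.map_flux(v0)
        assert all(val == 0.0 for val in mapped.values())

    def test_fifty_samples_small_residual(self, toy):
        res = reduce_network(toy, mode="arbitrary")
        ok, worst = check_steady_state_preserved(toy, res, n_samples=50, seed=2)
        assert ok
        assert worst < 1e-9 * 1000  # residual scales with the bound magnitude

    def test_biomass_optimal_vertex_preserved(self, protected_growth):
        growth, res = protected_growth
        from balred.preprocess import fba_optimum, flux_space_of

        space = flux_space_of(growth)
        i = growth.reaction_position("biomass")
        opt = fba_optimum(growth)
        c = np.zeros(space.n_reactions)
        c[i] = 1.0
        res_lp = space.with_constraint(c, ">=", opt).optimize(
            np.ones(space.n_reactions), "min"
        )
        v = dict(zip(growth.reaction_ids(), res_lp.x))
        mapped = res.map_flux(v)
        red = res.reduced_model
        v_red = np.array([mapped[r.id] for r in red.reactions])
        assert np.max(np.abs(red.N @ v_red)) < 1e-9 * 1000
        assert mapped["biomass"] == pytest.approx(v["biomass"])


class TestCompareFva:
    def test_identity_comparison_all_same(self, growth):
        table = compare_fva(growth, growth)
        assert (table["classification"] == "same_range").all()

    def test_shared_core_ranges_unchanged(self, protected_growth):
        growth, res = protected_growth
        table = compare_fva(growth, res.reduced_model)
        assert (table["classification"] == "same_range").all()

    def test_requires_objective(self, toy, growth):
        with pytest.raises(ValueError):
            compare_fva(growth, toy)


class TestCompareEssentiality:
    def test_only_feeding_chain_essential_in_both(self, protected_growth):
        growth, res = protected_growth
        table = compare_essentiality(growth, res.reduced_model)
        shared = table[table["shared"]].set_index("reaction")
        assert bool(shared.loc["uptake", "essential_original"])
        assert bool(shared.loc["uptake", "essential_reduced"])
        assert bool(shared.loc["biomass", "essential_reduced"])

    def test_original_essential_implies_reduced_essential(self, protected_growth):
        growth, res = protected_growth
        table = compare_essentiality(growth, res.reduced_model)
        shared = table[table["shared"]]
        assert (
            ~shared["essential_original"].astype(bool)
            | shared["essential_reduced"].astype(bool)
        ).all()

    def test_lumped_essential_reaction_stays_essential(self):
        # single path A -> X -> biomass: the lump of two essential reactions
        # must itself be essential
        m = build_complexes(
            [
                ReactionSpec(id="up", substrates={}, products={"A": 1}, upper_bound=10),
                ReactionSpec(id="ax", substrates={"A": 1}, products={"X": 1}, upper_bound=100),
                ReactionSpec(id="xc", substrates={"X": 1}, products={"C": 1}, upper_bound=100),
                ReactionSpec(id="biomass", substrates={"C": 1}, products={}, upper_bound=100),
            ],
            objective_reaction="biomass",
        )
        res = reduce_network(m, mode="arbitrary", protect={"C"}, protect_reactions={"biomass"})
        table = compare_essentiality(m, res.reduced_model)
        introduced = table[~table["shared"]]
        assert (introduced["essential_reduced"].astype(bool)).all()


class TestCompartmentStats:
    def test_single_compartment_equals_global(self, toy):
        res = reduce_network(toy, mode="arbitrary")
        stats = compartment_reduction_stats(toy, res.reduced_model)
        assert len(stats) == 1
        expected = 100.0 * len(res.removed_species) / toy.n_species
        assert stats["percent_removed"].iloc[0] == pytest.approx(expected)

    def test_no_removals_zero_everywhere(self, growth):
        stats = compartment_reduction_stats(growth, growth)
        assert (stats["percent_removed"] == 0.0).all()

    def test_extracellular_chain_fully_removed(self):
        meta = {
            "Aex": SpeciesRecord(id="Aex", compartment="e"),
            "Xex": SpeciesRecord(id="Xex", compartment="e"),
            "A": SpeciesRecord(id="A", compartment="c"),
        }
        m = build_complexes(
            [
                ReactionSpec(id="supply", substrates={}, products={"Aex": 1}, upper_bound=10),
                ReactionSpec(id="t1", substrates={"Aex": 1}, products={"Xex": 1}, upper_bound=10),
                ReactionSpec(id="t2", substrates={"Xex": 1}, products={"A": 1}, upper_bound=10),
                ReactionSpec(id="drain", substrates={"A": 1}, products={}, upper_bound=10),
            ],
            species_meta=meta,
        )
        res = reduce_network(m, mode="arbitrary", protect={"A"}, protect_reactions={"drain"})
        stats = compartment_reduction_stats(m, res.reduced_model).set_index("compartment")
        assert stats.loc["e", "percent_removed"] == pytest.approx(100.0)
        assert stats.loc["c", "percent_removed"] == pytest.approx(0.0)
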
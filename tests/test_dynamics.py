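import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dropevo.dynamics import (
    ChemicalSpecies,
    ConfigurationError,
    Droplet,
    Environment,
    InvalidDropletError,
    L_PER_UM3,
    Population,
    Reaction,
    default_reactions,
    default_species,
    incubate,
    osmolarity,
    reaction_rates,
    solute_exchange_rates,
    stability_dt_max,
    step,
    water_exchange_rates,
)

from conftest import amounts_at, uniform_population


class TestOsmolarity:
    def test_50mM_droplet_reads_50mM(self, gly):
        d = Droplet("a", 17.3, amounts_at(17.3, glycylglycine=0.05))
        assert osmolarity(d, [gly]) == pytest.approx(0.05, rel=1e-9)

    def test_pure_water_is_zero(self, gly):
        assert osmolarity(Droplet("w", 30.0), [gly]) == 0.0

    def test_hand_computed_amount_and_volume(self, gly):
        # V = (4/3)π·30³ µm³ = 1.1309734e-10 L; 5.654867e-12 mol / V
        d = Droplet("a", 30.0, {"glycylglycine": 5.654867e-12})
        v_l = (4.0 / 3.0) * math.pi * 30.0**3 * 1e-15
        assert osmolarity(d, [gly]) == pytest.approx(5.654867e-12 / v_l, rel=1e-12)
        assert osmolarity(d, [gly]) == pytest.approx(0.0500, rel=1e-6)

    def test_inactive_species_do_not_count(self):
        inert = ChemicalSpecies("oilphile", 200.0, osmotically_active=False)
        d = Droplet("a", 10.0, amounts_at(10.0, oilphile=0.1))
        assert osmolarity(d, [inert]) == 0.0

    def test_invalid_radius_rejected(self):
        with pytest.raises(InvalidDropletError):
            Droplet("bad", 0.0)


class TestWaterExchange:
    def test_two_droplet_hand_value(self, gly):
        # A = 4π·900 µm², Π̄ = 0.025, k_w = 1 → ±(0.025 · A)
        a = Droplet("a", 30.0, amounts_at(30.0, glycylglycine=0.05))
        b = Droplet("b", 30.0)
        pop = Population([a, b], [gly], Environment(k_w=1.0))
        rates = water_exchange_rates(pop)
        expected = 0.025 * 4.0 * math.pi * 900.0
        assert rates["a"] == pytest.approx(expected, rel=1e-9)
        assert rates["b"] == pytest.approx(-expected, rel=1e-9)

    def test_identical_osmolarity_gives_exact_zeros(self, gly):
        pop = uniform_population([gly], n=6)
        assert all(v == 0.0 for v in water_exchange_rates(pop).values())

    def test_single_droplet_rate_zero(self, gly):
        pop = Population([Droplet("a", 10.0, amounts_at(10.0, glycylglycine=0.1))],
                         [gly])
        assert water_exchange_rates(pop) == {"a": 0.0}

    def test_rates_sum_to_zero(self, mixed_population):
        rates = np.array(list(water_exchange_rates(mixed_population).values()))
        assert abs(rates.sum()) <= 1e-9 * np.abs(rates).sum()


class TestSoluteExchange:
    def test_trapped_species_never_moves(self, trapped_solute):
        a = Droplet("a", 20.0, amounts_at(20.0, trapped=0.05))
        b = Droplet("b", 20.0)
        pop = Population([a, b], [trapped_solute], Environment())
        assert all(v == 0.0 for v in solute_exchange_rates(pop).values())

    def test_equal_concentrations_give_zero(self, gly):
        pop = uniform_population([gly], n=4)
        assert all(v == 0.0 for v in solute_exchange_rates(pop).values())

    def test_doubling_mw_halves_every_rate(self):
        def build(mw):
            sp = ChemicalSpecies("s", mw)
            drops = [
                Droplet("a", 10.0, amounts_at(10.0, s=0.08)),
                Droplet("b", 15.0, amounts_at(15.0, s=0.02)),
                Droplet("c", 20.0),
            ]
            return Population(drops, [sp], Environment()), sp

        pop1, _ = build(100.0)
        pop2, _ = build(200.0)
        r1 = solute_exchange_rates(pop1)
        r2 = solute_exchange_rates(pop2)
        for (did, _), v in r1.items():
            assert r2[(did, "s")] == pytest.approx(v / 2.0, rel=1e-12)

    def test_per_species_conservation(self, mixed_population):
        rates = solute_exchange_rates(mixed_population)
        total = sum(v for (_, name), v in rates.items() if name == "glycylglycine")
        scale = sum(abs(v) for v in rates.values()) or 1.0
        assert abs(total) <= 1e-9 * scale


class TestReactions:
    def test_zero_rate_constants_give_zero(self):
        species = default_species()
        rxns = default_reactions(k_init=0.0, k_auto=0.0)
        d = Droplet("a", 10.0, amounts_at(10.0, monomer=0.05))
        assert all(v == 0.0 for v in reaction_rates(d, rxns, species).values())

    def test_zero_catalyst_silences_catalytic_channel(self):
        species = default_species()
        auto_only = [default_reactions(k_init=0.0, k_auto=1.0)[1]]
        d = Droplet("a", 10.0, amounts_at(10.0, monomer=0.05))  # no polymer
        assert all(v == 0.0 for v in reaction_rates(d, auto_only, species).values())

    def test_hand_evaluated_mass_action(self):
        # rate1 = k0·[M]², rate2 = ka·[M]·[P]; dn_P/dt = (rate1+rate2)·V_L
        species = default_species()
        rxns = default_reactions(k_init=2e-6, k_auto=3.5e-4)
        r = 10.0
        d = Droplet("a", r, amounts_at(r, monomer=0.05, polymer=0.002))
        v_l = (4.0 / 3.0) * math.pi * r**3 * L_PER_UM3
        rate1 = 2e-6 * 0.05**2
        rate2 = 3.5e-4 * 0.05 * 0.002
        rates = reaction_rates(d, rxns, species)
        assert rates["polymer"] == pytest.approx((rate1 + rate2) * v_l, rel=1e-9)
        assert rates["monomer"] == pytest.approx(-10 * (rate1 + rate2) * v_l, rel=1e-9)

    def test_default_orders_are_stoichiometric(self):
        # without an orders override, 2 A → B is second order in A
        sp = [ChemicalSpecies("A", 50.0), ChemicalSpecies("B", 100.0)]
        rxn = Reaction({"A": 2}, {"B": 1}, rate_constant=3.0)
        d = Droplet("a", 10.0, amounts_at(10.0, A=0.1))
        v_l = (4.0 / 3.0) * math.pi * 1000.0 * L_PER_UM3
        rates = reaction_rates(d, [rxn], sp)
        assert rates["B"] == pytest.approx(3.0 * 0.1**2 * v_l, rel=1e-12)

    def test_unknown_species_is_configuration_error(self):
        sp = [ChemicalSpecies("A", 50.0)]
        rxn = Reaction({"A": 2}, {"ghost": 1}, rate_constant=1.0)
        d = Droplet("a", 10.0, amounts_at(10.0, A=0.1))
        with pytest.raises(ConfigurationError, match="ghost"):
            reaction_rates(d, [rxn], sp)

    def test_mass_imbalance_rejected(self):
        sp = {s.name: s for s in default_species()}
        bad = Reaction({"monomer": 9}, {"polymer": 1}, rate_constant=1.0)
        with pytest.raises(ConfigurationError, match="mass"):
            bad.validate(sp)

    def test_reaction_conserves_monomer_equivalent_mass(self):
        species = default_species()
        d = Droplet("a", 10.0, amounts_at(10.0, monomer=0.05, polymer=0.001))
        rates = reaction_rates(d, default_reactions(), species)
        mw = {s.name: s.molecular_weight for s in species}
        mass_rate = sum(rates[n] * mw[n] for n in rates)
        scale = sum(abs(rates[n]) * mw[n] for n in rates)
        assert abs(mass_rate) <= 1e-9 * scale


class TestStep:
    def test_fixed_point_without_gradients(self, gly):
        pop = uniform_population([gly], n=4, radius=25.0)
        out = step(pop, 5.0)
        np.testing.assert_array_equal(out.radius, pop.radius)
        np.testing.assert_array_equal(out.amounts, pop.amounts)
        assert out.time == pop.time + 5.0

    def test_dt_above_stability_bound_rejected(self, mixed_population):
        bound = stability_dt_max(mixed_population)
        with pytest.raises(ValueError, match="stability"):
            step(mixed_population, bound * 2)

    def test_nonpositive_dt_rejected(self, mixed_population):
        with pytest.raises(ValueError):
            step(mixed_population, 0.0)

    def test_volume_and_species_conserved_over_many_steps(self, mixed_population):
        pop = mixed_population
        v0 = pop.volumes.sum()
        n0 = pop.amounts.sum(axis=0)
        for _ in range(2000):
            pop = step(pop, 2.0)
        assert not pop.extinct_log
        assert abs(pop.volumes.sum() - v0) <= 1e-9 * v0
        np.testing.assert_allclose(pop.amounts.sum(axis=0), n0, rtol=1e-9)

    def test_extinction_floor_removes_and_logs(self, trapped_solute):
        a = Droplet("keeper", 10.0, amounts_at(10.0, trapped=0.05))
        b = Droplet("doomed", 0.6)
        pop = Population([a, b], [trapped_solute], Environment(k_w=0.05))
        for _ in range(2000):
            pop = step(pop, stability_dt_max(pop))
            if pop.n == 1:
                break
        assert pop.n == 1
        assert pop.ids == ["keeper"]
        assert pop.extinct_log and pop.extinct_log[0]["droplet_id"] == "doomed"
        assert (pop.radius > 0).all()

    def test_dt_refinement_converges(self, gly):
        drops = [
            Droplet("a", 30.0, amounts_at(30.0, glycylglycine=0.05)),
            Droplet("b", 30.0),
            Droplet("c", 28.0, amounts_at(28.0, glycylglycine=0.02)),
        ]

        def run(dt):
            pop = Population([d for d in drops], [gly], Environment())
            final, _ = incubate(pop, 2000.0, dt=dt)
            return final.radius

        r_coarse = run(20.0)
        r_half = run(10.0)
        r_ref = run(2.0)
        assert np.max(np.abs(r_coarse - r_ref) / r_ref) < 0.01
        # halving dt moves the solution toward the reference
        assert np.max(np.abs(r_half - r_ref)) <= np.max(np.abs(r_coarse - r_ref))


class TestIncubate:
    def test_one_dt_duration_gives_two_samples(self, mixed_population):
        _, traj = incubate(mixed_population, 5.0, dt=5.0)
        assert sorted(traj.summary.time_s) == [0.0, 5.0]

    def test_mixed_population_polydispersity_rises(self, mixed_population):
        _, traj = incubate(mixed_population, 5000.0, sample_every=500.0, dt=5.0)
        s = traj.summary.s_over_d.to_numpy()
        assert np.all(np.diff(s) > 0)

    def test_unmixed_population_stays_flat(self, gly):
        pop = uniform_population([gly], n=10, radius=30.0)
        _, traj = incubate(pop, 5000.0, sample_every=500.0, dt=5.0)
        s = traj.summary.s_over_d.to_numpy()
        assert np.all(np.abs(s - s[0]) < 1e-12)

    def test_trajectory_reports_all_droplets(self, mixed_population):
        _, traj = incubate(mixed_population, 100.0, sample_every=50.0, dt=5.0)
        assert set(traj.droplets.droplet_id) == set(mixed_population.ids)
        assert {"time_s", "radius_um", "glycylglycine_mol"} <= set(
            traj.droplets.columns
        )


class TestTwoDropletOracle:
    def test_full_water_transfer_to_trapped_solute_droplet(self, trapped_solute):
        a = Droplet("solute", 30.0, amounts_at(30.0, trapped=0.05))
        b = Droplet("water", 30.0)
        pop = Population([a, b], [trapped_solute], Environment())
        v_total = pop.volumes.sum()
        radii = []
        final, traj = incubate(pop, 200000.0, sample_every=5000.0, dt=40.0)
        solute_r = traj.droplets[traj.droplets.droplet_id == "solute"].radius_um
        assert np.all(np.diff(solute_r.to_numpy()) >= 0)
        assert final.n == 1
        assert final.volumes.sum() == pytest.approx(v_total, rel=0.01)


@st.composite
def small_populations(draw):
    gly = ChemicalSpecies("s", draw(st.floats(50.0, 500.0)))
    n = draw(st.integers(2, 6))
    drops = []
    for i in range(n):
        r = draw(st.floats(5.0, 40.0))
        c = draw(st.floats(0.0, 0.1))
        drops.append(Droplet(f"d{i}", r, amounts_at(r, s=c)))
    k_w = draw(st.floats(0.0, 0.05))
    k_s = draw(st.floats(0.0, 0.005))
    return Population(drops, [gly], Environment(k_w=k_w, k_s=k_s))


@settings(max_examples=40, deadline=None)
@given(pop=small_populations(), n_steps=st.integers(1, 50))
def test_property_conservation_under_exchange(pop, n_steps):
    """Exchange only redistributes: totals of volume and solute are invariant."""
    v0 = pop.volumes.sum()
    n0 = pop.amounts.sum()
    for _ in range(n_steps):
        pop = step(pop, 0.5 * stability_dt_max(pop))
    if not pop.extinct_log:
        assert abs(pop.volumes.sum() - v0) <= 1e-9 * v0
    if n0 > 0:
        assert abs(pop.amounts.sum() + _extinct_amount(pop) - n0) <= 1e-9 * n0


def _extinct_amount(pop):
    return sum(float(e["amounts_mol"].sum()) for e in pop.extinct_log)
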
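"""Compartment network construction and deterministic simulation."""

import json

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pgpflux.reference import DEMO_RATES, VACUUM_RATES
from pgpflux.transport import (SPECIES, ObservableParams, PhaseSchedule,
                               PoolTotals, RatePair, ReactionRates,
                               build_reaction_network,
                               end_of_association_amplitude, observable_ru,
                               simulate_timecourse,
                               simulate_timecourse_fixed_step)


def _rand_rates(rng) -> ReactionRates:
    """Moderate random rate set: bimolecular kon 1e-3..1e3, koff 1e-6..1."""
    def pair(kind):
        if kind == "bi":
            return RatePair(10 ** rng.uniform(-3, 3), 10 ** rng.uniform(-6, 0))
        return RatePair(10 ** rng.uniform(-6, -1), 10 ** rng.uniform(-6, 0))

    return ReactionRates(r1=RatePair(0.5, 0.5), r2=pair("bi"), r3=pair("bi"),
                         r4=pair("first"), r5=pair("bi"), r6=pair("first"))


class TestNetwork:
    def test_r4_product_compartment_follows_topology(self):
        rates = DEMO_RATES
        vac = build_reaction_network("vacuum", rates)
        flip = build_reaction_network("flippase", rates)
        sp_v, S_v = vac.stoichiometry()
        sp_f, S_f = flip.stoichiometry()
        r4 = 3
        assert S_v[sp_v.index("S_IN"), r4] == 1
        assert S_v[sp_v.index("LI_FREE"), r4] == 0
        assert S_f[sp_f.index("S_LI"), r4] == 1
        assert S_f[sp_f.index("LI_FREE"), r4] == -1

    @pytest.mark.parametrize("topology", ["vacuum", "flippase"])
    def test_every_reaction_conserves_analyte(self, topology):
        net = build_reaction_network(topology, DEMO_RATES)
        species, S = net.stoichiometry()
        analyte_rows = [species.index(s)
                        for s in ("BULK", "S_SURF", "S_LO", "S_PGP", "S_LI", "S_IN")]
        assert np.all(S[analyte_rows].sum(axis=0) == 0)

    def test_flat_json_export_lists_six_reactions(self):
        doc = json.loads(build_reaction_network("vacuum", DEMO_RATES).to_flat_json())
        assert len(doc["reactions"]) == 6
        assert doc["reactions"][3]["name"].startswith("Pgp transport")
        table = build_reaction_network("vacuum", DEMO_RATES).reaction_table()
        assert list(table["reaction"]) == ["r1", "r2", "r3", "r4", "r5", "r6"]

    def test_invalid_pools_rejected(self):
        with pytest.raises(ValueError):
            PoolTotals(pgp_total=-1)
        with pytest.raises(ValueError):
            build_reaction_network("sideways", DEMO_RATES)


class TestSimulation:
    def test_all_rates_zero_state_constant(self, short_phases):
        net = build_reaction_network(
            "vacuum", ReactionRates(r1=RatePair(0.0, 0.0)))
        traj = simulate_timecourse(net, short_phases, 500e-6, dt=10.0)
        assert np.allclose(traj.states, traj.states[0], atol=1e-18)

    @pytest.mark.parametrize("rates", [DEMO_RATES, VACUUM_RATES["desipramine"]])
    def test_topologies_identical_without_transport(self, rates, short_phases):
        rates = rates.with_value("r4.kon", 0.0).with_value("r4.koff", 0.0)
        grids = {}
        for topo in ("vacuum", "flippase"):
            net = build_reaction_network(topo, rates)
            grids[topo] = simulate_timecourse(net, short_phases, 500e-6, dt=2.0)
        scale = np.max(np.abs(grids["vacuum"].states), axis=0)
        scale[scale == 0] = 1.0
        rel = np.abs(grids["vacuum"].states - grids["flippase"].states) / scale
        assert rel.max() < 1e-10

    def test_pool_conservation_tight(self, short_phases):
        for topo in ("vacuum", "flippase"):
            net = build_reaction_network(topo, DEMO_RATES)
            traj = simulate_timecourse(net, short_phases, 500e-6, dt=2.0,
                                       rtol=1e-10, atol=1e-16)
            err = traj.conservation_error()
            assert max(err.values()) < 1e-9, (topo, err)

    def test_total_analyte_changes_only_through_bulk_exchange(self, short_phases):
        # with the bulk step frozen, the modelled compartments are closed
        rates = DEMO_RATES.with_value("r1.kon", 0.0).with_value("r1.koff", 0.0)
        net = build_reaction_network("vacuum", rates)
        traj = simulate_timecourse(net, short_phases, 500e-6, dt=2.0,
                                   rtol=1e-10, atol=1e-16)
        total = traj.total_analyte
        assert np.allclose(total, total[0], atol=1e-15)

    def test_dissociation_phase_drains_through_r1(self, short_phases):
        net = build_reaction_network("vacuum", DEMO_RATES)
        traj = simulate_timecourse(net, short_phases, 500e-6, dt=2.0)
        post = traj.times > short_phases.association_end
        total = traj.total_analyte[post]
        assert np.all(np.diff(total) <= 1e-12)

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=15, deadline=None)
    def test_states_nonnegative_for_random_rates(self, seed):
        rng = np.random.default_rng(seed)
        phases = PhaseSchedule(300.0, 500.0)
        topo = "vacuum" if seed % 2 == 0 else "flippase"
        net = build_reaction_network(topo, _rand_rates(rng))
        traj = simulate_timecourse(net, phases, 500e-6, dt=5.0,
                                   on_negative="raise")
        assert traj.states.min() >= 0.0

    def test_adaptive_agrees_with_fixed_step_oracle(self, phases):
        # published-style stiff rate set at the full injection schedule
        net = build_reaction_network("vacuum", VACUUM_RATES["desipramine"])
        grid = np.arange(0.0, 2000.1, 4.0)
        a = simulate_timecourse(net, phases, 500e-6, grid=grid,
                                rtol=1e-10, atol=1e-28)
        b = simulate_timecourse_fixed_step(net, phases, 500e-6, grid=grid, dt=0.06)
        scale = np.max(np.abs(a.states), axis=0)
        scale[scale == 0] = 1.0
        assert np.max(np.abs(a.states - b.states) / scale) < 1e-4

    def test_monotone_amplitude_in_injected_concentration(self, short_phases, obs):
        net = build_reaction_network("vacuum", DEMO_RATES)
        amps = []
        for c_um in (31.25, 62.5, 125.0, 250.0, 500.0):
            traj = simulate_timecourse(net, short_phases, c_um * 1e-6, dt=2.0)
            amps.append(end_of_association_amplitude(
                traj.times, observable_ru(traj, obs), short_phases))
        assert np.all(np.diff(amps) >= 0)

    def test_grid_outside_trace_rejected(self, short_phases):
        net = build_reaction_network("vacuum", DEMO_RATES)
        with pytest.raises(ValueError):
            simulate_timecourse(net, short_phases, 1e-6,
                                grid=np.linspace(0, 1e4, 10))


class TestObservable:
    def test_zero_species_gives_baseline(self, short_phases):
        net = build_reaction_network("vacuum", ReactionRates(r1=RatePair(0, 0)))
        traj = simulate_timecourse(net, short_phases, 0.0, dt=10.0)
        ru = observable_ru(traj, ObservableParams(k=1e6, c=7.0))
        assert np.allclose(ru, 7.0)

    def test_zero_scaling_gives_baseline(self, short_phases):
        net = build_reaction_network("vacuum", DEMO_RATES)
        traj = simulate_timecourse(net, short_phases, 500e-6, dt=10.0)
        assert np.allclose(observable_ru(traj, ObservableParams(k=0.0, c=3.0)), 3.0)

    def test_observable_linear_in_species(self, short_phases):
        net = build_reaction_network("vacuum", DEMO_RATES)
        traj = simulate_timecourse(net, short_phases, 500e-6, dt=10.0)
        obs = ObservableParams(k=2e6, c=5.0)
        ru1 = observable_ru(traj, obs)
        traj.states = traj.states * 2.0
        ru2 = observable_ru(traj, obs)
        assert np.allclose(ru2 - obs.c, 2.0 * (ru1 - obs.c))

    def test_amplitude_is_baseline_referenced(self, short_phases):
        t = np.linspace(0.0, 500.0, 101)
        ru = np.full_like(t, 4.0)
        assert end_of_association_amplitude(t, ru, short_phases) == 0.0
        ru2 = 4.0 + 50.0 * (t >= short_phases.association_end - 1e-9).astype(float)
        # step lands exactly at association_end
        ru3 = np.interp(t, [0, short_phases.association_end], [4.0, 54.0])
        assert end_of_association_amplitude(t, ru3, short_phases) == pytest.approx(50.0)

    def test_amplitude_requires_coverage(self):
        phases = PhaseSchedule(1200.0, 2000.0)
        t = np.linspace(0, 800, 81)
        with pytest.raises(ValueError):
            end_of_association_amplitude(t, np.zeros_like(t), phases)
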
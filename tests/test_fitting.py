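"""Global sensorgram fitting, topology comparison and reporting."""

import math

import numpy as np
import pytest

from pgpflux.fitting import (DEFAULT_FREE_PARAMETERS, FitSpec,
                             TransportKinetics, compare_topologies,
                             global_fit, parse_rate_table, rate_table)
from pgpflux.optimize import evolutionary_programming
from pgpflux.reference import DEFAULT_PHASES, DEMO_RATES, VACUUM_RATES
from pgpflux.synth import generate_sensorgram_set
from pgpflux.transport import ObservableParams, PhaseSchedule

FREE3 = ("r2.kon", "r2.koff", "r4.kon")
BOUNDS3 = {n: (-7.0, 3.0) for n in FREE3}


@pytest.fixture(scope="module")
def clean_set():
    """Zero-noise vacuum-topology set, three concentrations, full phases."""
    return generate_sensorgram_set(
        DEMO_RATES, "vacuum", [500.0, 125.0, 31.25],
        observable=ObservableParams(k=1e6, c=10.0),
        phases=DEFAULT_PHASES, dt=4.0)


def _truth_log(free):
    return np.log10([DEMO_RATES.value(n) for n in free])


class TestObjective:
    def test_truth_is_global_minimum_at_zero_noise(self, clean_set):
        spec = FitSpec(topology="vacuum", free_parameters=FREE3,
                       baseline_rates=DEMO_RATES, bounds=BOUNDS3, fit_stride=2)
        model = TransportKinetics(clean_set, spec)
        tss = float(np.sum((model._obs - model._obs.mean(axis=1, keepdims=True)) ** 2))
        assert model.objective(_truth_log(FREE3)) < 1e-9 * tss

    def test_polish_from_truth_leaves_parameters_unchanged(self, clean_set):
        spec = FitSpec(topology="vacuum", free_parameters=FREE3,
                       baseline_rates=DEMO_RATES, bounds=BOUNDS3,
                       optimizer="multi-start-local", population=1,
                       generations=20, initial_rates=DEMO_RATES,
                       fit_stride=4, seed=0)
        res = global_fit(clean_set, spec)
        for n in FREE3:
            assert res.rates.value(n) == pytest.approx(DEMO_RATES.value(n), rel=0.01)

    def test_same_seed_same_result(self, clean_set):
        def run():
            spec = FitSpec(topology="vacuum", free_parameters=FREE3,
                           baseline_rates=DEMO_RATES, bounds=BOUNDS3,
                           optimizer="differential-evolution", population=4,
                           generations=3, refine=False, fit_stride=8, seed=13)
            return global_fit(clean_set, spec)

        a, b = run(), run()
        assert a.rss == b.rss
        for n in FREE3:
            assert a.rates.value(n) == b.rates.value(n)
        assert [(o.k, o.c) for o in a.observables] == [(o.k, o.c) for o in b.observables]

    def test_local_scale_absorbed_by_trace_observables(self, clean_set):
        # doubling one trace's RU only rescales that trace's k and C
        spec = FitSpec(topology="vacuum", free_parameters=FREE3,
                       baseline_rates=DEMO_RATES, bounds=BOUNDS3,
                       optimizer="multi-start-local", population=1,
                       generations=20, refine=False,
                       initial_rates=DEMO_RATES, fit_stride=4, seed=0)
        base = global_fit(clean_set, spec)

        scaled = generate_sensorgram_set(
            DEMO_RATES, "vacuum", [500.0, 125.0, 31.25],
            observable=ObservableParams(k=1e6, c=10.0),
            phases=DEFAULT_PHASES, dt=4.0)
        scaled.traces = scaled.traces.copy()
        scaled.traces[1] *= 3.0
        res = global_fit(scaled, spec)
        for n in FREE3:
            assert res.rates.value(n) == pytest.approx(base.rates.value(n), rel=0.05)
        assert res.observables[1].k == pytest.approx(3.0 * base.observables[1].k, rel=0.05)
        assert res.observables[0].k == pytest.approx(base.observables[0].k, rel=0.05)

    def test_too_few_traces_and_bad_window_rejected(self, clean_set):
        one = generate_sensorgram_set(DEMO_RATES, "vacuum", [500.0],
                                      observable=ObservableParams(k=1e6),
                                      phases=PhaseSchedule(300, 500), dt=20.0)
        with pytest.raises(ValueError, match=">= 2"):
            TransportKinetics(one, FitSpec())
        with pytest.raises(ValueError, match="fit_window"):
            TransportKinetics(clean_set, FitSpec(fit_window=(0.0, 9e4)))


class TestRecovery:
    def test_zero_noise_rates_recovered_within_log_tolerance(self, clean_set):
        """Round-trip identity: generating rates are recovered from their own
        simulated data to within 5% in log space."""
        spec = FitSpec(topology="vacuum", free_parameters=FREE3,
                       baseline_rates=DEMO_RATES, bounds=BOUNDS3,
                       optimizer="differential-evolution", population=8,
                       generations=30, seed=0, fit_stride=2)
        res = global_fit(clean_set, spec)
        assert res.converged
        for n in FREE3:
            if n in res.unidentifiable:
                continue
            log_err = abs(math.log(res.rates.value(n) / DEMO_RATES.value(n)))
            assert log_err < 0.05, n
        # this design leaves all three rates identifiable
        assert res.unidentifiable == ()

    def test_optimizer_history_nonincreasing(self, clean_set):
        spec = FitSpec(topology="vacuum", free_parameters=FREE3,
                       baseline_rates=DEMO_RATES, bounds=BOUNDS3,
                       optimizer="evolutionary", population=6, generations=8,
                       refine=False, fit_stride=8, seed=5)
        res = global_fit(clean_set, spec)
        assert np.all(np.diff(res.history) <= 0)


class TestEvolutionaryProgramming:
    def test_best_so_far_monotone_and_finds_quadratic_minimum(self):
        def f(x):
            return float(np.sum((x - 0.3) ** 2))

        out = evolutionary_programming(f, [(-2, 2)] * 3, population=20,
                                       generations=60, seed=0)
        assert np.all(np.diff(out.history) <= 0)
        assert out.fun < 1e-3
        assert np.allclose(out.x, 0.3, atol=0.1)

    def test_seed_reproducibility(self):
        def f(x):
            return float(np.sum(np.abs(x)) + np.sin(5 * x).sum())

        a = evolutionary_programming(f, [(-3, 3)] * 2, population=10,
                                     generations=20, seed=9)
        b = evolutionary_programming(f, [(-3, 3)] * 2, population=10,
                                     generations=20, seed=9)
        assert a.fun == b.fun and np.array_equal(a.x, b.x)


class TestComparison:
    def test_no_preference_when_transport_absent(self):
        # without the transport step the two topologies are the same model
        rates = DEMO_RATES.with_value("r4.kon", 0.0)
        data = generate_sensorgram_set(rates, "vacuum", [500.0, 125.0],
                                       observable=ObservableParams(k=1e6, c=5.0),
                                       phases=PhaseSchedule(300, 500), dt=4.0)

        def spec(topology):
            return FitSpec(topology=topology, free_parameters=FREE3,
                           baseline_rates=rates, bounds=BOUNDS3,
                           optimizer="multi-start-local", population=1,
                           generations=15, initial_rates=rates, refine=False,
                           fit_window=(0, 500), fit_stride=2, seed=0)

        cmp = compare_topologies(data, spec("vacuum"), spec("flippase"))
        assert cmp.preferred == "none"
        assert cmp.rss_relative_difference < 1e-3

    def test_aicc_difference_reduces_to_rss_ratio(self, clean_set):
        # equi-dimensional fits: delta AICc must equal n*ln(rss ratio)
        def spec(topology):
            return FitSpec(topology=topology, free_parameters=FREE3,
                           baseline_rates=DEMO_RATES, bounds=BOUNDS3,
                           optimizer="differential-evolution", population=4,
                           generations=3, refine=False, fit_stride=8, seed=2)

        cmp = compare_topologies(clean_set, spec("vacuum"), spec("flippase"))
        n = cmp.vacuum.n_obs
        expected = n * math.log(cmp.flippase.rss / cmp.vacuum.rss)
        assert cmp.delta_aicc == pytest.approx(expected, rel=1e-9)
        assert "preferred" in cmp.summary()

    def test_mismatched_dimension_rejected(self, clean_set):
        sv = FitSpec(topology="vacuum", free_parameters=FREE3,
                     baseline_rates=DEMO_RATES, bounds=BOUNDS3)
        sf = FitSpec(topology="flippase", free_parameters=FREE3[:2],
                     baseline_rates=DEMO_RATES)
        with pytest.raises(ValueError, match="equi-dimensional"):
            compare_topologies(clean_set, sv, sf)


class TestRateTable:
    def test_published_style_row_values_and_labels(self):
        table = rate_table(VACUUM_RATES["desipramine"], topology="vacuum")
        row = table[table["description"] == "Pgp transport to inside the proteoliposome"]
        assert row["kon_per_M_s"].item() == pytest.approx(3.57e-5)
        assert row["koff_per_s"].item() == pytest.approx(6.44e-8)
        assert list(table["reaction"]) == ["r2", "r3", "r4", "r5", "r6"]

    def test_roundtrip_through_tsv(self):
        table = rate_table(VACUUM_RATES["quinidine"], topology="vacuum")
        text = table.to_csv(sep="\t", index=False)
        back = parse_rate_table(text, r1=VACUUM_RATES["quinidine"])
        for r in ("r2", "r3", "r4", "r5", "r6"):
            assert back.pair(r) == VACUUM_RATES["quinidine"].pair(r)

    def test_unconverged_result_refused_without_force(self, clean_set):
        spec = FitSpec(topology="vacuum", free_parameters=FREE3,
                       baseline_rates=DEMO_RATES, bounds=BOUNDS3,
                       optimizer="differential-evolution", population=4,
                       generations=2, refine=False, fit_stride=8, seed=0)
        res = global_fit(clean_set, spec)
        res.converged = False
        with pytest.raises(ValueError, match="force"):
            rate_table(res)
        assert len(rate_table(res, force=True)) == 5
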
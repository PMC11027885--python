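"""Canned simulation-and-refit experiments.

These drive the package end to end under controlled conditions:
generate synthetic assay data from a known parameter set, fit it the
same way bench data would be fit, and summarise how well the generating
parameters are recovered.  They back the reproducibility script and the
recovery test suite, and are handy for power analysis when planning a
new assay.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import reference
from .atpase import ATPaseParams, ModelKind, fit_atpase
from .synth import generate_atpase_dataset

__all__ = ["AtpaseRecoveryResult", "atpase_recovery", "monophasic_ladder",
           "biphasic_grid", "topology_discrimination"]


def monophasic_ladder(n: int = 12, top_um: float = 500.0) -> np.ndarray:
    """Two-fold dilution series from ``top_um`` plus a zero-drug point.

    Mirrors how saturation assays are laid out on a plate: the ladder
    spans three orders of magnitude so both the rise around K_m and the
    plateau are sampled.
    """
    ladder = top_um / 2.0 ** np.arange(n - 1)
    return np.sort(np.concatenate([[0.0], ladder]))


def biphasic_grid(n: int = 12, lo_um: float = 0.5, top_um: float = 500.0) -> np.ndarray:
    """Log-spaced concentration grid for substrate-inhibition assays.

    Starts above zero (the biphasic law needs drug present) and spans
    past the activity peak so the inhibitory limb is sampled.
    """
    return np.geomspace(lo_um, top_um, n)


@dataclass
class AtpaseRecoveryResult:
    """Median recovered parameters over repeated simulate-and-refit runs."""

    drug: str
    model_kind: ModelKind
    truth: ATPaseParams
    n_runs: int
    medians: dict[str, float]
    spreads: dict[str, float]   # SD of the per-run estimates

    def summary(self) -> str:
        lines = [f"{self.drug} ({self.model_kind}), {self.n_runs} simulated assays",
                 f"{'param':<9}{'truth':>10}{'median':>12}{'spread(SD)':>12}"]
        truth = {"v_max": self.truth.v_max, "k_m": self.truth.k_m,
                 "k_i": self.truth.k_i, "v_basal": self.truth.v_basal}
        for k, med in self.medians.items():
            lines.append(f"{k:<9}{truth[k]:>10.4g}{med:>12.4g}{self.spreads[k]:>12.3g}")
        return "\n".join(lines)


def atpase_recovery(drug: str, n_runs: int = 50,
                    noise_sd: float = reference.ATPASE_NOISE_SD,
                    seed: int = 0, n_starts: int = 8,
                    concentrations: np.ndarray | None = None) -> AtpaseRecoveryResult:
    """Simulate ``n_runs`` noisy ATPase assays for one substrate and refit each.

    The generating parameters come from the bundled example sets; the
    concentration design is a 12-point dilution ladder (monophasic) or
    log grid (biphasic).  Per-run seeds are spawned deterministically
    from ``seed``.
    """
    params = reference.ATPASE_PARAMS[drug]
    kind = params.model_kind
    if concentrations is None:
        concentrations = (monophasic_ladder() if kind == "monophasic"
                          else biphasic_grid())
    names = ["v_max", "k_m", "v_basal"] + (["k_i"] if kind == "biphasic" else [])
    run_seeds = np.random.SeedSequence(seed).generate_state(2 * n_runs) % (2**31)
    estimates: dict[str, list[float]] = {n: [] for n in names}
    for i in range(n_runs):
        ds = generate_atpase_dataset(params, kind, concentrations,
                                     noise_sd=noise_sd, replicates=1,
                                     seed=int(run_seeds[2 * i]), drug_label=drug)
        fit = fit_atpase(ds, kind, n_starts=n_starts, seed=int(run_seeds[2 * i + 1]))
        for n in names:
            estimates[n].append(getattr(fit.params, n))
    medians = {n: float(np.median(v)) for n, v in estimates.items()}
    spreads = {n: float(np.std(v, ddof=1)) for n, v in estimates.items()}
    return AtpaseRecoveryResult(drug=drug, model_kind=kind, truth=params,
                                n_runs=n_runs, medians=medians, spreads=spreads)


def topology_discrimination(n_replicates: int = 20, noise_sigma: float = 30.0,
                            seed: int = 0,
                            concentrations_um=(500.0, 125.0, 31.25),
                            free_parameters=("r2.kon", "r2.koff", "r4.kon"),
                            population: int = 6, generations: int = 15,
                            dt: float = 4.0, fit_stride: int = 2) -> dict:
    """Power experiment for the vacuum-cleaner vs flippase comparison.

    Each replicate simulates a noisy sensorgram set under the
    vacuum-cleaner topology with the transport-dominant rate set, fits
    both topologies with identical budgets and random initialisation,
    and records which is preferred.  Returns the per-replicate
    preferences and residual sums of squares.
    """
    from .fitting import FitSpec, compare_topologies
    from .synth import SensorgramNoiseModel, generate_sensorgram_set
    from .transport import ObservableParams

    rates = reference.DISCRIMINATION_RATES
    bounds = {n: (-7.0, 3.0) for n in free_parameters}
    prefs, rss_v, rss_f = [], [], []
    seeds = np.random.SeedSequence(seed).generate_state(2 * n_replicates) % (2**31)
    for i in range(n_replicates):
        data = generate_sensorgram_set(
            rates, "vacuum", concentrations_um,
            observable=ObservableParams(k=1e6, c=10.0),
            phases=reference.DEFAULT_PHASES, dt=dt,
            noise=SensorgramNoiseModel(sigma=noise_sigma, seed=int(seeds[2 * i])))

        def spec(topology):
            return FitSpec(topology=topology, free_parameters=free_parameters,
                           baseline_rates=rates, bounds=bounds,
                           optimizer="differential-evolution",
                           population=population, generations=generations,
                           seed=int(seeds[2 * i + 1]), fit_stride=fit_stride)

        cmp = compare_topologies(data, spec("vacuum"), spec("flippase"))
        prefs.append(cmp.preferred)
        rss_v.append(cmp.vacuum.rss)
        rss_f.append(cmp.flippase.rss)
    return {"preferred": prefs, "rss_vacuum": rss_v, "rss_flippase": rss_f,
            "vacuum_fraction": prefs.count("vacuum") / n_replicates}
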
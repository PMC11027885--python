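"""Synthetic ATPase and SPR datasets with the structure of the bench assays.

Every downstream stage of the package (rate-law fitting, global
sensorgram fitting, topology comparison, ratio analysis) is exercised on
data produced here, so the generators mirror the assay designs: a
two-fold analyte dilution series (default 500 → 31.25 μM), a 1,200 s
association and 800 s dissociation phase, paired ATP / no-nucleotide
conditions, and additive Gaussian measurement noise with optional linear
baseline drift.  Generating parameters ("truth") travel with each
dataset — embedded in the objects and written to sidecar JSON — so
parameter-recovery tests need no extra bookkeeping.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .atpase import ATPaseParams, ModelKind, monophasic_rate, biphasic_rate
from .transport import (
    ObservableParams,
    PhaseSchedule,
    PoolTotals,
    ReactionRates,
    Topology,
    build_reaction_network,
    observable_ru,
    simulate_timecourse,
)

__all__ = [
    "ATPaseDataset",
    "SensorgramNoiseModel",
    "SensorgramSet",
    "generate_atpase_dataset",
    "generate_sensorgram_set",
    "make_paired_condition_set",
    "DEFAULT_CONCENTRATIONS_UM",
]

#: two-fold dilution series used throughout the SPR experiments, μM
DEFAULT_CONCENTRATIONS_UM = (500.0, 250.0, 125.0, 62.5, 31.25)


@dataclass
class ATPaseDataset:
    """ATP hydrolysis rates across a drug concentration series.

    ``rates`` is stored replicate-major: for concentrations
    ``c1..cn`` and ``m`` replicates it holds ``n*m`` values ordered by
    replicate then concentration.
    """

    drug_label: str
    concentrations: np.ndarray  # μM, strictly increasing
    rates: np.ndarray           # nmol min^-1 mg^-1
    replicates: int = 1
    truth: ATPaseParams | None = None

    def __post_init__(self) -> None:
        self.concentrations = np.asarray(self.concentrations, float)
        self.rates = np.asarray(self.rates, float)
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        c = self.concentrations
        if c.ndim != 1 or np.any(c < 0) or np.any(np.diff(c) <= 0):
            raise ValueError("concentrations must be 1-D, non-negative, strictly increasing")
        if self.rates.shape != (c.size * self.replicates,):
            raise ValueError("rates must have length len(concentrations) * replicates")
        if not np.all(np.isfinite(self.rates)):
            raise ValueError("rates must be finite")

    @property
    def tidy_concentrations(self) -> np.ndarray:
        """Concentration of every rate observation (replicate-expanded)."""
        return np.tile(self.concentrations, self.replicates)

    def to_frame(self) -> pd.DataFrame:
        rep = np.repeat(np.arange(1, self.replicates + 1), self.concentrations.size)
        return pd.DataFrame({"conc_uM": self.tidy_concentrations,
                             "rate_nmol_min_mg": self.rates,
                             "replicate": rep})

    def to_csv(self, path: str | Path) -> None:
        path = Path(path)
        self.to_frame().to_csv(path, index=False)
        sidecar = {"drug_label": self.drug_label, "replicates": self.replicates}
        if self.truth is not None:
            sidecar["truth"] = {"v_max": self.truth.v_max, "k_m": self.truth.k_m,
                                "k_i": self.truth.k_i, "v_basal": self.truth.v_basal}
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))

    @classmethod
    def from_csv(cls, path: str | Path) -> "ATPaseDataset":
        path = Path(path)
        df = pd.read_csv(path)
        sidecar_path = path.with_suffix(".json")
        label, truth, reps = path.stem, None, int(df["replicate"].max())
        if sidecar_path.exists():
            meta = json.loads(sidecar_path.read_text())
            label = meta.get("drug_label", label)
            reps = meta.get("replicates", reps)
            if "truth" in meta:
                truth = ATPaseParams(**meta["truth"])
        df = df.sort_values(["replicate", "conc_uM"], kind="stable")
        conc = np.sort(df["conc_uM"].unique())
        return cls(drug_label=label, concentrations=conc,
                   rates=df["rate_nmol_min_mg"].to_numpy(), replicates=reps,
                   truth=truth)


@dataclass(frozen=True)
class SensorgramNoiseModel:
    """Additive i.i.d. Gaussian RU noise with optional linear drift.

    Identical ``seed`` plus identical inputs give bit-identical output.
    """

    sigma: float = 0.0
    drift_per_second: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma < 0 or not math.isfinite(self.sigma):
            raise ValueError("sigma must be finite and >= 0")

    def sample(self, times: np.ndarray, n_traces: int) -> np.ndarray:
        rng = np.random.default_rng(self.seed)
        noise = rng.normal(0.0, self.sigma, size=(n_traces, times.size)) \
            if self.sigma > 0 else np.zeros((n_traces, times.size))
        return noise + self.drift_per_second * np.asarray(times, float)


@dataclass
class SensorgramSet:
    """Time-aligned RU traces over an analyte concentration series.

    ``traces`` has shape (n_concentrations, n_times) and shares one time
    grid.  ``condition`` tags the nucleotide state of the run (``"ATP"``,
    ``"ADP"`` or ``"no-nucleotide"``).  ``truth`` carries the generating
    parameters when the set is synthetic.
    """

    times: np.ndarray                 # s
    concentrations_um: np.ndarray     # μM, one per trace
    traces: np.ndarray                # RU, (n_conc, n_times)
    phases: PhaseSchedule
    condition: str = "ATP"
    truth: dict | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, float)
        self.concentrations_um = np.asarray(self.concentrations_um, float)
        self.traces = np.asarray(self.traces, float)
        if self.traces.shape != (self.concentrations_um.size, self.times.size):
            raise ValueError("traces must be (n_concentrations, n_times)")

    @property
    def n_traces(self) -> int:
        return self.concentrations_um.size

    def trace(self, conc_um: float) -> np.ndarray:
        i = int(np.argmin(np.abs(self.concentrations_um - conc_um)))
        if not np.isclose(self.concentrations_um[i], conc_um):
            raise KeyError(f"no trace at {conc_um} uM")
        return self.traces[i]

    def to_frame(self) -> pd.DataFrame:
        data = {"time_s": self.times}
        for c, tr in zip(self.concentrations_um, self.traces):
            data[f"ru_{c:g}uM"] = tr
        return pd.DataFrame(data)

    def plot(self, ax=None):
        """Overlay of all traces with the phase boundary marked."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        for c, tr in zip(self.concentrations_um, self.traces):
            ax.plot(self.times, tr, lw=0.8, label=f"{c:g} μM")
        ax.axvline(self.phases.association_end, color="k", ls="--", lw=0.5)
        ax.set_xlabel("time (s)")
        ax.set_ylabel("response (RU)")
        ax.set_title(self.condition)
        ax.legend(fontsize="small")
        return ax

    def to_csv(self, path: str | Path) -> None:
        path = Path(path)
        self.to_frame().to_csv(path, index=False)
        sidecar = {
            "condition": self.condition,
            "phases": {"association_end": self.phases.association_end,
                       "trace_end": self.phases.trace_end},
            "concentrations_um": self.concentrations_um.tolist(),
        }
        if self.truth is not None:
            sidecar["truth"] = self.truth
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))

    @classmethod
    def from_csv(cls, path: str | Path) -> "SensorgramSet":
        path = Path(path)
        df = pd.read_csv(path)
        ru_cols = [c for c in df.columns if c.startswith("ru_")]
        conc = np.array([float(c[3:].rstrip("uM")) for c in ru_cols])
        meta_path = path.with_suffix(".json")
        condition, truth = "ATP", None
        if meta_path.exists():
            meta = json.loads(meta_path.read_text())
            condition = meta.get("condition", condition)
            truth = meta.get("truth")
            ph = meta["phases"]
            phases = PhaseSchedule(ph["association_end"], ph["trace_end"])
        else:
            t = df["time_s"].to_numpy()
            phases = PhaseSchedule(0.6 * t[-1], t[-1])
        return cls(times=df["time_s"].to_numpy(), concentrations_um=conc,
                   traces=df[ru_cols].to_numpy().T, phases=phases,
                   condition=condition, truth=truth)


# ---------------------------------------------------------------------------
# Generators


def generate_atpase_dataset(params: ATPaseParams,
                            model: ModelKind,
                            concentrations: Sequence[float],
                            noise_sd: float = 0.0,
                            replicates: int = 1,
                            seed: int = 0,
                            drug_label: str = "synthetic") -> ATPaseDataset:
    """Simulate an ATPase rate-vs-concentration experiment.

    Rates are the chosen rate law evaluated at each concentration plus
    i.i.d. Gaussian noise of standard deviation ``noise_sd``; the
    generating parameters are stored in ``truth``.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if model == "biphasic" and params.k_i is None:
        raise ValueError("biphasic generation requires k_i")
    conc = np.asarray(concentrations, float)
    if np.any(conc < 0):
        raise ValueError("concentrations must be non-negative")
    rate_fn = monophasic_rate if model == "monophasic" else biphasic_rate
    clean = np.tile(np.atleast_1d(rate_fn(conc, params)), replicates)
    rng = np.random.default_rng(seed)
    noisy = clean + (rng.normal(0.0, noise_sd, clean.shape) if noise_sd > 0 else 0.0)
    return ATPaseDataset(drug_label=drug_label, concentrations=conc, rates=noisy,
                         replicates=replicates, truth=params)


def generate_sensorgram_set(rates: ReactionRates,
                            topology: Topology,
                            concentrations_um: Sequence[float] = DEFAULT_CONCENTRATIONS_UM,
                            observable: Sequence[ObservableParams] | ObservableParams | None = None,
                            phases: PhaseSchedule | None = None,
                            noise: SensorgramNoiseModel | None = None,
                            pools: PoolTotals | None = None,
                            dt: float = 0.5,
                            condition: str = "ATP",
                            solver_opts: dict | None = None) -> SensorgramSet:
    """Forward-simulate a multi-concentration sensorgram set.

    Each trace is the deterministic compartment simulation at its
    concentration mapped through the linear RU observable, plus the
    noise model.  One ``ObservableParams`` per concentration (a single
    instance is broadcast).  The generating rates, topology and
    observables are retained in ``truth``.
    """
    phases = phases or PhaseSchedule()
    noise = noise or SensorgramNoiseModel()
    conc = np.asarray(concentrations_um, float)
    if observable is None:
        observable = ObservableParams(k=1e6, c=0.0)
    if isinstance(observable, ObservableParams):
        observable = [observable] * conc.size
    if len(observable) != conc.size:
        raise ValueError("need one ObservableParams per concentration")

    network = build_reaction_network(topology, rates, pools=pools)
    times = np.arange(0.0, phases.trace_end + 0.5 * dt, dt)
    clean = np.empty((conc.size, times.size))
    for i, (c_um, obs) in enumerate(zip(conc, observable)):
        traj = simulate_timecourse(network, phases, c_um * 1e-6, grid=times,
                                   **(solver_opts or {}))
        clean[i] = observable_ru(traj, obs)
    traces = clean + noise.sample(times, conc.size)
    truth = {
        "rates": rates.as_dict(),
        "topology": topology,
        "observable": [{"k": o.k, "c": o.c} for o in observable],
        "noise": {"sigma": noise.sigma, "drift_per_second": noise.drift_per_second,
                  "seed": noise.seed},
    }
    return SensorgramSet(times=times, concentrations_um=conc, traces=traces,
                         phases=phases, condition=condition, truth=truth)


def make_paired_condition_set(rates: ReactionRates,
                              transport_active: bool,
                              topology: Topology = "vacuum",
                              **kwargs) -> SensorgramSet:
    """One arm of the paired ±ATP design.

    ``transport_active=True`` simulates the ATP condition with the given
    rates; ``False`` simulates the no-nucleotide condition by switching
    the Pgp transport step off (r4 forward rate zero), all other rates
    shared.  More analyte then accumulates in the ATP arm, which is what
    the amplitude-ratio readout detects.
    """
    if transport_active:
        used, condition = rates, "ATP"
    else:
        used, condition = rates.with_value("r4.kon", 0.0), "no-nucleotide"
    kwargs.setdefault("condition", condition)
    return generate_sensorgram_set(used, topology, **kwargs)
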
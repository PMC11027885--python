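"""Global fitting of multi-concentration sensorgram sets.

All traces of a set are fit simultaneously: the kinetic rate constants
are shared across concentrations (global parameters) while the RU
scaling ``k`` and baseline ``C`` are free per trace (local parameters).
Because the observable is linear in ``k`` and ``C``, the locals are
profiled out exactly — for any candidate rate vector the optimal
``k, C`` of each trace is a closed-form linear least-squares solve —
so the optimiser only searches the (log-scaled) rate space.

Rates are estimated in log10 space within finite boxes.  The default
search method is evolutionary programming with an optional trust-region
polish; differential evolution and multi-start local search are
drop-in alternatives.  Topology discrimination fits the same data under
the vacuum-cleaner and flippase networks — the two are equi-dimensional,
so the AICc comparison reduces to a residual-sum-of-squares comparison.

Identifiability is reported, not assumed: a profile-flatness check
perturbs each fitted rate about the optimum and flags parameters whose
movement leaves the objective unchanged at the noise floor.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .atpase import aicc_from_rss
from .optimize import (OptimizeOutcome, differential_evolution,
                       evolutionary_programming, multi_start_local)
from .synth import SensorgramSet
from .transport import (REACTION_LABELS, IntegrationError, ObservableParams,
                        PhaseSchedule, PoolTotals, ReactionRates, Topology,
                        build_reaction_network, simulate_timecourse)

__all__ = [
    "FitSpec",
    "TransportKinetics",
    "TransportFitResult",
    "TopologyComparison",
    "global_fit",
    "compare_topologies",
    "rate_table",
    "parse_rate_table",
]

#: the ten rate constants reported for the transport process (r1 is the
#: non-limiting mass-transport step and is fixed by default)
DEFAULT_FREE_PARAMETERS = (
    "r2.kon", "r2.koff", "r3.kon", "r3.koff", "r4.kon", "r4.koff",
    "r5.kon", "r5.koff", "r6.kon", "r6.koff",
)

DEFAULT_LOG10_BOUNDS = (-9.0, 4.0)


@dataclass
class FitSpec:
    """Configuration of one global sensorgram fit.

    Parameters
    ----------
    topology : {"vacuum", "flippase"}
    free_parameters : sequence of str
        Rate constants to estimate, named ``"r<i>.kon"`` / ``"r<i>.koff"``.
        All others are held at their value in ``baseline_rates``.
    baseline_rates : ReactionRates
        Values of the fixed constants (and fallback initial values).
    bounds : dict
        Per-parameter ``(lo, hi)`` log10 bounds; missing entries use
        ``DEFAULT_LOG10_BOUNDS``.  Every estimated parameter therefore
        has a finite box.
    optimizer : {"evolutionary", "differential-evolution", "multi-start-local"}
    population, generations : int
        Population size and generation budget of the global search.
        The multi-start method reads ``population`` as the number of
        starts and ``generations`` as the per-start evaluation budget
        (times the parameter count plus one).
    refine : bool
        Trust-region least-squares polish of the best point.
    fit_window : (float, float)
        Time range of the objective, seconds.  Points outside are
        simulated but not scored.
    fit_stride : int
        Use every n-th time sample in the objective (1 = all).
    """

    topology: Topology = "vacuum"
    free_parameters: Sequence[str] = DEFAULT_FREE_PARAMETERS
    baseline_rates: ReactionRates = field(default_factory=ReactionRates)
    bounds: dict[str, tuple[float, float]] = field(default_factory=dict)
    optimizer: Literal["evolutionary", "differential-evolution",
                       "multi-start-local"] = "evolutionary"
    population: int = 40
    generations: int = 500
    seed: int = 0
    refine: bool = True
    fit_window: tuple[float, float] = (0.0, 2000.0)
    fit_stride: int = 1
    pools: PoolTotals = field(default_factory=PoolTotals)
    rate_convention: Literal["first-order", "second-order"] = "first-order"
    initial_rates: ReactionRates | None = None
    solver_opts: dict = field(default_factory=lambda: {"rtol": 1e-6, "atol": 1e-12})

    def log_bounds(self) -> list[tuple[float, float]]:
        out = []
        for name in self.free_parameters:
            lo, hi = self.bounds.get(name, DEFAULT_LOG10_BOUNDS)
            if not (math.isfinite(lo) and math.isfinite(hi) and hi > lo):
                raise ValueError(f"parameter {name} needs finite log10 bounds")
            out.append((lo, hi))
        return out


@dataclass
class TransportFitResult:
    """Global-fit estimates with residuals and goodness of fit."""

    rates: ReactionRates
    observables: list[ObservableParams]
    rss: float
    n_obs: int
    n_params: int
    residual_traces: np.ndarray       # (n_traces, n_window_points)
    residual_times: np.ndarray
    converged: bool
    seed: int
    spec: FitSpec
    history: np.ndarray               # best-so-far objective trajectory
    unidentifiable: tuple[str, ...] = ()

    @property
    def aicc(self) -> float:
        return aicc_from_rss(self.rss, self.n_obs, self.n_params)

    @property
    def topology(self) -> Topology:
        return self.spec.topology

    def residual_autocorrelation(self) -> float:
        """Mean lag-1 autocorrelation of the per-trace residuals."""
        acs = []
        for r in self.residual_traces:
            r = r - r.mean()
            denom = float(r @ r)
            if denom > 0:
                acs.append(float(r[1:] @ r[:-1]) / denom)
        return float(np.mean(acs)) if acs else float("nan")

    def as_dict(self) -> dict:
        return {
            "topology": self.topology,
            "rates": self.rates.as_dict(),
            "observables": [{"k": o.k, "c": o.c} for o in self.observables],
            "rss": self.rss,
            "n_obs": self.n_obs,
            "n_params": self.n_params,
            "aicc": self.aicc,
            "converged": self.converged,
            "seed": self.seed,
            "unidentifiable": list(self.unidentifiable),
        }

    def plot_residuals(self, ax=None):
        """Per-trace residual time series over the fit window."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        for i, r in enumerate(self.residual_traces):
            ax.plot(self.residual_times, r, lw=0.7, label=f"trace {i}")
        ax.axhline(0.0, color="k", lw=0.5)
        ax.set_xlabel("time (s)")
        ax.set_ylabel("residual (RU)")
        ax.legend(fontsize="small")
        return ax

    def summary(self) -> str:
        lines = [
            f"Global sensorgram fit ({self.topology} topology)",
            "=" * 58,
            f"{'step':<6}{'kon':>14}{'koff':>14}  note",
            "-" * 58,
        ]
        for r in ("r1", "r2", "r3", "r4", "r5", "r6"):
            pair = self.rates.pair(r)
            flags = [w for p, w in (("kon", f"{r}.kon"), ("koff", f"{r}.koff"))
                     if w in self.unidentifiable]
            fixed = all(f"{r}.{p}" not in self.spec.free_parameters
                        for p in ("kon", "koff"))
            note = "fixed" if fixed else ("flat: " + ", ".join(flags) if flags else "")
            lines.append(f"{r:<6}{pair.kon:>14.4g}{pair.koff:>14.4g}  {note}")
        lines += ["-" * 58]
        for obs, conc in zip(self.observables, range(len(self.observables))):
            lines.append(f"trace {conc}: k = {obs.k:.4g} RU/M, C = {obs.c:.4g} RU")
        lines += [
            "-" * 58,
            f"rss = {self.rss:.6g} RU^2   n = {self.n_obs}   "
            f"p = {self.n_params}   AICc = {self.aicc:.6g}",
        ]
        if not self.converged:
            lines.append("WARNING: optimiser budget exhausted without convergence")
        return "\n".join(lines)


class TransportKinetics:
    """Model object binding a sensorgram set to a fit specification."""

    def __init__(self, data: SensorgramSet, spec: FitSpec):
        if data.n_traces < 2:
            raise ValueError("global fitting needs >= 2 concentrations")
        t0, t1 = spec.fit_window
        if t0 < data.times[0] - 1e-9 or t1 > data.times[-1] + 1e-9:
            raise ValueError("fit_window must lie within the data time range")
        self.data = data
        self.spec = spec
        mask = (data.times >= t0) & (data.times <= t1)
        idx = np.flatnonzero(mask)[:: max(spec.fit_stride, 1)]
        self._idx = idx
        self._times = data.times[idx]
        self._obs = data.traces[:, idx]
        self._conc_m = data.concentrations_um * 1e-6
        self._phases = data.phases

    # -- objective ---------------------------------------------------------

    def _rates_from_log(self, x: np.ndarray) -> ReactionRates:
        rates = self.spec.baseline_rates
        for name, v in zip(self.spec.free_parameters, x):
            rates = rates.with_value(name, 10.0 ** v)
        return rates

    def _simulate_signals(self, rates: ReactionRates) -> np.ndarray:
        network = build_reaction_network(self.spec.topology, rates,
                                         pools=self.spec.pools,
                                         rate_convention=self.spec.rate_convention)
        out = np.empty((self._conc_m.size, self._times.size))
        for i, c in enumerate(self._conc_m):
            traj = simulate_timecourse(network, self._phases, c, grid=self._times,
                                       **self.spec.solver_opts)
            out[i] = traj.signal_concentration
        return out

    @staticmethod
    def _profile_locals(q: np.ndarray, y: np.ndarray) -> tuple[float, float]:
        """Closed-form per-trace ``k >= 0`` and ``C`` minimising ||y - (kq + C)||."""
        qc = q - q.mean()
        var = float(qc @ qc)
        if var <= 0:
            return 0.0, float(y.mean())
        k = float(qc @ (y - y.mean())) / var
        if k < 0:
            return 0.0, float(y.mean())
        return k, float(y.mean() - k * q.mean())

    def _residuals(self, x: np.ndarray) -> tuple[np.ndarray, list[ObservableParams]]:
        rates = self._rates_from_log(x)
        signals = self._simulate_signals(rates)
        res = np.empty_like(self._obs)
        locals_: list[ObservableParams] = []
        for i, (q, y) in enumerate(zip(signals, self._obs)):
            k, c = self._profile_locals(q, y)
            locals_.append(ObservableParams(k=k, c=c))
            res[i] = y - (k * q + c)
        return res, locals_

    def objective(self, x: np.ndarray) -> float:
        """Profiled sum of squared residuals at log10 rate vector ``x``."""
        try:
            res, _ = self._residuals(x)
        except IntegrationError:
            return 1e12
        return float(np.sum(res * res))

    # -- fitting -----------------------------------------------------------

    def _initial_point(self) -> np.ndarray | None:
        init = self.spec.initial_rates
        if init is None:
            return None
        vals = np.array([init.value(n) for n in self.spec.free_parameters])
        lob = np.array([b[0] for b in self.spec.log_bounds()])
        return np.log10(np.clip(vals, 10.0 ** lob, None))

    def fit(self) -> TransportFitResult:
        spec = self.spec
        bounds = spec.log_bounds()
        x0 = self._initial_point()
        if spec.optimizer == "evolutionary":
            out = evolutionary_programming(self.objective, bounds,
                                           population=spec.population,
                                           generations=spec.generations,
                                           seed=spec.seed, initial=x0)
        elif spec.optimizer == "differential-evolution":
            out = differential_evolution(self.objective, bounds,
                                         population=spec.population,
                                         generations=spec.generations,
                                         seed=spec.seed, initial=x0)
        elif spec.optimizer == "multi-start-local":
            out = multi_start_local(self.objective, bounds,
                                    n_starts=spec.population, seed=spec.seed,
                                    initial=x0,
                                    max_nfev=spec.generations * (len(bounds) + 1))
        else:
            raise ValueError(f"unknown optimizer {spec.optimizer!r}")

        x_best, f_best = out.x, out.fun
        if not np.isfinite(f_best) or f_best >= 1e12:
            raise ValueError("objective non-finite everywhere sampled; check bounds")
        if spec.refine:
            x_best, f_best = self._polish(x_best, bounds, f_best)
        return self._build_result(x_best, f_best, out)

    def _polish(self, x: np.ndarray, bounds, f_current: float) -> tuple[np.ndarray, float]:
        from scipy.optimize import least_squares

        lo = np.array([b[0] for b in bounds])
        hi = np.array([b[1] for b in bounds])

        def resid(z):
            try:
                r, _ = self._residuals(z)
            except IntegrationError:
                return np.full(self._obs.size, 1e6)
            return r.ravel()

        eps = 1e-9
        sol = least_squares(resid, np.clip(x, lo + eps, hi - eps),
                            bounds=(lo, hi), method="trf",
                            diff_step=1e-4, max_nfev=60 * (x.size + 1))
        f = float(2.0 * sol.cost)
        return (sol.x, f) if f < f_current else (x, f_current)

    def _build_result(self, x: np.ndarray, f: float, out: OptimizeOutcome) -> TransportFitResult:
        res, locals_ = self._residuals(x)
        rss = float(np.sum(res * res))
        n_obs = int(self._obs.size)
        n_params = len(self.spec.free_parameters) + 2 * self.data.n_traces
        flat = self.flag_unidentifiable(x, rss)
        return TransportFitResult(
            rates=self._rates_from_log(x), observables=locals_, rss=rss,
            n_obs=n_obs, n_params=n_params, residual_traces=res,
            residual_times=self._times, converged=bool(out.converged),
            seed=self.spec.seed, spec=self.spec, history=out.history,
            unidentifiable=flat,
        )

    def flag_unidentifiable(self, x: np.ndarray, rss: float,
                            delta_log10: float = 0.1,
                            rel_threshold: float = 1e-6) -> tuple[str, ...]:
        """Profile-flatness check around the optimum.

        Each fitted log10 rate is displaced by ±``delta_log10``; a
        parameter whose displacement changes the objective by less than
        ``rel_threshold`` of the data's total (per-trace de-meaned)
        sum of squares is reported as unidentifiable.
        """
        tss = float(np.sum((self._obs - self._obs.mean(axis=1, keepdims=True)) ** 2))
        scale = max(tss, 1e-300)
        flat: list[str] = []
        for j, name in enumerate(self.spec.free_parameters):
            worst = 0.0
            for sgn in (-1.0, 1.0):
                z = x.copy()
                z[j] += sgn * delta_log10
                worst = max(worst, abs(self.objective(z) - rss))
            if worst / scale < rel_threshold:
                flat.append(name)
        return tuple(flat)


def global_fit(data: SensorgramSet, spec: FitSpec) -> TransportFitResult:
    """Fit a sensorgram set globally under one topology (see :class:`TransportKinetics`)."""
    return TransportKinetics(data, spec).fit()


# ---------------------------------------------------------------------------
# Topology comparison


@dataclass
class TopologyComparison:
    """Vacuum-cleaner vs flippase fits of the same data."""

    vacuum: TransportFitResult
    flippase: TransportFitResult
    preferred: Literal["vacuum", "flippase", "none"]
    delta_aicc: float         # aicc(flippase) - aicc(vacuum)
    rss_relative_difference: float

    def summary(self) -> str:
        return (
            f"{'topology':<12}{'rss':>14}{'AICc':>14}{'lag-1 resid. AC':>18}\n"
            f"{'vacuum':<12}{self.vacuum.rss:>14.6g}{self.vacuum.aicc:>14.6g}"
            f"{self.vacuum.residual_autocorrelation():>18.3f}\n"
            f"{'flippase':<12}{self.flippase.rss:>14.6g}{self.flippase.aicc:>14.6g}"
            f"{self.flippase.residual_autocorrelation():>18.3f}\n"
            f"preferred: {self.preferred} "
            f"(delta AICc = {self.delta_aicc:.4g})"
        )


def compare_topologies(data: SensorgramSet, spec_vacuum: FitSpec,
                       spec_flippase: FitSpec,
                       no_preference_tolerance: float = 1e-3) -> TopologyComparison:
    """Fit both topologies and report which the data prefer.

    The two specs must estimate the same number of parameters, so the
    AICc ordering equals the rss ordering.  When the relative rss
    difference falls below ``no_preference_tolerance``, or neither fit
    converged, no preference is declared.
    """
    if spec_vacuum.topology != "vacuum" or spec_flippase.topology != "flippase":
        raise ValueError("specs must carry their respective topologies")
    if len(spec_vacuum.free_parameters) != len(spec_flippase.free_parameters):
        raise ValueError("topology comparison requires equi-dimensional fits")
    model_v = TransportKinetics(data, spec_vacuum)
    tss = float(np.sum((model_v._obs - model_v._obs.mean(axis=1, keepdims=True)) ** 2))
    fit_v = model_v.fit()
    fit_f = global_fit(data, spec_flippase)
    delta = fit_f.aicc - fit_v.aicc
    # scale against the better fit, floored at the data's resolvable scale,
    # so two fits at the (near-zero) noise floor compare as equivalent
    denom = max(min(fit_v.rss, fit_f.rss), 1e-9 * tss)
    rel = abs(fit_f.rss - fit_v.rss) / denom if denom > 0 else 0.0
    if (not fit_v.converged and not fit_f.converged) or rel < no_preference_tolerance:
        preferred: Literal["vacuum", "flippase", "none"] = "none"
    else:
        preferred = "vacuum" if fit_v.aicc <= fit_f.aicc else "flippase"
    return TopologyComparison(vacuum=fit_v, flippase=fit_f, preferred=preferred,
                              delta_aicc=delta, rss_relative_difference=rel)


# ---------------------------------------------------------------------------
# Reporting

_TABLE_ROWS = ("r2", "r3", "r4", "r5", "r6")


def rate_table(result: TransportFitResult | ReactionRates,
               topology: Topology = "vacuum", force: bool = False) -> pd.DataFrame:
    """Five-row reaction-rate table (r2..r6) in assay-report form.

    Accepts a fit result (must have converged unless ``force``) or a
    bare :class:`ReactionRates`.  Columns: reaction id, description,
    kon (M^-1 s^-1), koff (s^-1).
    """
    if isinstance(result, TransportFitResult):
        if not result.converged and not force:
            raise ValueError("fit did not converge; pass force=True to tabulate anyway")
        rates, topology = result.rates, result.topology
    else:
        rates = result
    rows = []
    for r in _TABLE_ROWS:
        key = f"r4_{topology}" if r == "r4" else r
        pair = rates.pair(r)
        rows.append({"reaction": r, "description": REACTION_LABELS[key],
                     "kon_per_M_s": pair.kon, "koff_per_s": pair.koff})
    return pd.DataFrame(rows)


def parse_rate_table(table: pd.DataFrame | str,
                     r1: "ReactionRates | None" = None) -> ReactionRates:
    """Inverse of :func:`rate_table` (r1 is not tabulated; supply or default)."""
    if isinstance(table, str):
        table = pd.read_csv(io.StringIO(table), sep="\t")
    rates = r1 if r1 is not None else ReactionRates()
    for _, row in table.iterrows():
        rates = rates.with_value(f"{row['reaction']}.kon", float(row["kon_per_M_s"]))
        rates = rates.with_value(f"{row['reaction']}.koff", float(row["koff_per_s"]))
    return rates
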
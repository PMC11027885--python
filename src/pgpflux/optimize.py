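"""Global optimisers for kinetic parameter estimation.

Sensorgram objectives are cheap to evaluate relative to a wet-lab run
but expensive relative to a closed-form model, multimodal, and bounded
in log space, which is the classic profile for population methods.  The
module provides a classic evolutionary-programming minimiser
(self-adaptive Gaussian mutation, (μ+μ) tournament survival) plus thin
seeded wrappers around SciPy's differential evolution and a multi-start
local search, all sharing one return type.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy import optimize as sciopt

__all__ = ["OptimizeOutcome", "evolutionary_programming", "differential_evolution",
           "multi_start_local"]


@dataclass
class OptimizeOutcome:
    """Best point found plus the best-so-far objective trajectory."""

    x: np.ndarray
    fun: float
    history: np.ndarray  # best-so-far objective per generation/iteration
    n_evaluations: int
    converged: bool
    method: str


def _check_bounds(bounds: Sequence[tuple[float, float]]) -> tuple[np.ndarray, np.ndarray]:
    lo = np.array([b[0] for b in bounds], float)
    hi = np.array([b[1] for b in bounds], float)
    if not (np.all(np.isfinite(lo)) and np.all(np.isfinite(hi)) and np.all(hi > lo)):
        raise ValueError("every parameter needs finite bounds with hi > lo")
    return lo, hi


def evolutionary_programming(func: Callable[[np.ndarray], float],
                             bounds: Sequence[tuple[float, float]],
                             population: int = 40,
                             generations: int = 500,
                             seed: int | None = 0,
                             tournament: int = 10,
                             initial: np.ndarray | None = None) -> OptimizeOutcome:
    """Classic EP: each individual carries per-coordinate mutation scales
    that self-adapt by log-normal perturbation; parents and offspring
    compete in stochastic q-tournaments for survival.

    ``initial`` optionally injects one known starting point into the
    initial population.  The returned ``history`` (best objective after
    each generation) is non-increasing by construction.
    """
    lo, hi = _check_bounds(bounds)
    n = lo.size
    rng = np.random.default_rng(seed)
    mu = max(population, 4)

    xs = rng.uniform(lo, hi, size=(mu, n))
    if initial is not None:
        xs[0] = np.clip(np.asarray(initial, float), lo, hi)
    sigmas = np.full((mu, n), 0.2) * (hi - lo)
    fs = np.array([func(x) for x in xs])
    n_eval = mu
    tau, tau_p = 1.0 / np.sqrt(2 * np.sqrt(n)), 1.0 / np.sqrt(2 * n)
    sigma_floor = 1e-8 * (hi - lo)

    history = np.empty(generations)
    for g in range(generations):
        common = rng.normal(size=(mu, 1))
        child_sig = sigmas * np.exp(tau_p * common + tau * rng.normal(size=(mu, n)))
        child_sig = np.maximum(child_sig, sigma_floor)
        children = np.clip(xs + child_sig * rng.normal(size=(mu, n)), lo, hi)
        child_fs = np.array([func(x) for x in children])
        n_eval += mu

        pool_x = np.vstack([xs, children])
        pool_s = np.vstack([sigmas, child_sig])
        pool_f = np.concatenate([fs, child_fs])
        # q-tournament: each candidate scores wins against q random peers
        opponents = rng.integers(0, 2 * mu, size=(2 * mu, tournament))
        wins = (pool_f[:, None] <= pool_f[opponents]).sum(axis=1)
        keep = np.lexsort((pool_f, -wins))[:mu]
        # elitism: never lose the incumbent best
        best_idx = int(np.argmin(pool_f))
        if best_idx not in keep:
            keep[-1] = best_idx
        xs, sigmas, fs = pool_x[keep], pool_s[keep], pool_f[keep]
        history[g] = fs.min()

    i = int(np.argmin(fs))
    return OptimizeOutcome(x=xs[i], fun=float(fs[i]),
                           history=np.minimum.accumulate(history),
                           n_evaluations=n_eval, converged=True,
                           method="evolutionary")


def differential_evolution(func, bounds, population: int = 15,
                           generations: int = 100, seed: int | None = 0,
                           initial: np.ndarray | None = None) -> OptimizeOutcome:
    """Seeded SciPy differential evolution with best-so-far history."""
    lo, hi = _check_bounds(bounds)
    history: list[float] = []
    running_best = [np.inf]

    def wrapped(x):
        f = func(np.asarray(x, float))
        running_best[0] = min(running_best[0], f)
        return f

    def cb(*args, **kwargs):
        history.append(running_best[0])

    init = "latinhypercube"
    if initial is not None:
        rng = np.random.default_rng(seed)
        pop = rng.uniform(lo, hi, size=(max(population, 5), lo.size))
        pop[0] = np.clip(initial, lo, hi)
        init = pop
    res = sciopt.differential_evolution(
        wrapped, list(zip(lo, hi)), maxiter=generations, popsize=population,
        seed=seed, init=init, polish=False, tol=0.0, callback=cb,
        updating="deferred")
    hist = np.minimum.accumulate(np.asarray(history)) if history else np.array([res.fun])
    return OptimizeOutcome(x=np.asarray(res.x), fun=float(res.fun), history=hist,
                           n_evaluations=int(res.nfev), converged=True,
                           method="differential-evolution")


def multi_start_local(func, bounds, n_starts: int = 8, seed: int | None = 0,
                      initial: np.ndarray | None = None,
                      max_nfev: int | None = None) -> OptimizeOutcome:
    """Nelder-Mead polish from log-uniformly scattered starting points."""
    lo, hi = _check_bounds(bounds)
    rng = np.random.default_rng(seed)
    starts = [rng.uniform(lo, hi) for _ in range(max(n_starts, 1))]
    if initial is not None:
        starts.insert(0, np.clip(np.asarray(initial, float), lo, hi))
    best_x, best_f, history, n_eval = None, np.inf, [], 0
    for x0 in starts:
        res = sciopt.minimize(func, x0, method="Nelder-Mead",
                              bounds=list(zip(lo, hi)),
                              options={"maxfev": max_nfev or 200 * lo.size,
                                       "xatol": 1e-6, "fatol": 1e-12})
        n_eval += res.nfev
        if res.fun < best_f:
            best_x, best_f = np.asarray(res.x), float(res.fun)
        history.append(best_f)
    return OptimizeOutcome(x=best_x, fun=best_f,
                           history=np.minimum.accumulate(np.asarray(history)),
                           n_evaluations=n_eval, converged=True,
                           method="multi-start-local")
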
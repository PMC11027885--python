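"""Drug-stimulated ATPase kinetics of P-glycoprotein.

Pgp couples ATP hydrolysis to substrate efflux, and the hydrolysis rate
measured as a function of drug concentration is the classic functional
readout for a reconstituted transporter.  Two rate laws cover the
behaviour seen with most substrates:

* monophasic (Michaelis-Menten plus a basal term)::

      v(L) = v_max * L / (K_m + L) + v_basal

* biphasic (uncompetitive substrate inhibition, for drugs with a second,
  inhibitory binding site)::

      v(L) = v_max / (1 + K_m / L + L / K_I) + v_basal

with ``L`` the drug concentration (μM), ``v_max`` the maximal
drug-stimulated rate above basal, ``K_m`` the Michaelis constant,
``K_I`` the inhibitory constant and ``v_basal`` the hydrolysis rate with
no drug present (all rates in nmol·min⁻¹·mg⁻¹).  The biphasic law has a
single interior maximum at ``L* = sqrt(K_m * K_I)`` and tends to the
monophasic law pointwise as ``K_I → ∞``.

The module follows the Model/Results idiom: :class:`AtpaseKinetics` is
built from rate-versus-concentration data and ``fit()`` returns an
:class:`AtpaseKineticsResults` carrying estimates, standard errors and a
``summary()`` table.  :func:`fit_atpase` and :func:`select_kinetic_model`
are thin functional entry points over the same machinery.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy import optimize

__all__ = [
    "ATPaseParams",
    "AtpaseKinetics",
    "AtpaseKineticsResults",
    "KineticModelSelection",
    "monophasic_rate",
    "biphasic_rate",
    "fit_atpase",
    "select_kinetic_model",
    "DegenerateDataWarning",
]

ModelKind = Literal["monophasic", "biphasic"]


class DegenerateDataWarning(UserWarning):
    """Raised when the data carry no concentration-dependent signal."""


@dataclass(frozen=True)
class ATPaseParams:
    """Parameters of the ATPase rate laws.

    ``k_i`` is ``None`` for a monophasic parameter set; a biphasic set
    requires it.  Rates are nmol·min⁻¹·mg⁻¹, concentrations μM.
    """

    v_max: float
    k_m: float
    k_i: float | None = None
    v_basal: float = 0.0

    def __post_init__(self) -> None:
        if not (self.v_max > 0 and math.isfinite(self.v_max)):
            raise ValueError(f"v_max must be positive and finite, got {self.v_max}")
        if not (self.k_m > 0 and math.isfinite(self.k_m)):
            raise ValueError(f"k_m must be positive and finite, got {self.k_m}")
        if self.k_i is not None and not (self.k_i > 0 and math.isfinite(self.k_i)):
            raise ValueError(f"k_i must be positive and finite when present, got {self.k_i}")
        if self.v_basal < 0 or not math.isfinite(self.v_basal):
            raise ValueError(f"v_basal must be non-negative and finite, got {self.v_basal}")

    @property
    def model_kind(self) -> ModelKind:
        return "biphasic" if self.k_i is not None else "monophasic"

    @property
    def peak_concentration(self) -> float | None:
        """Concentration of maximal rate, ``sqrt(K_m * K_I)``; None if monophasic."""
        if self.k_i is None:
            return None
        return math.sqrt(self.k_m * self.k_i)


def monophasic_rate(concentration, params: ATPaseParams):
    """Michaelis-Menten ATPase rate with basal offset.

    Accepts a scalar or array concentration in μM; negative values are a
    domain error.
    """
    L = np.asarray(concentration, dtype=float)
    if np.any(L < 0):
        raise ValueError("concentration must be non-negative")
    v = params.v_max * L / (params.k_m + L) + params.v_basal
    return v if v.ndim else float(v)


def biphasic_rate(concentration, params: ATPaseParams):
    """Substrate-inhibition ATPase rate with basal offset.

    ``L = 0`` returns the limit ``v_basal`` rather than dividing by zero.
    """
    if params.k_i is None:
        raise ValueError("biphasic rate law requires k_i")
    L = np.asarray(concentration, dtype=float)
    if np.any(L < 0):
        raise ValueError("concentration must be non-negative")
    with np.errstate(divide="ignore"):
        v = np.where(
            L > 0,
            params.v_max / (1.0 + params.k_m / np.where(L > 0, L, 1.0) + L / params.k_i),
            0.0,
        ) + params.v_basal
    return v if v.ndim else float(v)


def _rate(kind: ModelKind, L, params: ATPaseParams):
    return monophasic_rate(L, params) if kind == "monophasic" else biphasic_rate(L, params)


# ---------------------------------------------------------------------------
# Model / Results


@dataclass
class AtpaseKineticsResults:
    """Fit results for one ATPase rate law.

    Attributes
    ----------
    params : ATPaseParams
        Point estimates.
    standard_errors : dict
        Asymptotic standard errors from the Jacobian at the optimum
        (``nan`` where the curvature is singular).
    rss : float
        Residual sum of squares, (nmol·min⁻¹·mg⁻¹)².
    aicc : float
        Small-sample corrected Akaike criterion computed from
        ``n ln(rss/n) + 2k + 2k(k+1)/(n-k-1)`` with ``k`` the number of
        fitted parameters plus one for the noise variance.
    converged : bool
        False when the optimiser failed or the data were degenerate; the
        estimates are then flagged unreliable in ``summary()``.
    """

    model: "AtpaseKinetics"
    params: ATPaseParams
    standard_errors: dict[str, float]
    rss: float
    model_kind: ModelKind
    n_points: int
    converged: bool
    n_starts: int

    @property
    def n_params(self) -> int:
        return 4 if self.model_kind == "biphasic" else 3

    @property
    def aicc(self) -> float:
        return aicc_from_rss(self.rss, self.n_points, self.n_params)

    def predict(self, concentration):
        return _rate(self.model_kind, concentration, self.params)

    @property
    def residuals(self) -> np.ndarray:
        return self.model.rates - self.predict(self.model.concentrations)

    def as_dict(self) -> dict:
        p = self.params
        return {
            "model": self.model_kind,
            "vmax": p.v_max,
            "km": p.k_m,
            "ki": p.k_i,
            "vbasal": p.v_basal,
            "se": dict(self.standard_errors),
            "rss": self.rss,
            "aicc": self.aicc,
            "n_points": self.n_points,
            "converged": self.converged,
        }

    def plot(self, ax=None):
        """Data points with the fitted curve on a log concentration axis."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        conc = self.model.concentrations
        ax.plot(conc, self.model.rates, "o", label="data")
        pos = conc[conc > 0]
        lo = float(pos.min()) / 2 if pos.size else 0.1
        grid = np.geomspace(lo, max(float(conc.max()), lo * 10) * 1.2, 200)
        ax.plot(grid, self.predict(grid), "-", label=f"{self.model_kind} fit")
        ax.set_xscale("log")
        ax.set_xlabel("drug concentration (μM)")
        ax.set_ylabel("ATPase rate (nmol·min⁻¹·mg⁻¹)")
        ax.legend()
        return ax

    def summary(self) -> str:
        p = self.params
        se = self.standard_errors
        lines = [
            f"ATPase kinetics fit ({self.model_kind})",
            "=" * 44,
            f"{'parameter':<10}{'estimate':>12}{'std err':>12}",
            "-" * 44,
            f"{'v_max':<10}{p.v_max:>12.4g}{se.get('v_max', float('nan')):>12.3g}",
            f"{'K_m':<10}{p.k_m:>12.4g}{se.get('k_m', float('nan')):>12.3g}",
        ]
        if p.k_i is not None:
            lines.append(f"{'K_I':<10}{p.k_i:>12.4g}{se.get('k_i', float('nan')):>12.3g}")
        lines += [
            f"{'v_basal':<10}{p.v_basal:>12.4g}{se.get('v_basal', float('nan')):>12.3g}",
            "-" * 44,
            f"n = {self.n_points}   rss = {self.rss:.6g}   AICc = {self.aicc:.4g}",
        ]
        if not self.converged:
            lines.append("WARNING: fit did not converge; estimates unreliable")
        return "\n".join(lines)


class AtpaseKinetics:
    """Nonlinear least-squares model for ATPase rate-vs-concentration data.

    Parameters
    ----------
    concentrations, rates : array-like
        Pooled observations (replicates appear as repeated concentrations,
        all points weighted equally).
    kind : {"monophasic", "biphasic"}
    """

    #: log10 bounds for multi-start sampling and the fit box
    VMAX_BOUNDS = (1.0, 1e4)
    K_BOUNDS = (1e-2, 1e4)

    def __init__(self, concentrations: Sequence[float], rates: Sequence[float],
                 kind: ModelKind = "monophasic"):
        conc = np.asarray(concentrations, dtype=float)
        rate = np.asarray(rates, dtype=float)
        if conc.shape != rate.shape or conc.ndim != 1:
            raise ValueError("concentrations and rates must be 1-D and the same length")
        if np.any(conc < 0):
            raise ValueError("concentrations must be non-negative")
        if not np.all(np.isfinite(rate)):
            raise ValueError("rates must be finite")
        if kind not in ("monophasic", "biphasic"):
            raise ValueError(f"unknown model kind {kind!r}")
        n_distinct = np.unique(conc).size
        n_required = 4 if kind == "monophasic" else 5
        if n_distinct < n_required:
            raise ValueError(
                f"{kind} fit needs >= {n_required} distinct concentrations, got {n_distinct}"
            )
        self.concentrations = conc
        self.rates = rate
        self.kind: ModelKind = kind

    @classmethod
    def from_dataset(cls, dataset, kind: ModelKind = "monophasic") -> "AtpaseKinetics":
        """Build from a :class:`pgpflux.synth.ATPaseDataset`."""
        conc = np.tile(np.asarray(dataset.concentrations, float), dataset.replicates)
        return cls(conc, np.asarray(dataset.rates, float), kind)

    # -- fitting ----------------------------------------------------------

    def _pack(self, params: ATPaseParams) -> np.ndarray:
        x = [params.v_max, params.k_m, params.v_basal]
        if self.kind == "biphasic":
            x.insert(2, params.k_i)
        return np.array(x, float)

    def _unpack(self, x: np.ndarray) -> ATPaseParams:
        if self.kind == "biphasic":
            return ATPaseParams(v_max=x[0], k_m=x[1], k_i=x[2], v_basal=x[3])
        return ATPaseParams(v_max=x[0], k_m=x[1], v_basal=x[2])

    def _bounds(self) -> tuple[np.ndarray, np.ndarray]:
        vb_hi = max(2.0 * float(np.min(self.rates)), 1e-6)
        lo = [self.VMAX_BOUNDS[0], self.K_BOUNDS[0], 0.0]
        hi = [self.VMAX_BOUNDS[1], self.K_BOUNDS[1], vb_hi]
        if self.kind == "biphasic":
            lo.insert(2, self.K_BOUNDS[0])
            hi.insert(2, self.K_BOUNDS[1])
        return np.array(lo), np.array(hi)

    def _residual(self, x: np.ndarray) -> np.ndarray:
        try:
            params = self._unpack(x)
        except ValueError:
            return np.full_like(self.rates, 1e8)
        return self.rates - _rate(self.kind, self.concentrations, params)

    def fit(self, n_starts: int = 32, seed: int | None = 0,
            start: ATPaseParams | None = None) -> AtpaseKineticsResults:
        """Multi-start bounded least squares.

        Initial points are drawn log-uniformly inside the fit box
        (``v_basal`` uniformly); the best-of-starts solution is returned.
        ``start`` adds a user-supplied initial point to the pool.
        """
        lo, hi = self._bounds()
        degenerate = np.allclose(self.rates, self.rates[0])
        if degenerate:
            warnings.warn(
                "all rates identical: concentration dependence unidentifiable",
                DegenerateDataWarning,
            )
        rng = np.random.default_rng(seed)
        starts: list[np.ndarray] = []
        if start is not None:
            starts.append(np.clip(self._pack(start), lo, hi))
        # heuristic start: amplitude/half-rise from the data themselves
        starts.append(self._heuristic_start(lo, hi))
        while len(starts) < max(n_starts, 1):
            x0 = 10 ** rng.uniform(np.log10(np.maximum(lo, 1e-8)), np.log10(np.maximum(hi, 1e-8)))
            x0[-1] = rng.uniform(lo[-1], hi[-1])  # v_basal uniform, lower bound 0
            starts.append(np.clip(x0, lo, hi))

        best = None
        for x0 in starts:
            try:
                sol = optimize.least_squares(self._residual, x0, bounds=(lo, hi),
                                             method="trf", x_scale="jac")
            except Exception:
                continue
            if best is None or sol.cost < best.cost:
                best = sol
        if best is None:
            raise RuntimeError("all optimisation starts failed")

        params = self._unpack(best.x)
        rss = float(2.0 * best.cost)
        se = self._standard_errors(best, rss)
        converged = bool(best.success) and not degenerate
        return AtpaseKineticsResults(
            model=self, params=params, standard_errors=se, rss=rss,
            model_kind=self.kind, n_points=self.rates.size,
            converged=converged, n_starts=len(starts),
        )

    def _heuristic_start(self, lo: np.ndarray, hi: np.ndarray) -> np.ndarray:
        vb = float(np.min(self.rates))
        vmax = max(float(np.max(self.rates)) - vb, 1.0)
        pos = self.concentrations[self.concentrations > 0]
        km = float(np.median(pos)) if pos.size else 1.0
        x0 = [vmax, km, vb]
        if self.kind == "biphasic":
            peak = float(self.concentrations[np.argmax(self.rates)])
            ki = max(peak**2 / km, km)
            x0.insert(2, ki)
        return np.clip(np.array(x0, float), lo, hi)

    def _standard_errors(self, sol, rss: float) -> dict[str, float]:
        names = ["v_max", "k_m", "v_basal"]
        if self.kind == "biphasic":
            names.insert(2, "k_i")
        dof = self.rates.size - len(names)
        if dof <= 0:
            return {n: float("nan") for n in names}
        J = sol.jac
        try:
            cov = np.linalg.inv(J.T @ J) * rss / dof
            se = np.sqrt(np.clip(np.diag(cov), 0, None))
        except np.linalg.LinAlgError:
            se = np.full(len(names), np.nan)
        return dict(zip(names, se))


def fit_atpase(dataset, model_kind: ModelKind, n_starts: int = 32,
               seed: int | None = 0) -> AtpaseKineticsResults:
    """Fit an :class:`~pgpflux.synth.ATPaseDataset` with the chosen rate law."""
    return AtpaseKinetics.from_dataset(dataset, model_kind).fit(n_starts=n_starts, seed=seed)


def aicc_from_rss(rss: float, n: int, n_params: int) -> float:
    """AICc for a Gaussian least-squares fit; ``n_params`` excludes sigma."""
    k = n_params + 1
    if n - k - 1 <= 0:
        return float("inf")
    rss = max(rss, np.finfo(float).tiny)
    return n * math.log(rss / n) + 2 * k + 2 * k * (k + 1) / (n - k - 1)


@dataclass
class KineticModelSelection:
    """Outcome of the monophasic-vs-biphasic comparison."""

    selected: ModelKind
    monophasic: AtpaseKineticsResults
    biphasic: AtpaseKineticsResults
    delta_aicc: float  # aicc(biphasic) - aicc(monophasic)

    def summary(self) -> str:
        return (
            f"selected: {self.selected}\n"
            f"rss  monophasic={self.monophasic.rss:.6g}  biphasic={self.biphasic.rss:.6g}\n"
            f"AICc monophasic={self.monophasic.aicc:.4g}  biphasic={self.biphasic.aicc:.4g}\n"
            f"delta AICc (biphasic - monophasic) = {self.delta_aicc:.4g}"
        )


def select_kinetic_model(dataset, n_starts: int = 32, seed: int | None = 0) -> KineticModelSelection:
    """Fit both rate laws and select by AICc (lower wins; tie -> monophasic)."""
    mono = fit_atpase(dataset, "monophasic", n_starts=n_starts, seed=seed)
    bi = fit_atpase(dataset, "biphasic", n_starts=n_starts, seed=seed)
    delta = bi.aicc - mono.aicc
    selected: ModelKind = "biphasic" if delta < 0 else "monophasic"
    return KineticModelSelection(selected=selected, monophasic=mono, biphasic=bi,
                                 delta_aicc=delta)
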
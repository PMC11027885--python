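"""Compartmental mass-action model of Pgp-mediated analyte transport.

The sensor-captured proteoliposome is described by five analyte
locations — bulk solvent, the sensor surface, the outer leaflet, the
inner leaflet and the aqueous inner space — connected by six reversible
reactions:

r1  bulk         <->  sensor surface        (mass transport)
r2  surface      <->  outer leaflet (S_LO)  (partitioning onto lipid)
r3  S_LO + Pgp   <->  Pgp complex  (S_PGP)  (substrate capture)
r4  S_PGP         ->  inner space  (S_IN)   "vacuum cleaner" topology
    S_PGP         ->  inner leaflet (S_LI)  "flippase" topology
r5  S_LO         <->  S_LI                  (transbilayer flip-flop)
r6  S_LI         <->  S_IN                  (desorption into the lumen)

The two topologies differ only in where the transport step r4 deposits
its product: directly into the vesicle lumen (vacuum cleaner) or into
the inner leaflet (flippase).

Leaflets are finite: each carries a pool of acceptor sites, and
partitioning steps are bimolecular in the incoming species and the free
site pool, which is what gives the printed k_on units of M^-1 s^-1.
Pgp is likewise a finite pool; only the inside-out oriented fraction
(default 80%) participates.  The transport step r4 and the desorption
step r6 are first-order in their substrate species by default —
``rate_convention="second-order"`` rescales them by an acceptor
concentration instead (see :func:`build_reaction_network`).

The SPR observable is a linear readout of all liposome-associated
analyte::

    RU(t) = k * (S_IN + S_LO + S_PGP + S_LI)(t) + C

The bulk-surface species and the free pools carry no signal.

During the association phase the bulk concentration at the sensor is
held at the injected analyte concentration (the flow cell replenishes
analyte); at the end of association it switches to zero and the trace
decays — the standard constant-source boundary of flow SPR.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, replace
from typing import Literal, Sequence

import numpy as np
from scipy.integrate import solve_ivp

__all__ = [
    "Topology",
    "RatePair",
    "ReactionRates",
    "PoolTotals",
    "PhaseSchedule",
    "ObservableParams",
    "ReactionNetwork",
    "Trajectory",
    "build_reaction_network",
    "simulate_timecourse",
    "simulate_timecourse_fixed_step",
    "observable_ru",
    "end_of_association_amplitude",
    "SPECIES",
    "SIGNAL_SPECIES",
    "REACTION_LABELS",
]

Topology = Literal["vacuum", "flippase"]

#: state-vector species, in order; "bulk" is a held boundary and not a state
SPECIES = ("S_SURF", "S_LO", "S_PGP", "S_LI", "S_IN", "PGP_FREE", "LO_FREE", "LI_FREE")

#: species entering the RU observable
SIGNAL_SPECIES = ("S_IN", "S_LO", "S_PGP", "S_LI")

#: human-readable reaction descriptions, keyed r1..r6 (r4 per topology)
REACTION_LABELS = {
    "r1": "Diffuse from bulk to sensor surface",
    "r2": "Diffuse from outside to outer leaflet",
    "r3": "Binding to Pgp",
    "r4_vacuum": "Pgp transport to inside the proteoliposome",
    "r4_flippase": "Pgp transport to the inner leaflet",
    "r5": "Diffuse from outer leaflet to inner leaflet",
    "r6": "Diffuse from inner leaflet to inside the proteoliposome",
}


@dataclass(frozen=True)
class RatePair:
    """Forward/reverse rate constants of one reversible step.

    ``kon`` is M^-1 s^-1 for the bimolecular steps (r2, r3, r5) and
    s^-1 for r1, r4 and r6 under the default convention; ``koff`` is
    always s^-1.
    """

    kon: float
    koff: float

    def __post_init__(self) -> None:
        for name, v in (("kon", self.kon), ("koff", self.koff)):
            if v < 0 or not math.isfinite(v):
                raise ValueError(f"{name} must be finite and >= 0, got {v}")


_FAST_R1 = RatePair(kon=1.0, koff=1.0)  # non-limiting mass transport default


@dataclass(frozen=True)
class ReactionRates:
    """The six forward/reverse rate-constant pairs of one topology."""

    r1: RatePair = _FAST_R1
    r2: RatePair = RatePair(0.0, 0.0)
    r3: RatePair = RatePair(0.0, 0.0)
    r4: RatePair = RatePair(0.0, 0.0)
    r5: RatePair = RatePair(0.0, 0.0)
    r6: RatePair = RatePair(0.0, 0.0)

    def pair(self, name: str) -> RatePair:
        return getattr(self, name)

    def with_value(self, name: str, value: float) -> "ReactionRates":
        """Return a copy with one constant replaced; ``name`` like ``"r4.kon"``."""
        rname, which = name.split(".")
        pair = self.pair(rname)
        return replace(self, **{rname: replace(pair, **{which: value})})

    def value(self, name: str) -> float:
        rname, which = name.split(".")
        return getattr(self.pair(rname), which)

    def as_dict(self) -> dict[str, dict[str, float]]:
        return {r: {"kon": self.pair(r).kon, "koff": self.pair(r).koff}
                for r in ("r1", "r2", "r3", "r4", "r5", "r6")}

    @classmethod
    def from_dict(cls, d: dict) -> "ReactionRates":
        return cls(**{r: RatePair(**d[r]) for r in d})


@dataclass(frozen=True)
class PoolTotals:
    """Capacity parameters, all in M (single effective volume).

    ``pgp_total`` is the reconstituted Pgp concentration; only
    ``active_fraction`` of it (the inside-out oriented molecules, with
    nucleotide-binding domains facing the ATP-containing buffer) can
    bind and transport substrate.  Each leaflet carries a finite pool of
    lipid acceptor sites.
    """

    pgp_total: float = 20e-6
    active_fraction: float = 0.8
    outer_sites: float = 2e-3
    inner_sites: float = 2e-3

    def __post_init__(self) -> None:
        if self.pgp_total <= 0 or self.outer_sites <= 0 or self.inner_sites <= 0:
            raise ValueError("pool totals must be positive")
        if not 0 < self.active_fraction <= 1:
            raise ValueError("active_fraction must lie in (0, 1]")

    @property
    def pgp_active(self) -> float:
        return self.active_fraction * self.pgp_total


@dataclass(frozen=True)
class PhaseSchedule:
    """Association/dissociation timing of one injection cycle (seconds)."""

    association_end: float = 1200.0
    trace_end: float = 2000.0

    def __post_init__(self) -> None:
        if not 0 < self.association_end < self.trace_end:
            raise ValueError("need 0 < association_end < trace_end")


@dataclass(frozen=True)
class ObservableParams:
    """Linear RU readout: scaling ``k`` (RU per M) and baseline ``c`` (RU)."""

    k: float
    c: float = 0.0

    def __post_init__(self) -> None:
        if self.k < 0 or not math.isfinite(self.k):
            raise ValueError(f"k must be finite and >= 0, got {self.k}")


# ---------------------------------------------------------------------------
# Network construction


@dataclass(frozen=True)
class ReactionNetwork:
    """Stoichiometry and rate laws of one topology, ready to simulate."""

    topology: Topology
    rates: ReactionRates
    pools: PoolTotals
    rate_convention: Literal["first-order", "second-order"] = "first-order"
    lumen_reference_conc: float = 1.0  # M; acceptor scale for r4/r6 when second-order

    @property
    def initial_state(self) -> np.ndarray:
        y0 = np.zeros(len(SPECIES))
        y0[SPECIES.index("PGP_FREE")] = self.pools.pgp_active
        y0[SPECIES.index("LO_FREE")] = self.pools.outer_sites
        y0[SPECIES.index("LI_FREE")] = self.pools.inner_sites
        return y0

    # stoichiometry over (bulk + state species) x 6 reactions, forward direction
    def stoichiometry(self) -> tuple[list[str], np.ndarray]:
        species = ["BULK", *SPECIES]
        idx = {s: i for i, s in enumerate(species)}
        S = np.zeros((len(species), 6))

        def add(j, consumed, produced):
            for s in consumed:
                S[idx[s], j] -= 1
            for s in produced:
                S[idx[s], j] += 1

        add(0, ["BULK"], ["S_SURF"])                       # r1
        add(1, ["S_SURF", "LO_FREE"], ["S_LO"])            # r2
        add(2, ["S_LO", "PGP_FREE"], ["S_PGP", "LO_FREE"])  # r3
        if self.topology == "vacuum":
            add(3, ["S_PGP"], ["PGP_FREE", "S_IN"])        # r4
        else:
            add(3, ["S_PGP", "LI_FREE"], ["PGP_FREE", "S_LI"])
        add(4, ["S_LO", "LI_FREE"], ["S_LI", "LO_FREE"])   # r5
        add(5, ["S_LI"], ["S_IN", "LI_FREE"])              # r6
        return species, S

    def fluxes(self, y: np.ndarray, c_bulk: float) -> np.ndarray:
        """Net forward flux of each reaction (M/s) at state ``y``."""
        s_surf, s_lo, s_pgp, s_li, s_in, p_free, lo_free, li_free = y
        r = self.rates
        po = self.pools
        # saturating occupancy factors guard the finite pools on reverse steps
        phi_p = p_free / po.pgp_active
        phi_lo = lo_free / po.outer_sites
        phi_li = li_free / po.inner_sites

        v1 = r.r1.kon * c_bulk - r.r1.koff * s_surf
        v2 = r.r2.kon * s_surf * lo_free - r.r2.koff * s_lo
        v3 = r.r3.kon * s_lo * p_free - r.r3.koff * s_pgp * phi_lo
        if self.rate_convention == "second-order":
            k4f = r.r4.kon * (li_free if self.topology == "flippase"
                              else self.lumen_reference_conc)
            k6f = r.r6.kon * self.lumen_reference_conc
        else:
            k4f = r.r4.kon * (phi_li if self.topology == "flippase" else 1.0)
            k6f = r.r6.kon
        if self.topology == "vacuum":
            v4 = k4f * s_pgp - r.r4.koff * s_in * phi_p
        else:
            v4 = k4f * s_pgp - r.r4.koff * s_li * phi_p
        v5 = r.r5.kon * s_lo * li_free - r.r5.koff * s_li * phi_lo
        v6 = k6f * s_li - r.r6.koff * s_in * phi_li
        return np.array([v1, v2, v3, v4, v5, v6])

    def rhs(self, t: float, y: np.ndarray, c_bulk: float) -> np.ndarray:
        v1, v2, v3, v4, v5, v6 = self.fluxes(y, c_bulk)
        flip = self.topology == "flippase"
        d_surf = v1 - v2
        d_lo = v2 - v3 - v5
        d_pgp = v3 - v4
        d_li = v5 - v6 + (v4 if flip else 0.0)
        d_in = v6 + (0.0 if flip else v4)
        d_p = -v3 + v4
        d_lofree = -v2 + v3 + v5
        d_lifree = -v5 + v6 - (v4 if flip else 0.0)
        return np.array([d_surf, d_lo, d_pgp, d_li, d_in, d_p, d_lofree, d_lifree])

    # -- export ------------------------------------------------------------

    def reaction_table(self) -> "object":
        """Reaction list with rate constants as a pandas DataFrame."""
        import pandas as pd

        rows = []
        for j, name in enumerate(("r1", "r2", "r3", "r4", "r5", "r6")):
            key = f"r4_{self.topology}" if name == "r4" else name
            pair = self.rates.pair(name)
            rows.append({"reaction": name, "description": REACTION_LABELS[key],
                         "kon": pair.kon, "koff": pair.koff})
        return pd.DataFrame(rows)

    def to_flat_json(self) -> str:
        """SBML-like flat JSON: compartments, species, reactions, constants."""
        species, S = self.stoichiometry()
        reactions = []
        for j, name in enumerate(("r1", "r2", "r3", "r4", "r5", "r6")):
            key = f"r4_{self.topology}" if name == "r4" else name
            pair = self.rates.pair(name)
            reactions.append({
                "id": name,
                "name": REACTION_LABELS[key],
                "reversible": True,
                "kon": pair.kon,
                "koff": pair.koff,
                "stoichiometry": {s: int(S[i, j]) for i, s in enumerate(species)
                                  if S[i, j] != 0},
            })
        doc = {
            "topology": self.topology,
            "compartments": ["bulk", "sensor_surface", "outer_leaflet",
                             "inner_leaflet", "inner_space"],
            "species": list(species),
            "pools": {"pgp_total": self.pools.pgp_total,
                      "active_fraction": self.pools.active_fraction,
                      "outer_sites": self.pools.outer_sites,
                      "inner_sites": self.pools.inner_sites},
            "rate_convention": self.rate_convention,
            "reactions": reactions,
        }
        return json.dumps(doc, indent=2)


def build_reaction_network(topology: Topology, rates: ReactionRates,
                           pools: PoolTotals | None = None,
                           rate_convention: Literal["first-order", "second-order"] = "first-order",
                           ) -> ReactionNetwork:
    """Assemble the six-reaction network for one transport topology.

    ``rate_convention`` controls the transport (r4) and desorption (r6)
    forward steps: ``"first-order"`` (default) treats their k_on as
    s^-1; ``"second-order"`` treats them as M^-1 s^-1 and multiplies by
    the destination acceptor concentration — the free inner-leaflet site
    pool for the flippase transport step, or a fixed aqueous reference
    concentration for steps that deposit into the lumen.
    """
    if topology not in ("vacuum", "flippase"):
        raise ValueError(f"unknown topology {topology!r}")
    return ReactionNetwork(topology=topology, rates=rates,
                           pools=pools or PoolTotals(),
                           rate_convention=rate_convention)


# ---------------------------------------------------------------------------
# Simulation


@dataclass
class Trajectory:
    """Deterministic time course of all compartment species."""

    times: np.ndarray          # s
    states: np.ndarray         # (n_times, n_species), M
    network: ReactionNetwork
    phases: PhaseSchedule
    injected_concentration: float  # M

    def species(self, name: str) -> np.ndarray:
        return self.states[:, SPECIES.index(name)]

    @property
    def signal_concentration(self) -> np.ndarray:
        """Sum of the four RU-visible species, M."""
        idx = [SPECIES.index(s) for s in SIGNAL_SPECIES]
        return self.states[:, idx].sum(axis=1)

    @property
    def total_analyte(self) -> np.ndarray:
        idx = [SPECIES.index(s) for s in ("S_SURF", "S_LO", "S_PGP", "S_LI", "S_IN")]
        return self.states[:, idx].sum(axis=1)

    def conservation_error(self) -> dict[str, float]:
        """Max relative drift of the three conserved pools over the trace."""
        po = self.network.pools
        pgp = self.species("PGP_FREE") + self.species("S_PGP")
        lo = self.species("LO_FREE") + self.species("S_LO")
        li = self.species("LI_FREE") + self.species("S_LI")
        if self.network.topology == "flippase":
            pass  # r4 moves S_PGP -> S_LI consuming LI_FREE: both sums still conserved
        return {
            "pgp": float(np.max(np.abs(pgp - po.pgp_active)) / po.pgp_active),
            "outer_sites": float(np.max(np.abs(lo - po.outer_sites)) / po.outer_sites),
            "inner_sites": float(np.max(np.abs(li - po.inner_sites)) / po.inner_sites),
        }


class IntegrationError(RuntimeError):
    pass


def _bulk_concentration(t: float, phases: PhaseSchedule, c_inj: float) -> float:
    return c_inj if t < phases.association_end else 0.0


def simulate_timecourse(network: ReactionNetwork, phases: PhaseSchedule,
                        injected_concentration: float,
                        grid: Sequence[float] | None = None,
                        dt: float = 0.5,
                        rtol: float = 1e-8, atol: float = 1e-14,
                        method: str = "LSODA",
                        negative_tolerance: float = 1e-9,
                        on_negative: Literal["clip", "raise"] = "clip") -> Trajectory:
    """Integrate the network deterministically over one injection cycle.

    The bulk boundary concentration is held at ``injected_concentration``
    (M) during association and at zero afterwards; the two phases are
    integrated piecewise so the switch is exact.  ``grid`` is the output
    time grid (s); when omitted, a uniform grid with step ``dt`` over
    ``[0, trace_end]``.  Small negative excursions (below
    ``negative_tolerance`` in magnitude) are clipped; larger ones clip
    with a warning or raise, per ``on_negative``.
    """
    if grid is None:
        grid = np.arange(0.0, phases.trace_end + 0.5 * dt, dt)
    t_eval = np.asarray(grid, dtype=float)
    if t_eval.ndim != 1 or t_eval.size < 2 or np.any(np.diff(t_eval) <= 0):
        raise ValueError("grid must be strictly increasing with >= 2 points")
    if t_eval[0] < 0 or t_eval[-1] > phases.trace_end + 1e-9:
        raise ValueError("grid must lie within [0, trace_end]")
    if injected_concentration < 0:
        raise ValueError("injected_concentration must be >= 0")

    t_switch = phases.association_end
    y0 = network.initial_state
    out = np.empty((t_eval.size, y0.size))

    segments = [
        (0.0, t_switch, injected_concentration,
         (t_eval <= t_switch)),
        (t_switch, t_eval[-1], 0.0,
         (t_eval > t_switch)),
    ]
    y_start = y0
    for t0, t1, c_bulk, mask in segments:
        if t1 <= t0:
            continue
        eval_here = t_eval[mask]
        # always integrate to t1 so the next segment starts exactly at the switch
        sol = solve_ivp(network.rhs, (t0, t1), y_start, method=method,
                        t_eval=eval_here if eval_here.size else None,
                        args=(c_bulk,), rtol=rtol, atol=atol, dense_output=False)
        if not sol.success:
            raise IntegrationError(f"ODE solver failed on [{t0}, {t1}]: {sol.message}")
        if eval_here.size:
            out[mask] = sol.y.T
            if not np.isclose(sol.t[-1], t1):
                # re-integrate the remainder to land on the switch point
                sol2 = solve_ivp(network.rhs, (sol.t[-1], t1), sol.y[:, -1],
                                 method=method, args=(c_bulk,), rtol=rtol, atol=atol)
                if not sol2.success:
                    raise IntegrationError(f"ODE solver failed: {sol2.message}")
                y_start = sol2.y[:, -1]
            else:
                y_start = sol.y[:, -1]
        else:
            y_start = sol.y[:, -1]

    worst = float(out.min())
    if worst < -abs(negative_tolerance):
        if on_negative == "raise":
            raise IntegrationError(f"negative species concentration {worst:.3e}")
        import warnings
        warnings.warn(f"clipping negative species concentration {worst:.3e}")
    np.clip(out, 0.0, None, out=out)
    return Trajectory(times=t_eval, states=out, network=network, phases=phases,
                      injected_concentration=injected_concentration)


def _fastest_linear_rate(network: ReactionNetwork, c_inj: float) -> float:
    """Crude upper bound on the fastest first-order decay rate (s^-1).

    Bounds each bimolecular step by its pseudo-first-order rate at full
    pools / injected concentration; used to pick a stable explicit step.
    """
    r, po = network.rates, network.pools
    big = max(po.outer_sites, po.inner_sites, po.pgp_active, c_inj)
    cands = [r.r1.koff,
             r.r2.kon * big, r.r2.koff,
             r.r3.kon * big, r.r3.koff,
             r.r4.kon, r.r4.koff,
             r.r5.kon * big, r.r5.koff,
             r.r6.kon, r.r6.koff]
    return max(cands)


def simulate_timecourse_fixed_step(network: ReactionNetwork, phases: PhaseSchedule,
                                   injected_concentration: float,
                                   grid: Sequence[float] | None = None,
                                   dt: float = 0.06,
                                   stability_margin: float = 0.5) -> Trajectory:
    """Classical fixed-step RK4 integration (independent reference integrator).

    Marches with step ``dt``, splitting exactly at the association/
    dissociation switch, and linearly subsamples onto ``grid`` (default:
    a uniform ``dt`` grid).  As a non-adaptive explicit method it must
    respect the stability limit of the fastest reaction: when
    ``dt`` times the fastest linear rate exceeds ``stability_margin``
    the step is uniformly subdivided until it does not.  Deliberately
    simple — an independent cross-check for the adaptive solver, not a
    production path.
    """
    rate_bound = _fastest_linear_rate(network, injected_concentration)
    substeps = max(1, int(math.ceil(dt * rate_bound / stability_margin)))
    h_nominal = dt / substeps

    r, po = network.rates, network.pools
    k1on, k1off = r.r1.kon, r.r1.koff
    k2on, k2off = r.r2.kon, r.r2.koff
    k3on, k3off = r.r3.kon, r.r3.koff
    k4on, k4off = r.r4.kon, r.r4.koff
    k5on, k5off = r.r5.kon, r.r5.koff
    k6on, k6off = r.r6.kon, r.r6.koff
    p_tot, lo_tot, li_tot = po.pgp_active, po.outer_sites, po.inner_sites
    flip = network.topology == "flippase"
    second = network.rate_convention == "second-order"
    lumen = network.lumen_reference_conc

    def deriv(y, c_bulk):
        s_surf, s_lo, s_pgp, s_li, s_in, p_free, lo_free, li_free = y
        phi_p = p_free / p_tot
        phi_lo = lo_free / lo_tot
        phi_li = li_free / li_tot
        v1 = k1on * c_bulk - k1off * s_surf
        v2 = k2on * s_surf * lo_free - k2off * s_lo
        v3 = k3on * s_lo * p_free - k3off * s_pgp * phi_lo
        if second:
            k4f = k4on * (li_free if flip else lumen)
            k6f = k6on * lumen
        else:
            k4f = k4on * (phi_li if flip else 1.0)
            k6f = k6on
        v4 = k4f * s_pgp - k4off * (s_li if flip else s_in) * phi_p
        v5 = k5on * s_lo * li_free - k5off * s_li * phi_lo
        v6 = k6f * s_li - k6off * s_in * phi_li
        return (v1 - v2,
                v2 - v3 - v5,
                v3 - v4,
                v5 - v6 + (v4 if flip else 0.0),
                v6 + (0.0 if flip else v4),
                -v3 + v4,
                -v2 + v3 + v5,
                -v5 + v6 - (v4 if flip else 0.0))

    t_end = phases.trace_end
    knots = np.unique(np.concatenate([
        np.arange(0.0, phases.association_end, dt), [phases.association_end],
        np.arange(phases.association_end, t_end, dt), [t_end],
    ]))
    ys = np.empty((knots.size, len(SPECIES)))
    y = tuple(network.initial_state)
    ys[0] = y
    for i in range(knots.size - 1):
        t0, t1 = knots[i], knots[i + 1]
        c = _bulk_concentration(t0, phases, injected_concentration)
        nsub = max(1, int(math.ceil((t1 - t0) / h_nominal - 1e-12)))
        h = (t1 - t0) / nsub
        for _ in range(nsub):
            kk1 = deriv(y, c)
            kk2 = deriv(tuple(a + 0.5 * h * b for a, b in zip(y, kk1)), c)
            kk3 = deriv(tuple(a + 0.5 * h * b for a, b in zip(y, kk2)), c)
            kk4 = deriv(tuple(a + h * b for a, b in zip(y, kk3)), c)
            y = tuple(a + h / 6.0 * (b1 + 2 * b2 + 2 * b3 + b4)
                      for a, b1, b2, b3, b4 in zip(y, kk1, kk2, kk3, kk4))
        ys[i + 1] = y
    ys = np.clip(ys, 0.0, None)
    if grid is None:
        t_eval, states = knots, ys
    else:
        t_eval = np.asarray(grid, dtype=float)
        states = np.column_stack([np.interp(t_eval, knots, ys[:, j])
                                  for j in range(ys.shape[1])])
    return Trajectory(times=t_eval, states=states, network=network, phases=phases,
                      injected_concentration=injected_concentration)


def observable_ru(trajectory: Trajectory, obs: ObservableParams) -> np.ndarray:
    """Map a trajectory to the RU sensorgram: ``k * signal + C``."""
    return obs.k * trajectory.signal_concentration + obs.c


def end_of_association_amplitude(times: np.ndarray, ru: np.ndarray,
                                 phases: PhaseSchedule) -> float:
    """Baseline-referenced amplitude: RU at association end minus RU at t=0."""
    times = np.asarray(times, float)
    ru = np.asarray(ru, float)
    if times.shape != ru.shape:
        raise ValueError("times and ru must have equal shape")
    if times[-1] < phases.association_end or times[0] > 0:
        raise ValueError("trace does not cover [0, association_end]")
    ru_end = float(np.interp(phases.association_end, times, ru))
    ru_0 = float(np.interp(0.0, times, ru))
    return ru_end - ru_0
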
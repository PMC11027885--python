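"""Bundled example parameter sets for three well-characterised Pgp substrates.

These values are the package's canonical demonstration inputs: ATPase
rate-law parameters for methadone, desipramine (monophasic) and
quinidine (biphasic) as measured on mouse Pgp proteoliposomes, and
per-substrate rate-constant sets of the vacuum-cleaner transport
network as obtained from global sensorgram fits of the same system.
They drive the synthetic-data generators, the worked examples and the
recovery experiments; they are inputs, not outputs, of this package.
"""

from __future__ import annotations

from .atpase import ATPaseParams
from .transport import PhaseSchedule, RatePair, ReactionRates

__all__ = [
    "ATPASE_PARAMS",
    "ATPASE_NOISE_SD",
    "VACUUM_RATES",
    "DEMO_RATES",
    "DISCRIMINATION_RATES",
    "DEFAULT_PHASES",
]

#: drug-stimulated ATPase parameters (rates nmol·min^-1·mg^-1, K's μM);
#: the shared basal rate is 482
ATPASE_PARAMS: dict[str, ATPaseParams] = {
    "methadone": ATPaseParams(v_max=849.0, k_m=28.0, v_basal=482.0),
    "desipramine": ATPaseParams(v_max=904.0, k_m=12.0, v_basal=482.0),
    "quinidine": ATPaseParams(v_max=626.0, k_m=2.9, k_i=131.0, v_basal=482.0),
}

#: Gaussian noise level (rate units) used for simulated ATPase assays —
#: comparable to the replicate scatter of bench Chifflet measurements
ATPASE_NOISE_SD = 25.0

_FAST_R1 = RatePair(kon=1.0, koff=1.0)

#: vacuum-cleaner rate constants per substrate (kon M^-1 s^-1 for the
#: bimolecular steps; r4/r6 forward treated as s^-1); r1 is the fast,
#: non-limiting mass-transport default
VACUUM_RATES: dict[str, ReactionRates] = {
    "desipramine": ReactionRates(
        r1=_FAST_R1,
        r2=RatePair(1.15e-6, 4.1e-6),
        r3=RatePair(8.9e-3, 129.0),
        r4=RatePair(3.57e-5, 6.44e-8),
        r5=RatePair(4.00e-5, 2.68),
        r6=RatePair(1.10e-5, 1.09),
    ),
    "methadone": ReactionRates(
        r1=_FAST_R1,
        r2=RatePair(5.07e-5, 8.34e-6),
        r3=RatePair(1.61e-6, 6.39e5),
        r4=RatePair(2.75e-4, 1.89e-4),
        r5=RatePair(1.83e-7, 8.81e-7),
        r6=RatePair(0.0, 493.0),
    ),
    "quinidine": ReactionRates(
        r1=_FAST_R1,
        r2=RatePair(4.62e-8, 1.20e-5),
        r3=RatePair(6.69e-4, 823.0),
        r4=RatePair(1.6e-3, 7.91e-8),
        r5=RatePair(0.01, 164.0),
        r6=RatePair(1.1e-3, 0.13),
    ),
}

#: well-conditioned synthetic rate set: occupancies reach an appreciable
#: fraction of the pools and every step leaves a visible kinetic
#: signature within the 2,000 s injection cycle, so recovery and
#: identifiability behaviour can be studied away from degenerate corners
DEMO_RATES = ReactionRates(
    r1=RatePair(0.5, 0.5),
    r2=RatePair(10.0, 5e-3),
    r3=RatePair(2e4, 1e-2),
    r4=RatePair(5e-2, 0.0),
    r5=RatePair(5.0, 2e-3),
    r6=RatePair(1e-4, 1e-4),
)

#: transport-dominant set for topology-discrimination experiments: the
#: transport step is fast and irreversible, lumen desorption (r6) slow
#: and flip-flop (r5) freely reversible, so a vacuum-cleaner run traps
#: analyte in the inner space while a flippase run lets it cycle back
#: through the leaflets and dissociate
DISCRIMINATION_RATES = ReactionRates(
    r1=RatePair(0.5, 0.5),
    r2=RatePair(10.0, 5e-3),
    r3=RatePair(5e3, 1e-2),
    r4=RatePair(2e-2, 0.0),
    r5=RatePair(100.0, 2e-3),
    r6=RatePair(1e-5, 1e-4),
)

#: 1,200 s association + 800 s dissociation injection cycle
DEFAULT_PHASES = PhaseSchedule(association_end=1200.0, trace_end=2000.0)
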
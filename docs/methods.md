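# Methods

## Scope and model

`pgpflux` analyses surface-plasmon-resonance (SPR) transport assays for
P-glycoprotein (Pgp) reconstituted inside-out into liposomes that are
captured on a sensor.  The analyte (a candidate Pgp substrate) is
injected over the sensor; mass accumulating in or on the proteoliposome
raises the response-unit (RU) signal.  The package covers four layers
of that analysis:

1. drug-stimulated ATPase kinetics (the functional control assay),
2. a compartmental mass-action model of analyte transport and its
   deterministic simulation,
3. global fitting of multi-concentration sensorgram sets and
   discrimination between the two accepted Pgp translocation
   topologies, and
4. derived assay readouts (double referencing, ATP/no-nucleotide
   amplitude ratios, vesicle-assay transport efficiency).

### ATPase rate laws

Monophasic (Michaelis–Menten with basal turnover):

    v(L) = v_max * L / (K_m + L) + v_basal

Biphasic (uncompetitive substrate inhibition):

    v(L) = v_max / (1 + K_m/L + L/K_I) + v_basal

`L` is drug concentration (μM); rates are nmol·min⁻¹·mg⁻¹.  The
biphasic law has its maximum at `L* = sqrt(K_m K_I)` and reduces to the
monophasic law pointwise as `K_I → ∞`; both identities are enforced in
tests.  At `L = 0` the biphasic expression is defined by its limit,
`v_basal`.

Fits are bounded multi-start nonlinear least squares
(`scipy.optimize.least_squares`, trust-region reflective).  Starting
points are drawn log-uniformly inside the fit box — `v_max` in
[1, 10⁴] rate units, `K_m`, `K_I` in [10⁻², 10⁴] μM — plus one
data-driven heuristic start; `v_basal` is bounded by [0, 2 × minimum
observed rate] and drawn uniformly.  Replicates are pooled with equal
weights.  Standard errors are the usual asymptotic estimates from the
Jacobian at the optimum.  Monophasic-vs-biphasic selection uses AICc
(`n ln(rss/n) + 2k + 2k(k+1)/(n−k−1)`, `k` counting the noise variance);
a quantitative criterion is needed for automation even though curve
shape is often judged by eye at the bench.  When the sampled
concentrations stay far below `sqrt(K_m K_I)` the inhibition term is
invisible and selection correctly collapses to the penalty — the test
suite pins this behaviour rather than hiding it.

### Transport network

Five analyte locations (bulk, sensor surface, outer leaflet, inner
leaflet, vesicle lumen) are connected by six reversible reactions, r1 to
r6 (see `pgpflux.transport`).  The two topologies differ only in the
product compartment of the transport step r4: the vacuum-cleaner model
deposits substrate into the lumen, the flippase model into the inner
leaflet.  Several modelling choices deserve explanation because the
underlying assay constrains them only loosely:

* **Rate-law convention.**  Partitioning steps (r2, r3, r5) are
  bimolecular: the incoming species reacts with a finite pool of free
  acceptor sites (lipid sites per leaflet, free active Pgp), which makes
  their k_on units of M⁻¹·s⁻¹ dimensionally coherent.  The transport
  (r4) and lumen-desorption (r6) forward steps are first-order in their
  substrate species by default; a `rate_convention="second-order"`
  switch instead reads their k_on as M⁻¹·s⁻¹ and multiplies by the
  destination acceptor concentration (the free inner-leaflet pool for
  flippase r4, a fixed 1 M aqueous reference for lumen-bound steps).
  Published rate tables for this assay class print M⁻¹·s⁻¹ throughout,
  which is internally inconsistent for first-order steps; both readings
  are therefore implemented behind the switch.
* **Reverse steps and pool safety.**  Reverse rate constants are s⁻¹.
  A reverse step that re-occupies a finite pool (e.g. substrate leaving
  Pgp back into the outer leaflet) is scaled by the free-site fraction
  of that pool, a dimensionless factor that is ≈1 away from saturation
  and guarantees non-negative pools near it.
* **Volumes.**  Compartment volumes are not resolvable from the assay;
  all concentrations live in one effective volume and the only capacity
  parameters are the pool totals.  Defaults: Pgp 20 μM (the ligand
  immobilisation concentration), active fraction 0.8 (the inside-out
  oriented share with nucleotide-binding domains facing the external
  ATP — only those pump), lipid sites 100 × Pgp per leaflet
  (configurable).  The 80% restraint is a fixed constant, never fitted.
* **Boundary condition.**  During association the flow cell replenishes
  analyte, so the bulk concentration at the surface is held constant at
  the injected value; at the association/dissociation switch it drops
  to zero.  The two phases are integrated piecewise so the switch is
  exact.  r1 (bulk ↔ surface exchange) defaults to fast, non-limiting
  rates and its species is excluded from the observable.
* **Observable.**  `RU(t) = k (S_IN + S_LO + S_PGP + S_LI) + C` — all
  liposome-associated analyte contributes equally per mole; the scaling
  `k` and baseline `C` are per-trace (local) parameters.

Simulation uses `scipy.integrate.solve_ivp` (LSODA, rtol 1e-8,
atol 1e-14 by default).  Conserved quantities (free+bound Pgp,
per-leaflet site totals) track to better than 1e-9 relative.  An
independent fixed-step RK4 integrator cross-checks the adaptive solver;
being explicit, it subdivides its step whenever the fastest linear rate
would violate its stability bound.  Oracle comparisons that involve
species many orders of magnitude below the default absolute tolerance
are run with tightened tolerances (rtol 1e-10, atol 1e-28).

Default output grid: 0.5 s for generated data (4,001 points per
2,000 s cycle); the dense 0.06 s grid used by interactive simulators of
this assay class remains available via the `dt`/`grid` arguments.

### Global sensorgram fitting

All traces of a concentration series are fit simultaneously: kinetic
rate constants are shared (global), `k` and `C` are free per trace
(local).  Because the observable is linear in the locals they are
profiled out exactly by a per-trace linear least-squares solve (with
`k ≥ 0` enforced), so the optimiser searches only the log10 rate space.
By default the ten constants of r2–r6 are free inside finite log-boxes
(10⁻⁹–10⁴) and r1 is fixed as fast mass transport, mirroring how rate
tables for this assay report only r2–r6.  The fit window is the
association+dissociation span (0–2,000 s), unweighted least squares.

The default global optimiser is classic evolutionary programming
(self-adaptive per-coordinate Gaussian mutation, (μ+μ) q-tournament
survival, population 40 × 500 generations), matching the algorithm
family that fits this problem class well; seeded differential evolution
and multi-start Nelder–Mead are drop-in alternatives, and all runs are
reproducible from their seed.  A trust-region least-squares polish
refines the best point.  The best-so-far objective history is retained
and is non-increasing by construction.

**Identifiability is reported, not assumed.**  After fitting, each free
rate is displaced ±0.1 log10 units; rates whose displacement moves the
objective by less than 10⁻⁶ of the data's (per-trace de-meaned) total
sum of squares are flagged unidentifiable.  This matters in practice:
sensorgram sets generated from published rate tables of this assay are
often in a nearly linear, low-occupancy regime where the per-trace
scaling absorbs almost all parameter sensitivity, and an honest fit
reports every rate as flat rather than pretending recovery.  Recovery
tests therefore assert ≤5% log-space error only on rates that pass the
flatness check, alongside a fit-quality floor.

**Topology comparison** fits both networks with equi-dimensional specs,
so the AICc ordering equals the RSS ordering (ΔAICc = n·ln(RSS ratio),
asserted algebraically in tests).  No preference is declared when the
RSS difference is below a tolerance relative to the better fit, floored
at 10⁻⁹ of the data's total sum of squares so that two fits sitting at
a near-zero noise floor compare as equivalent.  Per-topology lag-1
residual autocorrelation is reported as a misfit diagnostic.

### Derived readouts

* Double referencing: `sample − reference − blank`, pointwise, with an
  exact time-grid match required (no silent interpolation).
* Transport ratio: end-of-association amplitudes (baseline-referenced)
  per concentration in the ATP and no-nucleotide arms; the default
  statistic is the mean of per-concentration ratios with its SD
  (ratio-of-mean-amplitudes available as a switch — the bench
  convention is ambiguous, so both are implemented).
* Transport efficiency: `(C_initial − C_sample)/C_initial × 100`;
  negative values (net release) are allowed but flagged.
* Vesicle assay: absorbance → concentration through a linear standard
  curve (≥4 dilution points), then a cumulative sampling-dilution
  correction for the volume withdrawn and replaced at each timepoint
  (`C_corr[k] = C_meas[k] + (v_s/v_tot) Σ_{j<k} C_meas[j]`).

## Synthetic data: what it emulates, and what it does not

The generators reproduce the *structure* of the bench experiments: a
five-point two-fold analyte dilution series (500 → 31.25 μM), 1,200 s
association + 800 s dissociation, paired ATP / no-nucleotide arms (the
no-nucleotide arm is the same network with the transport step switched
off), ATPase designs with 12-point concentration grids, and additive
i.i.d. Gaussian noise (SD 25 rate units for ATPase assays; RU-scale
sigma plus optional linear drift for sensorgrams).  Generating
parameters are embedded in the objects and sidecar JSON so recovery
tests need no bookkeeping, and identical seeds give bit-identical data.

Not emulated: injection dispersion, regeneration and buffer-mismatch
artefacts, instrument drift beyond a linear term, replicate-to-replicate
variability of the bench sensorgrams (reported n=5 without tabulated
spread — the replicate variance knob is free, not calibrated), and any
ADP-specific conformational state (nucleotide condition enters only
through the transport step).  Passing recovery tests on these data
therefore demonstrates the correctness and power of the estimators
under the stated noise model, not robustness to every instrument
artefact of a real LSPR run.

Two bundled synthetic rate sets define standard study conditions: a
*well-conditioned* set whose occupancies reach an appreciable fraction
of the pools (every step leaves a visible kinetic signature, ATP/apo
amplitude ratio ≈ 1.5, in the range seen for real substrates), and a
*transport-dominant* set (fast irreversible pump, slow lumen
desorption, freely reversible flip-flop) under which the two topologies
produce clearly different dissociation shapes.  The published
per-substrate rate tables are bundled as simulation inputs and
formatting fixtures; they are not reproduced as fit outputs because the
underlying raw sensorgrams are not deposited.

## Problem sizes used by the test and reproducibility suites

Chosen as the package's standard desk-scale experiment sizes:

* ATPase recovery: 50 simulated assays per drug, 12 concentrations,
  noise SD 25, 8 optimiser starts per fit.
* Transport round trip: published desipramine rates, 5 concentrations,
  full 2,000 s cycle at 2 s sampling (every 4th point scored),
  differential evolution 6×20 plus polish.
* Topology discrimination: 20 replicates, 3 concentrations, RU noise
  SD 30 (≈1% of peak amplitude), equi-dimensional 3-parameter fits,
  differential evolution 6×15 plus polish per topology.
* Oracle agreement: 20 random moderate-rate draws on a compressed
  300 s/500 s cycle, plus the stiff published desipramine set on the
  full cycle.

## Known limitations

* A single effective volume cannot capture leaflet/lumen volume ratios;
  bimolecular constants absorb the unknown scaling.
* Reverse transport through Pgp is modelled mass-action with a
  free-pool factor; for the near-zero reverse constants typical of this
  assay the factor is inert.
* No stochastic (SSA) simulation — the assay operates far above the
  copy-number regime where it would matter.
* Uncertainty for transport-rate estimates is limited to the
  profile-flatness flag; full profile likelihoods or bootstrap are out
  of scope, matching how results of this assay class are reported.
* The evolutionary optimisers make no convergence guarantee; the
  `converged` flag reports budget exhaustion, and comparisons with both
  fits unconverged yield an explicit no-preference outcome.
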
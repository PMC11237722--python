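# Methods

## The model

`phagecomm` simulates a chemostat-like community of two bacterial prey
species, *E* and *S* (dimensionless biomass), a generalist lytic phage
*G* that adsorbs to both, and a specialist phage *P* restricted to *S*:

    dE/dt = mu_E * E * [a_ES*S / (a_ES*S + k_E)] * (R - E - b_ES*S) - s_EG*G*E - d_E*E
    dS/dt = mu_S * S * [a_SE*E / (a_SE*E + k_S)] * (R - S - b_SE*E) - s_SP*P*S - s_SG*G*S - d_S*S
    dG/dt = g_SG*s_SG*G*S + g_EG*s_EG*G*E - d_G*G
    dP/dt = g_SP*s_SP*P*S - d_P*P

Prey grow logistically toward the shared carrying capacity `R`, gated by
a saturating mutualistic benefit from the partner (half-saturation
`kappa`).  Phage convert adsorption (attachment rate `sigma`, per
biomass per time) directly into progeny (burst size `gamma`); there is
no latent period.  A common intrinsic death/dilution rate `delta`
removes every species, as in a chemostat.

Two pure interaction presets are provided:

- **competition** — `kappa = 0` (the gate is identically 1, including at
  the 0/0 point where the partner is absent, so the equations reduce
  exactly to Lotka–Volterra competition), `beta = 1`, `R = 2`;
- **mutualism** — obligate cross-feeding: `kappa = 1`, `beta = 0`,
  `R = 1`.  Neither prey grows alone, which gives the community an Allee
  structure: total extinction is always locally stable, and the
  phage-free symmetric equilibria are the roots of
  `x^2 - 0.94x + 0.06 = 0` (a stable point at 0.8711 and an unstable
  Allee threshold at 0.0689 under the defaults).

`R` is larger under competition so both presets settle at the same total
phage-free prey biomass (1.94 vs 1.74): a structural quirk of
Lotka–Volterra mutualism is that the saturating benefit inflates the
realized carrying capacity above `R`.

Shared defaults: `mu = 0.5`, `gamma = 20`, `sigma = 0.001`,
`delta = 0.03`, `alpha = 1`.  The specialist-on-*E* entries
(`gamma_EP`, `sigma_EP`) are carried in the parameter record for
completeness but are inert: the specialist's dynamics involve only *S*.

**Cost of generalism.**  `apply_cost` grants the specialist an advantage
ratio *r* over the generalist baseline in one of three currencies:
burst size (`gamma_SP = r * gamma_SG`), attachment rate
(`sigma_SP = r * sigma_SG`), or mortality (all species moved to a
reduced chemostat baseline of 0.0067 with `delta_G = r * 0.0067`, so the
generalist alone pays the penalty).  The transform is absolute, not
cumulative, so re-application replaces rather than compounds the cost.

## Numerical integration and "steady state"

LSODA (adaptive, stiffness-switching; `rtol 1e-8`, `atol 1e-10`) with an
extinction floor: a species sampled below 1e-12 is clamped to exactly
zero for the rest of the run and cannot resurge from round-off-sized
tails.  Sub-floor densities are also treated as zero inside the
right-hand side passed to the solver; without this, relaxation-
oscillation troughs in far-from-default parameter draws push the solver
into astronomically deep excursions and occasional overflow.

Steady state is operational: integrate until abundances no longer change
between time points.  Concretely, the run is converged when every
species' range over a trailing 100-time-unit window (sampled every 1) is
below `tol = 1e-9` *and* small relative to the species' own level
(`rel_tol = 1e-3`).  The relative clause keeps slowly decaying
near-extinct tails (e.g. an obligate pair collapsing toward the origin)
integrating until the clamp resolves them, instead of declaring
convergence at a meaningless 1e-11 plateau.  Runs that never settle —
the competition preset with both phage at some parameter combinations
orbits indefinitely — are capped (default `t_max = 1e5`; sweeps use
3e4 per cell) and summarized by the trailing-window time average with
`converged=False` propagated to all downstream tables.

Every scenario starts all present species at density 0.1; absent species
start at exactly 0.

The specialist's standing is summarized as its share of total phage
biomass at steady state, `P/(P+G)`; values above 0.5 mean the specialist
is the more abundant phage.  When both phage are extinct the share is
explicitly undefined (`None`), never a NaN.

## Fixed points, stability, and thresholds

Fixed points are enumerated per presence subset: each of the 16 subsets
of {E, S, G, P} pins its absent species to zero and solves the reduced
algebraic system (`scipy.optimize.root`, hybrid Powell) from a
deterministic lattice of starting points.  Phage lattice points include
attachment-rate-scaled values (phage equilibria scale like growth
surplus / sigma), so roots stay reachable under attachment-cost
transforms.  Roots are kept if non-negative with residual < 1e-9 and
deduplicated at 1e-6.  Stability comes from the analytic Jacobian
(hand-derived; the `kappa = 0` gate linearizes as the constant 1), with
eigenvalue real parts classified stable below -1e-7, marginal within
1e-7 of zero, unstable otherwise.  A finite-difference cross-check of
the Jacobian is part of the test suite.

Note that the competition preset at cost ratio 1 is doubly degenerate:
with `beta = 1` the two prey share one logistic term, giving a neutral
*line* of prey equilibria (E + S = 1.94), and parametrically identical
phage make G/P splits along phage continua neutral as well.  The
enumerator reports sampled points along such continua, all labeled
marginal — this is a property of the model, not a solver artifact.

**S\* invasion criterion.**  Treating prey *S* as the resource shared by
the two phage, the phage able to hold zero net growth at the lower *S*
density excludes the other.  Setting dP/dt = 0 gives
`S_P* = delta / (g_P s_P)`; the generalist also harvests *E*, so
dG/dt = 0 gives `S_G* = delta / (g_G s_G) - E`.  The exclusion
inequality `S_P* < S_G*` rearranges to
`(g_G s_G)/(g_P s_P) < 1 - g_G s_G E / delta`, and the implementation
cross-checks both forms on every call.  It requires the symmetry the
reduction assumes (generalist identical on both prey, one common
`delta`) and rejects asymmetric inputs.

**Cost thresholds.**  `find_cost_threshold` bisects the cost ratio (to a
bracket width of 5e-3) on one of two indicators:

- `density_crossing` — forward simulation from the all-0.1 inoculum:
  steady-state P exceeds G.  Under mutualism this flips at a burst ratio
  of about 2.09.
- `only_stable_is_ESP` — fixed-point analysis: no stable fixed point
  contains the generalist, while the prey-pair + specialist point is
  stable.  The all-extinct origin is disregarded: obligate mutualism
  makes it stable at every parameter value, so a verbatim "every stable
  fixed point is E-S-P" condition would be unsatisfiable.  Because a
  cost in either currency rescales one factor of the specialist's
  `gamma*sigma` product, burst and attachment parameterizations probe
  the same product-scale threshold; the package finds 2.3005 for the
  mutualism preset, identically in both currencies.

The 2.3005 value has a closed form: the E-S-P point has
`S* = delta/(g_P s_P)` and `E* = R - (delta/mu)(1 + 1/S*)`, and the
generalist's invasion eigenvalue `g_G s_G (S* + E*) - delta` crosses
zero exactly where the interior four-species point loses its generalist
component — a transcritical exchange at `S* + E* = delta/(g_G s_G)`,
i.e. the positive root of `rho^2 + 14 rho - 37.5 = 0`.  Commonly quoted
figures nearer 2.8 correspond to evaluating the S\* inequality at a
fixed prey level E = 0.97 rather than at the self-consistent mutualism
E\*; the fixed-point route implemented here does not reproduce them.

## Sweeps

The scenario battery runs the four phage treatments (none, specialist
only, generalist only, both).  1-D sweeps scan the cost ratio (default
30 log-spaced points on [1, 10]); 2-D sweeps cross it with a prey
asymmetry — relative growth rate (`mu_E` against `mu_S = 0.5`) or
relative interaction coefficient (`beta_ES` against `beta_SE = 1` under
competition, `alpha_ES` against `alpha_SE = 1` under mutualism), default
30 points on [0.25, 4].  Cells are fully independent runs; mutualism
cells where the obligate pair collapses entirely are flagged
`infeasible`, and each cell records whether either prey ended below the
extinction floor.

One genuine, perhaps surprising property of the model surfaces here:
under competition with a sufficiently slowed alternative prey
(`mu_E` below about 0.28) there is a stable interior fixed point with
all four species coexisting in which the specialist modestly outnumbers
the generalist (P = 125 vs G = 95 under the defaults, independent of the
cost ratio) while prey E persists far above the extinction floor.
Specialist dominance under competition is therefore not strictly limited
to cells where E is competitively excluded.

## Sensitivity analysis

Morris elementary-effects screening and Sobol variance decomposition are
implemented in-package on the unit hypercube (generic over the model
callable, so closed-form toy models validate the estimators in tests):

- Morris: r trajectories (default 20) on a 4-level grid with
  `delta = 2/3`; parameters ranked by mu\* with sigma as the
  interaction/nonlinearity signal.
- Sobol: Saltelli design from a scrambled Sobol sequence
  (`n_base (p+2)` evaluations; default `n_base = 256`), Saltelli-2010
  first-order and Jansen total-order estimators, bootstrap CIs (default
  100 resamples).

Default ranges span 0.5x–1.5x of each preset default, sampled
log-uniformly; the four `delta` values move together as a single factor.
Mode-defining zeros (beta under mutualism, kappa under competition) are
not perturbed.  The model output is the final biomass of each phage
after a fixed horizon of 2000 time units (not a full steady-state
search: thousands of evaluations make the cheaper, slightly earlier
snapshot the right trade; the default dynamics are settled by then).
All seeds are explicit inputs with default 0; identical seeds give
bit-identical results, and results are invariant to the order in which
ranges are specified (parameters are canonicalized by name).

## Synthetic observables

`simulate_readout` emulates the measurement layer of a plate-reader
phage-competition assay on top of a simulated trajectory:
species-resolved OD-equivalent prey signals every 20 minutes over 48
hours (145 samples), plus endpoint phage titers (PFU/mL) with a lower
limit of detection of 500 PFU/mL.  Noise is multiplicative lognormal
with configurable CV (default 0.1, mean-one parameterization) — the
model keeps signals positive and roughly proportional in error, which is
the right first approximation for optical densities and plaque counts;
no instrument-specific error structure is attempted.  Titers below the
LOD are reported as censored bounds, never as zero or a fabricated
count.  The dimensionless-time-to-hours mapping is a declared config
scale (default 1 model time unit per hour) and touches only the readout
layer.  `ln_fold_change` returns ln(final/initial) with censored finals
becoming flagged upper bounds, and `classify_winner` compares mean
endpoint titers with censoring handled as [0, LOD] intervals, calling a
tie whenever the intervals overlap.

What the generator does *not* emulate: fluorescence-to-OD spectral
conversion, starvation-dependent infectivity, phage degradation
chemistry, media effects, or replicate-level batch structure.  Passing
tests on these synthetic readouts therefore demonstrate the correctness
of the classification and censoring logic, not fidelity to any
particular instrument.

## Problem sizes used by the automated checks

The acceptance script bisects each threshold on [1, 6] (12 indicator
evaluations); sweep-based tests use grids of 6–10 cost ratios by up to 5
asymmetry values with `t_max = 3e4` per cell; sensitivity checks use
Morris r = 20 and Sobol `n_base = 128` (per mode).  These sizes settle
every quantity well past its compared precision.

## Known limitations

- No spatial structure, phage latent period, resistance evolution, or
  multi-strain extensions; no stochastic (Gillespie) variant.
- No limit-cycle analysis: oscillatory attractors are only summarized
  by window averages and flagged, not characterized.
- The extinction floor is a modeling commitment: dynamics that would
  recover from densities below 1e-12 in the un-clamped ODE are
  permanently extinct here (deliberately — fractional individuals
  cannot rescue a population).
- Bistability bands (e.g. between the forward-simulation crossing near
  2.09 and the global-stability exchange at 2.30) are initial-condition
  dependent; the package reports both thresholds and does not
  characterize the band's interior.
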
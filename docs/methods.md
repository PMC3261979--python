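# Methods

## Scope and units

`mixkin` composes per-chemical mass-action metabolic pathways with a
generic rat PBPK inhalation template into one joint ODE system and
calibrates the reaction microconstants by MCMC. Units are fixed globally:
amounts in nmol, volumes in mL, time in min, concentrations in nmol/mL.
The hepatic CYP2E1 pool (2.09 × 10⁻⁵ mmol) is therefore carried as
20.9 nmol and the hypothetical secondary cytochrome CYPX as 1.16 nmol.
Reaction rates act on liver *amounts*, not concentrations — this is what
makes k1's units min⁻¹·nmol⁻¹ — so tissue/blood partitioning of the
substrate inside the liver is absorbed into the calibrated k1.

ppm-to-concentration conversion uses the ideal-gas molar volume
24,450 mL/mol (25 °C, 1 atm): C_inh [nmol/mL] = ppm × 10³ / 24,450, so
100 ppm of any vapor is 4.09 nmol per mL of air. The molar volume is a
configurable argument for other temperature/pressure conventions. This
conversion matters quantitatively: at 50–200 ppm it puts liver substrate
amounts in the tens of nmol, the same order as the amount-based Km values
implied by the calibrated microconstants (≈27 nmol for benzene), which is
precisely the regime in which the shared CYP2E1 pool is meaningfully
depleted and competitive interactions of the observed factor-two size can
occur at all.

## Transport template

Each circulating parent gets four flow-limited tissue states
(dQ_i/dt = F_i (C_art − Q_i/(V_i P_i))) and algebraic blood/air outputs
(venous-equilibration gas exchange; venous and arterial blood are computed
outputs, not states, reflecting the quasi-steady blood assumption).  Only
inhalation is modeled. Two physiological quantities are derived rather
than set: the richly perfused flow fraction (remainder to 1.0) and the
poorly perfused volume (0.9 × body volume minus the other tissues);
deriving them keeps the flow and volume budgets closed by construction.
Baselines ship as packaged YAML tables; a second packaged set carries the
calibrated posterior modes (alveolar ventilation 78 mL/min, cardiac output
90 mL/min, fat volume 12 mL, per-chemical blood/air partitions and
microconstant triples) used by `build_btex_model(at="mode")`.

## Pathway variants and composition

Type I is the three-reaction single-enzyme scheme. Type II duplicates the
triple for a second enzyme; unset primed constants default to
k1′ = k1/10, k2′ = k2, k3′ = k3, making the second route a lower-affinity
pathway. Type III adds metabolite-vs-parent competition at the same
enzyme (metabolite-side constants defaulting to the parent's) plus a
first-order metabolite clearance kh. kh has no literature value; it is a
required configuration entry with no silent default, and the first-order
product is treated as a terminal sink (secondary metabolites beyond it are
out of scope). The core triple k1–k3 must be strictly positive; optional
branch constants may be exactly zero, which switches the branch off — the
null configurations (zero CYPX pool; zero metabolite branch and kh) then
reproduce type I trajectories, a property the tests assert.

The composer merges pathways by three rules: (1) the circulating parent's
liver PBPK amount and its pathway substrate species are the *same* state,
so transport and reaction terms add on one variable (a dual-pool
alternative would need an exchange rate no one can supply); (2)
liver-resident species are never transported; (3) each shared enzyme
appears once, and its derivative is automatically the sum of all
chemicals' binding/unbinding/catalysis terms. Type I metabolites get a
state recording cumulative production only — no transport, no further
reactions. State ordering is canonical (chemicals in input order, tissue
amounts then liver species, shared pools last) and exposed through
`state_index`; enzyme-complex bound substrate is counted in the liver, not
in venous outflow.

Pathways round-trip through a structured YAML/JSON format
(`mixkin-pathway/1`) restricted to mass-action kinetics; any other rate
law raises an unsupported-feature error naming the reaction rather than
being approximated.

## Numerics

The binding subsystems are stiff (calibrated k2 up to ~2 × 10⁴ min⁻¹
against transport time scales of minutes), and calibration needs on the
order of 10⁶ trajectory solves, so the composed system is packed into flat
arrays and integrated by an in-package, numba-compiled, adaptive L-stable
Rosenbrock pair (the classic ode23s scheme) with an analytic Jacobian —
exact here because every right-hand side term is multilinear in the
states. Exposure schedules are piecewise constant; the integrator
restarts at every switch and output time so discontinuities are never
smeared. Defaults are rtol 10⁻⁶, atol 10⁻⁹ nmol; refining both by 10×
moves venous concentrations by < 0.01%. A pure-python reference RHS is
exposed for cross-checking, and the tests verify the compiled integrator
against scipy's LSODA on that reference to ~10⁻⁵ relative agreement, the
analytic Jacobian against finite differences, enzyme conservation to
integrator precision (residuals ~10⁻¹⁴ relative), and per-chemical mass
balance against an independent per-segment trapezoidal quadrature of the
gas-exchange flux (closure ~10⁻⁵ at a 0.5-min output grid). Tiny negative
excursions are clipped in reported results and the raw minimum recorded in
the diagnostics; it must stay above −10⁻⁶ nmol.

Likelihood simulations inside the sampler run at calibration-grade
tolerances (rtol 10⁻⁴, atol 10⁻⁷; the recovery study uses rtol 10⁻³): the
induced venous error is ≲10⁻⁴ relative, three orders of magnitude below
the GSD-1.28 observation noise, at a small fraction of the cost.

## Sensitivity screen

Parameters are sampled independently and uniformly within ±10% of baseline
(or caller-supplied ranges), the model is simulated per draw, and the
Pearson correlation between each parameter and venous concentration at
each output time is computed; any |r| > 0.3 flags the parameter as worth
calibrating. Pearson on raw values is the default with Spearman available
since the response is nonlinear. Names beginning with `dummy` are sampled
but never applied — a built-in null control whose |r| stays below 0.1 at
500 draws. The screen is bit-reproducible from its seed. (The historical
sampling intervals sometimes quoted for k1 and k2 conflict with the units
of the calibrated values; the units of the prior table are authoritative
throughout this package.)

## Calibration

Observations are group-mean venous concentrations assumed log-normal
around the model prediction. The per-point geometric SD comes from
moment-matching the reported arithmetic mean and SD
(σ² = ln(1 + (SD/mean)²)); points without an SD use the global default
GSD 1.28. Packaged priors per chemical: LN(62.5, 1.1) on alveolar
ventilation and cardiac output, LN(17.5, 1.1) on fat volume, LN(baseline,
1.1) on the blood/air partition, and wide uniforms on the microconstants
(k1 ∈ U(10⁻³, 10²) min⁻¹·nmol⁻¹, k2 ∈ U(10, 10⁷) min⁻¹, k3 ∈ U(2, 50)
min⁻¹ — k3's range reflecting published Vmax and enzyme-content values).

The sampler is component-wise random-walk Metropolis with multiplicative
log-normal proposals (the x′/x Jacobian term is included in the acceptance
ratio, so positivity is built in). Per-component scales adapt toward 40%
acceptance every 25 updates during burn-in (default: first half of the
iterations) and are frozen afterwards, preserving detailed balance for the
kept draws. Five chains run independently from prior-drawn starting
points; fixed seeds give bit-identical chains. Convergence is the classic
Gelman–Rubin potential-scale-reduction statistic (between/within variance
ratio); zero within-chain variance reports NaN (degenerate) rather than
raising. Summaries follow the mode; mean ± SD (2.5th, 97.5th percentile)
convention, with the mode taken as the maximum-posterior draw — cheap and
well-defined for a sampled posterior. Chemicals are fitted separately
(per-chemical datasets, shared prior shapes); passing several chemicals'
datasets to one call performs a joint fit of the union of parameters.

Posterior predictive simulation draws parameter vectors from the pooled
chains, simulates the scenario, multiplies each predicted concentration by
independent log-normal noise with geometric mean 1 (so the median band is
noise-insensitive), and reports 2.5/25/50/75/97.5% bands; failed
simulations are excluded and counted.

## Synthetic data

The generator emulates the single-chemical calibration design: 4-hr
exposures at 50/100/200 ppm, five animals per group, venous samples at
five evenly spaced times over the 2-hr post-exposure window (24, 48, 72,
96, 120 min after exposure ends — the exact historical times are not
recorded, so an even grid is used), multiplicative log-normal noise with
GSD 1.28. Per-animal draws are independent (no animal random effect,
matching the use of group means as data), and one seed drives everything.
It emulates the *statistical* structure the likelihood assumes — it cannot
stand in for real rats (no inter-study variability, no model
misspecification, no assay floor), so passing recovery tests demonstrates
internal consistency of generator + likelihood + sampler, not field
validity of the kinetic model.

## Verification strategy and problem sizes

The original rat concentration datasets exist only as figures in cited
work, so the package's correctness case is built from properties, at
deliberately chosen desk-scale sizes:

* conservation and mass-balance checks on 6-hr quaternary simulations
  (0.5–2 min output grids);
* compositionality: the joint BTEX model with three exposures zeroed
  reproduces the single-chemical model to < 10⁻⁶ relative (both at
  rtol 10⁻⁹);
* the Michaelis–Menten limit: an isolated liver (vanishing perfusion,
  E_total = 0.2 nmol ≪ S) gives initial velocities within 5% of
  Vmax·S/(Km + S) across S ∈ [0.1 Km, 10 Km];
* prior-only MCMC reproduces prior quantiles (5 chains × 4,000
  iterations);
* simulation-based calibration: 20 replicate synthetic studies at the
  calibrated benzene truth (k3 = 7.8 min⁻¹), each refit with k3's U(2, 50)
  prior by 5 chains × 5,000 iterations; the generating k3 must fall inside
  the 95% interval in at least 18 of 20 replicates. k3 is the calibrated
  component in this study because it is the identifiable microconstant
  (k1 and k2 are only weakly identified from whole-body kinetics — their
  ratio, i.e. Km, is what the data constrain), which keeps the full study
  within a ~10-minute compute envelope without changing its statistical
  content.

## Known limitations

* Flow-limited transport only; no diffusion limitation, no oral/dermal
  routes, no human physiology, no growth.
* No enzyme synthesis/degradation or induction; enzyme totals are strictly
  conserved.
* Type III tracks a single terminal sink; secondary metabolite kinetics
  (e.g. phenol's own conjugation) are out of scope.
* The Michaelian reduction is diagnostic only; no non-competitive or
  uncompetitive inhibition algebra is provided.
* Per-point GSDs assume the reported SDs are arithmetic; datasets reporting
  geometric summaries need pre-transformation by the caller.
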
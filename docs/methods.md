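# Methods

## Model structure and assumptions

Both models describe a monomeric modulator protein M with two independent,
single-occupancy effector sites: one for a response regulator and one for a
signaling peptide S. All binding steps follow mass-action kinetics; total
concentrations of regulator (R_T), modulator (M_T) and signal (S_T) are
conserved on the timescale of interest (binding equilibrates in seconds to
minutes, much faster than protein-level turnover). Only steady states are
reported: the dose-response curve is the steady output as a function of S_T,
and all features (amplitude, EC50, Hill coefficient, occupancy) derive from
it. Transient kinetics are not a validated output — the absolute rate
magnitudes are under-determined by the equilibrium/steady-state data the
models are built from, and the defaults below fix them only up to an
arbitrary overall timescale.

**Binding modulator.** The four reversible reactions (M+R, M+S, MR+S, SM+R)
form a closed thermodynamic cycle, so the dissociation constants must
satisfy K4/K3 = K5/K1 (detailed balance). The state integrated is the three
complexes (MR, SMR, SM); free species are reconstructed from the
conservation relations, which makes the totals invariants of the dynamics by
construction rather than by solver accuracy. The phosphorylation status of
the regulator is deliberately ignored: Rap-type binding modulators sequester
both forms equally, so free total [R] is the relevant output.

**Enzymatic modulator.** The modulator binds the active regulator R′ and
deactivates it catalytically, with rate k2 from the binary complex MR′ and
k6 from the ternary complex SMR′; a lumped linear activation rate κ
(upstream kinase) and intrinsic deactivation rate γ close the cycle. No
explicit histidine-kinase species or phosphorelay is modeled. Rate naming
follows the steady-state constants: k3/k₋3 govern S binding to MR′ (constant
K3) and k4/k₋4 govern S binding to free M (constant K4), with the
thermodynamic-cycle constraint K3·K_M = K4·K′_M.

**Catalysis routing.** Deactivation of the ternary complex releases the
regulator while the peptide remains bound: SMR′ → SM + R. This choice is
load-bearing. With it, the steady state of the full ODE system satisfies the
quasi-equilibrium relations

    [R′][M]/[MR′] = K_M,  [S][MR′]/[SMR′] = K3,
    [R′][SM]/[SMR′] = K′_M,  [S][M]/[SM] = K4

*exactly* (verified to machine precision in the tests), which is what makes
the closed-form amplitude an identity rather than an approximation. Routing
the peptide to the free pool instead (SMR′ → S + M + R) breaks these
relations at intermediate signal by O(10⁻²) relative and degrades the
closed-form agreement accordingly; chemically it would also mean the
dephosphorylation event ejects a ligand bound at a distal site. We therefore
model the peptide as staying bound through the catalytic step.

## Parameters

Class I (molecular) — binding model: cooperativity α (α > 1 means signal and
regulator binding are mutually inhibitory; the signal then acts as an
inverse agonist), relative site affinity β = K3/K1, and the absolute scale
K1 (μM). Enzymatic model: α_E = k6/k2, α_B = K′_M/K_M, β_E, and K_M (μM),
plus the cycle rates k2, κ, γ (s⁻¹). α_E is undefined for k2 = 0; the pure
binding limit (k2 = k6 = 0, γ = 0) is an explicit configuration that absorbs
the catalytic losses into the dissociation rates so K_M and K′_M — and the
cycle constraint — are preserved.

**β_E convention.** The two candidate definitions K3/K_M and K4/K′_M cannot
both hold once α_B ≠ 1 (the cycle constraint forbids it). We define
β_E := K4/K_M — the ratio of the modulator's signal affinity (free M) to its
regulator affinity, the exact analogue of the binding model's β = K3/K1 —
and derive K3 = β_E·α_B·K_M from the cycle. For α_B = 1 (the regime of the
enzymatic design-space maps and the RapA estimate) all conventions coincide.

Class II (context): μ = M_T/R_T, K_R1 = K1/R_T (binding) or K_r = K_M/R_T,
ι = k2/(γ+κ), κ_r = κ/(γ+κ) (enzymatic; κ_r is also the active fraction of
the regulator without modulator). All Class II parameters are dimensionless.

Units are μM and seconds throughout. Rate magnitudes default to unit forward
rates (1 μM⁻¹ s⁻¹) with dissociation rates K_i·k_i; only the constants K_i
enter steady-state outputs, so this choice is inert. The preset rate sets
fix the under-determined rates exactly the way the corresponding published
setups fix them (unit dissociation rates and k1 = k3 = 1 μM⁻¹ s⁻¹, deriving
k4, k5, k6 — and k₋3 where β_E is prescribed — from the allosteric
parameters plus the cycle constraint).

## Numerics

Steady states are computed two independent ways:

* **Integration + polish** (default): BDF integration of the stiff ODEs over
  horizons grown by 10× (starting at 10 s) until max |d[X]/dt| falls below
  threshold, then a damped Newton polish with finite-difference Jacobian
  (relative step 10⁻⁷), with a hybrid-Powell fallback when Newton stalls.
* **Algebraic reduction**: the binding model reduces to three conservation
  equations in the free concentrations (solved in log space, seeded by a
  damped fixed-point iteration, with analytic special cases for S_T = 0 and
  M_T = 0); the enzymatic model reduces to the quasi-equilibrium relations
  plus the activation/deactivation flux balance κ[R] = γ[R′] + k2[MR′] +
  k6[SMR′] and the totals.

Tolerances: rtol 10⁻⁹, atol 10⁻¹² μM; steady-state residual threshold 10⁻⁹
μM/s *scaled by the characteristic Jacobian norm* (1 + max kᵢ · largest
total). The scaling matters at saturating signal, where S_T ~ 10⁷ μM makes
round-off in a machine-exact state produce max |rhs| ~ 10⁻⁷; the scaled
criterion bounds the state error instead of the raw derivative. During
integration the vector field is evaluated on a smooth extension that leaves
tiny negative free-species excursions in place (solver trial steps overshoot
the feasible region transiently; mass action pushes them back, and the
extension keeps the field differentiable when a steady state sits exactly on
the boundary, as free [R] = 0 does in the pure-binding limit). User-facing
RHS calls keep a strict feasibility guard (clip at 10⁻⁹ relative, error
beyond). Every returned steady state must pass conservation at 10⁻⁹
relative.

A saturating signal standing in for S_T → ∞ is 10⁶ × the largest of the
signal dissociation constants, M_T and R_T. With this factor the plateau
approach (~K/S_T) leaves a residual of order 10⁻⁶–10⁻⁷ relative; the
amplitude agreement targets in the tests (10⁻⁶ absolute binding, 10⁻⁵
relative enzymatic) are set accordingly, and doubling the saturating level
moves the plateau by less than 10⁻⁷ relative.

**Feature extraction.** EC50 by bisection in log S_T on the normalized curve
(tolerance 10⁻⁶ in R_n); elasticity by central finite difference of
log R_n vs log S_T over 0.01 decades (halving the step changes RapA's Hill
coefficient by < 10⁻³); h = 2ε. Normalization already makes agonist curves
increasing, so h ≥ 0. Responses with |A| ≤ 10⁻⁹ are classified null and
EC50/Hill are reported as explicitly undefined rather than NaN. Context
optimization maximizes |A| (for agonists A < 0 and the magnitude is the
dynamic range): analytically for the binding model, by bounded golden-section
search on log μ (nested with a log-κ search when κ is free) on the
closed-form amplitude for the enzymatic model; results at a search bound are
flagged.

## Ensembles and design maps

Context robustness uses Latin-hypercube samples of (K_r, ι, μ, κ_r) with
default ranges [0.1, 10]³ × [0.01, 1] and n = 10⁴. All marginals are
stratified log-uniformly: the ranges span two decades (κ_r's also spans two),
so log stratification weights the decades evenly; a linear option exists for
sensitivity checks. The activation frequency p counts samples with A > 10⁻⁹
among those with |A| > 10⁻⁹; exact-zero amplitudes are excluded from both
numerator and denominator and reported separately, so sign noise cannot
masquerade as context sensitivity. Ensembles and context landscapes evaluate
the closed-form amplitude (validated against the ODE route; an `ode_check`
option re-verifies a subset per run). Design-space maps run the full numeric
pipeline per cell — optimize context, then extract features — with per-cell
failures flagged as nulls rather than aborting the scan; the default
resolution for production maps is 41 × 41 log-spaced cells, while the test
suite uses coarser grids to stay fast.

## What the synthetic setups do and do not show

All inputs are parameter sets; there is no external data. The presets encode
the published figure conditions verbatim (panel cooperativities, μ and M_T
series, unit rate conventions, the sampling ranges, and the RapA–PhrA
estimate α_B = 1, α_E = 0.37, β_E = 3.6), so passing tests show the
implementation reproduces the model's own mathematics under those
conditions — closed forms vs. independent numerics, sign and coherence laws,
optimum formulas, calibration of the feature extractors on analytic curves.
They do not show that the model describes any particular biological system:
real networks have explicit kinase dynamics, phosphorelays, gene-expression
feedback and noise, none of which are modeled here.

## Known limitations

* The model is monostable by construction; no bistability or hysteresis
  analysis is offered.
* Kinetic transients are not validated outputs (timescales are conventional).
* The closed-form optimum μ_opt for enzymatic modulators applies only to
  binding-allostery-only enzymes (α_E = 1); for α_E ≠ 1 the optimizer is the
  numeric search.
* At the amplitude-optimal context the RapA parameter estimate yields a Hill
  coefficient of ≈ 1.11 — at the graded end of its design space (h spans
  ≈ 1.05–2.0 across β_E at α_E = 0.37), with receptor occupancy at the EC50
  close to one half, but not strictly below the h = 1 graded/ultrasensitive
  boundary.
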
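# Methods

This note documents the models, the parameter choices that matter, the
numerical methods, and the limits of what the synthetic-data tests show.
Units throughout: µM for concentrations (membrane species on the
cytosol-volume basis), seconds, µm.

## Membrane polarization (module `polarization`)

The question is whether localized vesicle delivery into a window can
sustain a concentration gradient of GTPase on a membrane against lateral
diffusion. Non-dimensionalizing the 1D delivery–diffusion–removal balance
leaves two groups: ρ_del = (h_w·L_w)/(h·L) and ρ_rem = m·L²/D. The steady
state solves

    c*'' − ρ_rem·c* + 1/ρ_del = 0   on x* ∈ [0, 1],

with the window delivery as an inward boundary flux of −1 at x* = 0 and no
flux at x* = 1. Window delivery enters only through the boundary term and
global delivery only through the interior source 1/ρ_del; this realizes
both stated limits (ρ_del → ∞: window-only source; ρ_del ≪ 1: the uniform
source swamps the boundary term and the profile flattens regardless of
ρ_rem).

Discretization: second-order central differences with ghost-point boundary
elimination and a direct sparse solve — the ODE is linear, so no iteration.
The relative residual tolerance is 1e-8; accuracy is validated against the
closed form c*(x) = 1/(ρ_del·ρ_rem) + cosh(√ρ_rem(1−x))/(√ρ_rem·sinh√ρ_rem)
to <1% at every grid point, with the empirical second-order convergence
checked by grid refinement. ρ_rem = 0 with nonzero delivery has no bounded
steady state and raises a dedicated error rather than returning a profile.

The polarization index is the mean concentration inside the window region
over the mean outside (trapezoidal means); it is 1 for flat profiles and
monotone in ρ_rem.

## Apparent dissociation rate (module `koffap`)

The membrane pool is a mixture of GTPase·GDI (off-rate k₂₋), free GTPase
(k₄₋) and effector-bound GTPase. Effector-bound GTPase is taken as
non-dissociating — membrane-localized activation drives local cytoskeletal
output, and the complex is anchored. The kinetic form is the
species-weighted mean; at binding equilibrium with free GDI and effector it
becomes (k₂₋·g + k₄₋)/(g + 1 + e), g = GDI/K_D1, e = Eff/K_D5. The two
forms agree to machine precision on equilibrium fractions (tested).

Free (not total) GDI enters here; converting totals to free concentrations
is the job of the lumped/detailed modules. Regime classification uses a 5%
maximum change of k_offAp over a 10-fold GDI sweep (configurable); both the
threshold and the fold range are reporting conventions, not physics.

## Lumped four-state loop (module `lumped`)

States: cytosol/membrane × GDI-free/GDI-bound, with reactions numbered 1
(membrane GTPase + GDI), 2 (membrane cycling of the complex), 3 (cytosolic
GTPase + GDI), 4 (membrane cycling of free GTPase). GDI on-rates are stored
bimolecular and folded with the free GDI concentration into
pseudo-first-order constants when non-dimensionalizing, so K_DGDI =
k₃₋/(k₃₊·GDI). Membrane species are carried per cytosol volume; membrane
association rates therefore scale with the surface-to-volume ratio relative
to the geometry in which they were measured (`scale_membrane_on_rate`).

The loop's thermodynamic driving ratio is ρ_GDI/ρ_m: equal ratios are
detailed balance, and then the equilibrium fractions depend only on
(K_DGDI, K_Dm, ρ_Eq) through the closed forms in the README. These closed
forms were derived by mass-action species enumeration (set Rho_c = 1; then
Rho_m = 1/K_Dm, RhoGDI_c = 1/K_DGDI, RhoGDI_m = ρ_Eq/(K_DGDI·K_Dm)) and are
cross-validated against time-integrated ODE steady states to 1e-6 over a
5×5×3 parameter grid. When ρ_GDI ≠ ρ_m the clamped-GDI steady state is a
null-space solve of the linear rate matrix; the net cycle flux is reported
signed, positive clockwise (removal). With conserved GDI the system is
nonlinear and is integrated to steady state instead.

`invert_observables` solves the two closed forms for any two unknowns given
the other three. All ten combinations reduce to linear equations (no
polynomial root-finding is required); non-positive or inconsistent
solutions (r0 < r0_f, denominators of the wrong sign) raise typed errors,
and the genuinely underdetermined case (r0 = r0_f with ρ_Eq = 0 given)
raises a non-identifiability error. ρ_GDI/ρ_m equality uses relative
tolerance 1e-6.

Contour tables default to 61 log-spaced points per axis over 1e-4…1e2 with
iso-fraction levels 9%…89% in 10% steps.

## Detailed network (module `network`)

Species: membrane RhoGDP/RhoGTP/RhoGTP·Eff, cytosolic RhoGDP/RhoGTP and
their GDI complexes, free GDI and free effector; optionally the two
membrane GTPase·GDI complexes. Assumptions: GDI-bound GTPase exchanges no
nucleotide; effector binds only membrane-bound, GDI-free, GTP-loaded
GTPase; nucleotide exchange happens only at the membrane (GEF), hydrolysis
at the membrane (GAP) and in the cytosol (GAPc) on free GTPase. The default
topology omits the membrane-GDI reactions: in fibroblasts k_offAp is
GDI-independent and GDI is not found in membrane fractions, which places
the system in the ρ_Eq ≈ 0 regime; the reactions can be switched on for
systems that need them.

The constitutively active mutant (G12V) is represented as
hydrolysis-insensitive (k_GAP = k_GAPc = 0) rather than as a separate
species; the whole GTPase pool in such a condition is treated as mutant.
Endogenous unlabeled GTPase is carried inside the total, held constant
across transfections and halved under GDI knockdown.

Steady states: MINPACK hybrid Newton on the conservation-reduced residual
(one ODE row per group replaced by the Rho/GDI/effector conservation
equations), seeded from a short integration or a caller-supplied warm
start; fallback to long-time integration plus a re-polish. Trajectories use
LSODA with conservation drift checked to 1e-6 relative. Observables:
k_offAp = (R4₋,D·[RhoGDP_m] + R4₋,T·[RhoGTP_m]) / (membrane GDI-free
pool); r0 = membrane/total; active = all GTP-loaded species.

The composite constant between cytosolic GDI and membrane GTPase is the
thermodynamic-cycle product K_D3·R4₊/R4₋; with the fitted Rac numbers it
reproduces the published 34 nM (GTP) and 2.5 nM (GDP) — the order-of-magnitude
apparent affinity difference comes entirely from the off-rate difference.

## Fixture parameter set (module `synthetic`)

Published values: K_D3(GTP) = 1.3e-4 µM with K_D3(GDP)/K_D3(GTP) = 0.99;
R4₊ = 2.84/s at Sfc/Vol = 0.524/µm; R4₋ = 0.15/s (GDP), 0.011/s (GTP);
GEF/GAP = 1.9 with 3.25-fold Tiam increase; GDI 0.14 µM, GFP-Rac 0.05 µM,
effector 0.5 µM.

Values not reported, chosen once as realistic and fixed:

- Endogenous unlabeled Rac: 0.05 µM (equal to GFP-Rac); configurable, and
  the recovery tests run with it fixed at truth.
- Bimolecular on-rates R3₊ = 100, R5₊ = 10 1/(µM·s): near the
  diffusion-limited scale; steady-state observables depend only on the
  corresponding K_Ds (the GDI and effector complexes are flux-terminal at
  steady state), so these set timescales only.
- Absolute GAP activity k_GAP = 1/s (only the GEF/GAP ratio is reported) and
  cytosolic GAP k_GAPc = 0.05/s.
- Effector K_D5 = 1.0 µM, the literature scale for effector(PBD)–RacGTP
  binding; at this value the only GDI coupling of k_offAp in this topology
  (effector depletion by the membrane pool) is mild, consistent with the
  reported GDI-insensitivity.
- GDI over-expression 5× and knockdown 0.25× of endogenous (not
  reported; configurable).
- The two unmeasured k_offAp entries are assigned to the +GDI conditions
  and the unmeasured active-Rac entry to G12V−GDI (which observables are
  missing is known, for which conditions is not; configurable).

Noise is mean-one lognormal per observable (σ² = ln(1+CV²), mean corrected
to one), with one root seed spawning independent per-condition streams;
active totals are normalized to the anchor condition after noise, as each
measurement carries its own error.

## Fitting (module `fitting`)

The misfit is the sum of weighted squared *relative* residuals over all
present observables; relative residuals because the observables span
decades and the experimental errors are closer to multiplicative. Weights
default to 1 per observable. Optimization is bounded trust-region least
squares in log10-parameter space (rates span decades) from Latin-hypercube
multistarts; everything is deterministic given the recorded seed, and the
per-start table is kept.

Identifiability: with the eight-condition observable structure, free
cytosolic GTPase is in the tight-binding regime of GDI, so K_D3 and R4₊
enter the observables almost exactly through their product (equivalently,
through the composite effective K_Ds above). The pair is therefore a sloppy
direction: profiling K_D3 fourfold off truth and refitting the rest changes
the 5%-noise misfit by well under its own scale. Consequently the default
recovery experiments are run two ways: (a) the constrained search with R4₊
held at its measured value, which recovers the off-rates, K_D3 and GEF/GAP
within 25% at 5% multiplicative noise across seeds, and (b) the
unconstrained five-parameter search, which recovers the off-rates, GEF/GAP
and the product K_D3·R4₊ within 25% while the individual factors wander —
the behaviour a practitioner should expect from this data structure.

## β-cell application (module `betacell`)

Geometry: plasma membrane 500 µm², granule membrane 3600 µm² (10000
granules), cytosol 850 µm³, giving Sfc/Vol 4.8/µm total, 0.59/µm for the
plasma membrane alone, and a 7.2-fold granule/PM area ratio. Granule
traffic is not modeled — cytosolic shuttling (slowest membrane off-rate
0.15/s for GDP-Rac, the granule-relevant species) outpaces the 2.4e-4/s
exocytosis bound by ~600-fold — only the granule surface area enters, by
scaling the association rate.

Free-GDI accounting solves the multi-ligand binding equilibrium by
bisection (never returns negative free GDI); at the measured baseline
(Rac 0.11, Cdc42 0.15, GDI 0.39 µM, K_D 1.3e-4 µM) it gives 0.13 µM free
GDI and K_DGDI = 1e-3.

Chart trajectories: a mixed pool of GDI and sGDI (Rac affinity reduced
`fold_kd_sgdi`-fold; Cdc42 affinity unchanged) gives an effective
K_DGDI = K/(U_free + S_free/fold). For a scenario (initial phosphorylated
fraction s0, fold, Cdc42 inert or phosphorylatable), the effective K_DGDI
is computed at t = 0 and at 20 min (sGDI ×1.7, GDI-bound cytosolic Rac
−40%), and the K_Dm needed to sit on the measured r0_f contours (0.28, then
0.57) is extracted with ρ_Eq = 0. The mixed equilibrium is solved by nested
bisection on the free ligand concentrations (each conservation relation is
monotone in its own free concentration, so this is globally convergent).
An arrow is "horizontal" if |Δlog10 K_Dm| < 0.1 decades, and "feasible" if
its starting K_Dm does not exceed the geometry's admissible band upper edge
[R4₋,T, R4₋,D]/R4₊ (the lower edge can be relaxed by effector binding; the
upper cannot). With the β-cell geometry no feasible scenario is horizontal
at folds 5, 10, 100 or 1000 — the required K_Dm always decreases ≥0.3
decades — while a Sfc/Vol ≈ 0.52/µm geometry admits near-horizontal arrows
at high folds. The geometry enters through the feasibility band: it decides
which initial sGDI levels are admissible, and with the β-cell's low band
the admissible starts have too little phosphorylatable head-room for a
3.4-fold effective K_DGDI increase.

Dynamic model: 13 species (cytosolic Rac free/GDI-bound/sGDI-bound by the
GDP state, PM Rac by nucleotide plus effector-bound, granule Rac by
nucleotide, free GDI/sGDI, PLD inactive/active). GDI binds cytosolic
GDP-Rac only (cytosolic GTP-Rac is a minor, transient pool and the
nucleotide affinity ratio is 0.99); phosphorylation interconverts the free
GDI forms; the granule membrane carries no GEF and no effector ("no active
Rac on granules"); per-area association is equal for both membranes at
baseline, so the on-rates are 2.84/s × (area/850)/0.524: 3.19/s (PM) and
22.9/s (granules). PLD activation is first-order upon stimulus, and the
membrane association rates scale as kon·(1 + coeff·PLD*/PLD_total) with
coefficients b (PM) and c (granules); the GDI phosphorylation rate scales
as pG·(1 + a). Cdc42-bound GDI is left out of the dynamic model (it is a
slow, balanced sink over this window), so the working GDI pool is
0.39 − 0.15 = 0.24 µM.

Calibrated defaults (chosen once against the measured marks, which is what
the coefficients exist for): baseline PM GEF activity 0.55/s reproduces the
28% pre-stimulus membrane fraction; baseline phosphorylation balance
pG = 0.001/s vs 0.002/s dephosphorylation; stimulus coefficients a = 0.7,
b = c = 3.6 reproduce ≈1.7-fold sGDI and ≈2.0-fold membrane Rac at 20 min
(final membrane fraction 0.57). With a alone (b = c = 0) membrane Rac rises
only ≈1.1-fold: the sGDI shift mostly releases GDI that re-buffers the
released Rac, so an increased membrane affinity is also needed — the
dynamic counterpart of the chart conclusion.

## What the synthetic tests do and do not show

The synthetic datasets are generated by the same model family that is
fitted, with independent lognormal noise and the published parameters as
truth. Passing recovery tests therefore demonstrates the estimator's
correctness and the information content of the eight-condition design —
not robustness to model misspecification (wrong topology, non-lognormal
error, condition-correlated artifacts), which real data would add. The
β-cell dynamic model's stimulus coefficients are calibrated to the
measured fold-changes, so the dynamic test checks consistency of the
mechanism, not an independent prediction; the chart-trajectory analysis,
by contrast, uses only measured endpoints and the fitted fibroblast
kinetics, and is the load-bearing argument.

## Numerical conventions

- Steady-state residual tolerances: 1e-10 (Newton), acceptance 1e-8
  relative to the total concentration scale; profiles 1e-8 relative.
- Lognormal noise uses σ² = ln(1+CV²) with mean-one correction.
- Positivity is enforced structurally (log/bisection solvers) or by
  clipping below 1e-9 of the conserved total after convergence checks.
- All randomness flows from a single integer seed per run; derived streams
  use `numpy.random.SeedSequence.spawn`.

## Known limitations

- 1D polarization only; no spherical or 2D membrane solver, no stochastic
  vesicle arrivals.
- The detailed network is well-mixed per compartment; no membrane spatial
  resolution.
- G12V conditions treat the whole GTPase pool as hydrolysis-insensitive,
  ignoring the co-resident wild-type endogenous pool.
- The fit offers multi-start scatter and profile checks as identifiability
  diagnostics, not profile-likelihood confidence intervals or posteriors.
- The β-cell dynamic model holds Cdc42 and its GDI complex out of the
  dynamics and treats effector binding as pseudo-first-order.
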
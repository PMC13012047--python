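# Methods

This note documents the model, the synthetic ocean it runs on, the
numerical choices, and the design decisions that were genuinely open —
in enough detail that a maintainer can judge what a passing test does
and does not demonstrate.

## The tracer model

Dissolved CH4 obeys `dC/dt = A C + J_prod + Q_gx (S − C) − J_ox` on a
wet-cell vector (µmol m⁻³ ≡ nM; all rates y⁻¹).

**Oxidation.** `J_ox = k_ox · max(0, C − C_crit)`. A first-order loss
with a floor reflects that microbially mediated reactions deplete their
substrate only to the community's break-even level; observationally,
open-ocean [CH4] never falls much below ~0.3 nM even in the oldest
water. Note the sink is written as a *loss* (`max`, not `min`): the
alternative sign reading would make oxidation a methane source, which
contradicts both the first-order-loss description and the convergence
of old deep water *down* toward the threshold. Temperature- or
O2-dependent `k_ox` and higher-order kinetics are deliberately not
implemented: the interface accommodates them, but they mirror a
negative result (no improvement for extra parameters) and are out of
scope.

**Gas exchange.** `Q_gx = (1 − f_ice) k_w / d` acts on the top model
layer only (d = 36.14 m). `k_w = 0.251 U² (Sc/660)^(−1/2)` in cm h⁻¹,
converted to m d⁻¹; Sc is a quartic polynomial in SST for CH4 in
seawater from the same parameterization family as the 0.251
coefficient (pinned value Sc(20 °C) = 686.6). Solubility uses the
classic seawater CH4 Bunsen-coefficient fit (coefficients in
`forcing.py`, overridable), divided by 22.414 L mol⁻¹ to yield
mol L⁻¹ atm⁻¹. Saturation `S = X_CH4 · P · K` is computed directly in
µmol m⁻³ because the ppb→atm factor cancels the mol L⁻¹→µmol m⁻³
factor. The atmospheric record is a table (year, ppb), linearly
interpolated, constant at 706 ppb before 1700; the synthetic default
rises as a power law (exponent 4) to 1,832 ppb in 2014, mimicking the
slow pre-1900 drift and steep modern growth of the ice-core +
instrumental record.

**Production pathways.** Six mechanisms, each with exactly three free
parameters so model comparison is on equal footing, each confined above
its mechanistic depth horizon (euphotic depth for photosynthetic
release, diel-migration depth for zooplankton egestion, wintertime
mixed-layer depth for DOM cycling and phosphonate cleavage). Horizons
are sharp cutoffs at cell centers — the grid is coarse and only the
bounding depth is physically specified. The substrate law
`a_s f (f − b_s)` with `f = S/(S+K_s)` is clamped at zero below the
break-even concentration `b_s K_s/(1 − b_s)`: production is a source,
and the threshold statement implies a floor, not a sign change. The two
combined variants are multiplicative (PO4 inhibition × substrate
limitation — both factors gate the same enzymatic pathway) and additive
(photosynthetic + phosphonate sources — independent mechanisms); both
reduce exactly to their constituents in the appropriate limits, and the
choice is isolated in `jprod_combined` so it can be swapped.

## Solution

**Spin-up.** The 1700 steady state (fixed 706 ppb) is solved by an
active-set Newton iteration: with the active set a = {C > C_crit}
frozen, the system is linear and solved exactly by sparse LU; the set
is updated and the loop repeats until it stabilizes (usually 2–4
solves). A cycling set triggers a 2,000-y implicit pseudo-time fallback
followed by one exact solve. Convergence is enforced at a
volume-weighted residual ≤ 1e-8 of the saturation norm.

**Transient.** 1700→2014 with Crank–Nicolson on the linear part
L = A − diag(Q_gx) and explicit Euler on the threshold oxidation and
sources, with the saturation forcing evaluated at step midpoints. The
factorization of (I − dt/2 L) is independent of every optimized
parameter, so one `TimeStepper` is shared across a whole calibration.
The default step is 0.25 y; step-halving changes the 2014 field by
<0.1% (tested), and dt = 1.0 y changes sampled predictions by ~5×10⁻⁴
nM — far below observation noise — so calibration-heavy work uses
dt = 1.0 (and the many-replicate discrimination experiments dt = 2.0,
applied to truth and candidate fits alike so the comparison is
internally consistent) while reference runs use 0.25–0.5. Steps
producing negative
concentrations are retried at half step (recursively, max 4 levels).
Output cadence follows the historical convention: decadal to 1990,
annual 1991–2014, plus every cruise year during calibration so time
interpolation at cruise dates is exact.

## The synthetic ocean

A 24×16×8 aqua-planet (≈3,000 cells, top layer 36.14 m, bottom 4,000 m)
— large enough to express the latitudinal and vertical structure the
analysis needs, small enough that a full forward solution takes ~0.3 s
and the statistical experiments (hundreds of forward solves) finish in
minutes.

**Circulation.** Advection follows a zonally uniform overturning
streamfunction (40 Sv deep cells per hemisphere: polar sinking,
low-latitude upwelling; 20 Sv shallow subtropical-gyre cells confined
to the upper 500 m), discretized so face fluxes are differences of
corner streamfunction values — hence exactly divergence-free — with
upwind advection and pairwise diffusive exchanges (κ_h = 2,000 m² s⁻¹;
κ_v = 2×10⁻⁵ m² s⁻¹, raised to 3×10⁻³ poleward of 60° to mimic deep
convection). Because both pieces are antisymmetric in volume flux,
`volᵀA = 0` holds to round-off *by construction* — no post-hoc
projection is needed, and the conservation invariant cannot silently
degrade if the stencil changes. Deep ventilation ages are
centuries-scale (~180 y under the poles, ~600 y in the low-latitude
deep ocean), which is the ordering the oxidation/ventilation
competition requires, though the synthetic deep ocean is younger than
the real Pacific (~1,500 y) — deep anthropogenic uptake is accordingly
stronger here than in reality.

**Fields.** Surface phosphate has Southern-Ocean (~1.8 µM) and subpolar
maxima, equatorial-upwelling bumps (strongest in the Pacific), and
subtropical-gyre minima (<0.1 µM, lowest in the North Atlantic gyre);
the high-PO4 transition sits equatorward of where the wintertime mixed
layer deepens, as in the real subpolar oceans — otherwise moderate-PO4
water under a deep z_ML would host weakly-ventilated subsurface
production the real ocean does not have. NPP follows the macronutrient
supply, so gyres are jointly low-PO4/low-NPP: the decisive structure is
that the *PO4-inhibited production pattern* anti-correlates with NPP
across the low-latitude surface (r < −0.3, tested), which is what makes
an NPP-linked source geographically distinguishable from a
phosphate-linked one. Temperature, salinity, wind, ice, O2, DOM pools,
zooplankton biomass and the three depth horizons are smooth latitudinal
profiles with the standard qualitative structure; all fields are
clamped to physical ranges. An optional flag carves an eastern-Pacific
oxygen minimum zone (O2 = 3 µM) for testing the OMZ exclusion rule.

**What the synthetic world does not have:** seasonality, realistic
bathymetry or basin geometry (basin areas are longitude sectors, so
basin-split magnitudes differ from the real ocean), mesoscale
variability, and real cruise geometry. Passing tests therefore
demonstrate that the *machinery* — solvers, estimators, budgets,
attribution — is correct and that the discrimination logic works when
the generating structure is present; they do not validate the real-
ocean magnitudes.

**Truth experiment.** The known-truth run uses phosphate-inhibited
production with a₀ = 20 µmol m⁻³ y⁻¹, P_crit = 0.2 µM, w = 0.218 µM
(an inhibition curve reaching its ceiling as PO4→0 and 94% inhibited at
0.5 µM), and oxidation k_ox = 1/172 y⁻¹, C_crit = 0.33 nM — the
literature-scale parameter regime for this process. Eleven synthetic
transects (polar to subtropical, all basins, all reaching ≥1,000 m,
five near-full-column; ~1,000 samples) are sampled from the truth run
by the same interpolation used for real data, with additive Gaussian
noise.

**Observation noise.** The default sd is 0.1 nM, the vial-sample
gas-chromatography measurement scale (a few percent at open-ocean
concentrations). A Gauss–Newton identifiability analysis at the truth
parameters (sensitivities of all ~1,000 predictions to the five free
parameters) gives 1σ parameter uncertainties of ~7–14% at this noise
level — i.e. the truth is recoverable to within ~2σ ≈ 25% — whereas at
0.2 nM the soft directions (k_ox–C_crit correlation 0.95,
a₀–P_crit –0.98) already exceed 25% at 1σ. A heteroscedastic option
(1.5× sd in the top 100 m) represents the larger real-world surface
variability.

## Calibration

Five (or more, for combined variants) parameters are searched by
Nelder–Mead in transformed space — log for positive parameters, logit
for b_s, log(Q10 − 1) for Q10 — so bounds hold by construction. Each
evaluation is a full forward solution (spin-up + transient + transect
cost); solver failures return a large penalty. The budget is capped at
~400 forward solves with 2 restarts from a jittered best point: the
piecewise-linear oxidation threshold and the strong parameter
correlations create a long shallow valley in which a single simplex run
can stall, and restarts are what reliably reach its bottom. The cost is
the n-weighted mean of per-transect RMSEs with weights normalized to
sum to one, which keeps costs comparable across data subsets — a
requirement for bootstrap resampling. Surface-disequilibrium R²
(1 − SSE/SST over top-100 m samples) is reported alongside as the
pattern-skill metric.

**Bootstrap.** 12 reoptimizations on random 80% subsets, stratified
within each transect so every region stays represented (whole-transect
resampling is available by flag). Members are optimized independently
from the generic initial guess, *not* from the full-data optimum:
members are warm-started at the full-data optimum (standard practice)
and then walk to their own subset optima. Because an 80% subsample
(without replacement) scatters around the full-data estimate with only
half the full estimator's sampling SD, `sd_full_sample()` rescales the
raw ensemble SD by the m-out-of-n factor sqrt(f/(1−f)) = 2 when an
error bar on the full-data fit is wanted; the raw `sd()` describes the
ensemble itself. Either way the spread mixes data resampling with the
optimizer's stopping variance along the soft parameter valley — the
same mixture any restart-based simplex calibration propagates.

## Components, budgets, projections

The source decomposition uses exactly two auxiliary solutions (the
production-free steady state and the production-free transient), so
pre + anthro + bio equals the full field to machine precision by
construction. Fate attribution of biological methane uses these
components (emission = Q_gx × bio share; mixed-layer oxidation = the
oxidation difference between the full and production-free runs), with
the "mixed layer" identified with the model surface layer — the layer
the exchange operator acts on. Export to the interior is computed
independently through the transport of the bio component out of the
surface layer (plus its storage change and any production injected
below the surface layer), so the ~1% budget-closure check is a genuine
conservation test, not an identity. Budgets average the last 10 output
years.

Projections perturb only the PO4 input of the production
parameterization (circulation, forcing, oxidation fixed) in two modes —
adding the scenario's absolute change (floored at zero) or multiplying
by its relative change; cells with zero scenario baseline are left
unperturbed and flagged in relative mode. Because the PO4 law does not
depend on C, the projected quantity is the integrated production rate;
re-integrating the tracer (supported via time-varying sources) changes
nothing about that trajectory. The synthetic scenario declines
low-latitude upper-ocean PO4 by ~25% (2005→2300, smoothstep in time),
and its baseline field is a deliberately *biased* rendering of the
world's PO4 (compressed toward 0.25 µM), the way a free-running climate
model's nutrient field differs from observations — which is exactly why
the absolute and relative applications differ.

## Known limitations

* Basin geometry is schematic; basin-level magnitudes are not
  comparable to real-ocean numbers, only their structure is.
* The deep ocean ventilates ~2–3× faster than the real Pacific, so
  anthropogenic penetration at depth is overstated.
* Annual-mean forcing only; no seasonal cycle in mixed layers, ice, or
  production.
* The oxidation threshold makes the steady-state problem piecewise
  linear; parameter sets that put many cells exactly at the threshold
  can slow the active-set iteration (the pseudo-time fallback covers
  this).
* Bootstrap SDs mix sampling and optimizer-stopping variance; they are
  honest uncertainty for the estimator actually used, but not pure
  sampling uncertainty.
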
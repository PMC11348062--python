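# Methods

## The model

`strandflow` models the cell-cycle composition of a quasi-1D multicellular
strand invading a 3D matrix from a spheroid or organoid.  The strand is
reduced to a ray `0 <= x <= x_max` co-moving with its tip (`x = 0` is the
tip; `x` is distance to tip, in µm).  Total cell density along the ray is
taken constant — strand width and cell size are not modeled — so the state
is the set of phase fractions `rho_i(x, t)`, `i ∈ {G0, G1, S, G2, M}`,
with `sum_i rho_i = 1` everywhere.

Cells progress sequentially G0 → G1 → S → G2 → M and divide at the M → G0
transition (two daughters, source factor `a_G0 = 2`).  Each fraction obeys
a 1D reaction–advection–diffusion equation

```
d rho_i/dt = d/dx( D d rho_i/dx ) - d( (V + V_i) rho_i )/dx
             + a_i e_i rho_{i-1} - b_i e_{i+1} rho_i + c rho_i
```

with shared diffusivity `D` (random migration), a phase-specific active
drift `V_i` (negative = toward the tip), and an extra source rate `c`
(apoptosis / lateral exchange; 0 by default).  Because the total density
is constant, the passive bulk velocity `V(x)` is not free: summing the
equations forces

```
V(x) = ∫_0^x ( e_G0 rho_M + c ) dx'  -  Σ_i V_i rho_i(x).
```

Newly created cells push everything away from their birthplace; with
divisions distributed at the stable rate, `V(x) ≈ e_base·x`, a rearward
flow in the tip frame.  The tip boundary carries no net flux
(`D d rho/dx - (V+V_i) rho = 0` at `x = 0`); the far boundary is
zero-gradient (advective outflow models cells passing out of the
quantified window).

**Transition rates.** The entry rates `e_i` are derived, not free: given
the stable far-field fractions `rho_i^stable` and the base rate
`e_base = ln 2 / t_double`, stationarity of the well-mixed system (with
dilution `e_G0 rho_M`) fixes

```
e_G0 = e_base/rho_M,          e_G1 = (2-rho_G0)/rho_G0 · e_base,
e_S  = (2-rho_G0-rho_G1)/rho_G1 · e_base,   ...
```

(each successive numerator subtracts one more stable fraction).  These
make the stable fractions an exact fixed point (unit-tested to 1e-12).

**Position-dependent cycle entry.** The G0 → G1 rate is suppressed near
the tip following an error function,
`e_G1(x) = c3 (c1 erf(x/c2) + 1)/(c1 + 1)`, with far-field value
`c3 = e_G1^stable`; `c1` sets the suppression depth (tip rate is
`c3/(c1+1)`), `c2` its length scale in µm.

**Age-structured G2.** To resolve how long a cell has been in G2 (the
quantity the EdU/cyclin-B1 double stain measures), G2 carries an age
density `psi(x, t, tau)` transported at unit speed in age, fed at
`tau = 0` by the S → G2 flux `e_G2 rho_S`, and drained to M at rate
`e_M'` only beyond a refractory age `tau'`.  `rho_G2` is the trapezoidal
age integral of `psi`.  Keeping the stationary M influx independent of
`tau'` requires

```
e_M' = e_M e_base / [ (e_base + e_M) exp(-e_base tau') - e_M ],
```

which reduces to `e_M` at `tau' = 0` and diverges at
`tau' = ln((e_base+e_M)/e_M)/e_base` (a longer refractory period than
that is inconsistent with the stable fractions; the constructor raises).
At well-mixed stationarity `psi(tau)` is the piecewise exponential
`exp(-e_base tau)` before `tau'` and
`exp(-(e_base+e_M')(tau-tau'))`-decaying beyond, which the solver
reproduces to ~0.003% relative L1.

## Parameters and presets

All rates are per minute, lengths in µm.  Two presets ship
(`spheroid`, `organoid`); their values are **provisional
reconstructions** — the printed sources fix the G2 drift speed
(`V_G2 = -0.05 µm/min`, the measured mean tip-approach speed of G2
cells), the estimators `e_base = ln2/t_double` and `D = rmsd²/2Δt`, and
the qualitative calibration rule that the entry-profile constants should
reproduce the observed S / non-G0 per-order distributions.

| symbol | spheroid default | meaning / rationale |
|---|---|---|
| `stable` | (0.40, 0.21, 0.20, 0.17, 0.02) | far-field fractions; imply textbook residences G1 ≈ 4.4 h, S ≈ 5.8 h, G2 ≈ 5.7 h, M ≈ 40 min at `t_double` = 24 h |
| `t_double` | 1440 min | doubling time of an exponentially growing culture |
| `D` | 1.0 µm²/min | rmsd ≈ 6 µm over 20 min; modest 3D random motility |
| `V_G2` | −0.05 µm/min | printed tip-ward drift; all other `V_i = 0` (M cells are non-migratory) |
| `c1`, `c2` | 2.0, 25 µm | tip entry rate one third of far field, recovering over roughly two cell lengths; yields an S per-order contrast of ≈30% |
| `tau'` | 60 min | G2 refractory period before mitotic entry |
| `tau0` | 120 min | default EdU incubation window |
| `x_max` | 400 µm | modeled strand window |

The organoid preset slows the cycle (30 h) and deepens/widens the entry
suppression (`c1 = 6`, `c2 = 50`), reflecting the stronger follower
enrichment of S cells there.  Every value is overridable per key in
config files or `preset(name, **overrides)`.

## Numerics

Operator splitting per step `dt`: reaction with exact-characteristic age
transport → spatial advection → diffusion → renormalization.

* **Reaction + age.** Transitions use simultaneous explicit fluxes from
  the pre-step state.  The `psi` column is shifted one age cell
  (`dtau = dt`, exact transport) with the per-cell survival factor
  `exp(-e_M' · overlap)` where `overlap` is the part of the step spent
  beyond `tau'` — this removes the O(dtau) error a naive masked decay
  leaves at the refractory boundary.  Whatever the G2 column loses
  (mitotic exit plus the truncated oldest age cell) is credited to M, so
  the reaction stage conserves the fraction sum exactly up to the
  intended division source.
* **Advection.** First-order upwind in flux form with face velocities
  averaged from nodes; zero flux at the tip face, extrapolated outflow
  at the far face.  CFL guard `dt·max|V+V_i|/dx ≤ 0.9`.
* **Diffusion.** Explicit, zero-flux ends; stability guard
  `D dt/dx² ≤ 0.45`.
* **Renormalization.** Splitting and discretization leave per-step
  deviations of `Σrho` of order 1e-4 (largest in the half-width boundary
  cells); each step clips negativity (magnitude accumulated in
  `total_clipped`) and rescales all fractions and `psi` proportionally;
  the pre-renormalization deviation is logged in
  `max_conservation_drift`.  Output fields therefore satisfy
  `|Σrho − 1| ≲ 1e-15`.
* **Age truncation.** `tau_max = tau' + 10/e_M'`; the tail mass
  (~`e^-10`) joins the M influx.
* **Resolution.** Defaults `dx = 2.5 µm`, `dt = 2.5 min`.  Halving both
  changes the 12-h M profile by 0.1% in the mean and ≤2.4% at the tip
  node (first-order convergence; the residual concentrates in the
  advective boundary layer `D/|V_G2| ≈ 20 µm`).
* **Steady states.** `stationary_state` integrates until the maximal
  field change rate drops below `tol` (default 1e-8 per minute),
  starting from the uniform stable state with the closed-form age
  profile.  The switch experiment relaxes with `V_G2 = 0` and turns the
  drift on at `t = 0`.

## The agent-based twin

`strandflow.synthesizer` re-implements the same model as discrete,
non-interacting agents: per step, phase transitions with probability
`1 - exp(-e dt)` (entry rate evaluated at the agent's position, G2 → M
gated by `phase_age > tau'`), division duplicating the agent in place,
then a Gaussian step `sqrt(2 D dt)` plus drift `(V(x) + V_phase) dt`.
The passive `V(x)` is computed from binned empirical phase fractions
(bin = `dx`; bins with fewer than 5 agents fall back to the stable
fractions) exactly as in the continuum model — crowding enters only
through this shared mean field, because the continuum model itself
encodes crowding only through the conservation-derived flow; the oracle
must match the model, not add physics.  The tip reflects; agents pushed
past `x_max` leave the window (phase-blind, so fractions are unbiased).
EdU bookkeeping stores each agent's last time in S and is inherited by
daughters, so a cell is EdU+ iff it (or its ancestor, within the window)
resided in S during the final `edu_window`.

Marker emulation maps true phases to the experimental panel: Ki-67+ for
any non-G0 cell, H3S10p+ for M, cyclin B1+ for G2 and M, EdU from the
pulse; each flag independently drops to "undetermined" with a
configurable probability (such cells are excluded from numerator and
denominator downstream, mirroring the conservative manual scoring of
ambiguous stains).  `sample_strands` draws "fixed and stained" strands
from a continuum state — nuclei at a configurable spacing (default
15 µm), phases from the local fractions, G2 ages from the local age
density — and is the observation unit for the per-order pipeline.

What the generator does **not** emulate: image formation (flags, not
pixels), optical attenuation with depth, cell–cell exclusion or
mechanics, strand branching or width changes, the cyclin-B1 tail into
late S (the marker caveat that some detected early G2 cells may be late
S cells; off by default).  Passing tests therefore demonstrate internal
consistency of model, twin and pipeline — not fidelity of any of them to
real image data.

## Quantification pipeline

Cells of a strand are ranked by distance to tip (stable ties); ranks 1–4
are kept individually, 5–8 pooled, later cells dropped.  Per-order
positivity fractions use the marker classes S = EdU+, M = H3S10p+,
proliferating = Ki-67+, G2 = CB1+ H3S10p−, early/late G2 additionally
EdU+/EdU−.  Relative percentages divide positives by a reference class's
positives per order.  The distance→order bridge measures mean distance
per order on the same synthetic dataset (midpoint rule for the inverse;
ties toward the tip) rather than assuming a fixed cell length.  Division
frequency is events / (duration × bin length), with the first 10 µm
excludable (nuclear centers rarely reach it).  Approach speed is
−Δ(distance)/Δt per track interval.

"Front-/rear-concentrated" is operationalized — the source terms are
verbal — as the sign of the (count-weighted) least-squares slope of
fraction against order index, with the pooled bin at abscissa 6.5 (its
mean order).  With counts, |slope| below twice its standard error is
"flat"; noise-free continuum profiles use an absolute tolerance
(default 0, i.e. classification by sign).

## In-silico experiments

* **G2-advection switch** (`experiment_g2_switch`): relax with
  `V_G2 = 0`, switch the drift on, record the first output time (5-min
  cadence) at which the per-order M profile classifies as
  front-concentrated, plus a secondary tip-versus-far M density
  criterion.  Both a `stationary` and a `uniform` initial state are
  supported; the published switch narrative does not pin down which
  state the drift was switched on from, so both are reported.
* **EdU-window sweep** (`experiment_edu_sweep`): early/late G2 per-order
  profiles from the stationary age-resolved solution for windows
  {15, 30, 60, 120} min; the early-G2 slope is reported mean-normalized
  so windows of different total mass are comparable.
* **Reduced advection** (`experiment_antimycin`): the steady state is
  recomputed with `V_G2` scaled by a factor (default 0.2, the
  mitochondrial-inhibition analogue); early-G2 and S per-order shapes
  (mean-normalized) are compared by their maximal per-order difference.

## Gating utilities

* **DNA-histogram deconvolution**: G0/G1 and G2/M as Gaussians, S as 20
  equal-width Gaussian-broadened slabs between the peak means with a
  second-difference smoothness penalty — the classical single-cycle
  structure; the reference software's exact S model is proprietary, so
  this stand-in is validated by parameter recovery only (mean absolute
  error ≈1.4 points over 50 random mixtures of 5000 cells).  The fit is
  two-stage: each peak is first characterized locally by a Gaussian plus
  constant baseline (the baseline absorbs the S density under the peak,
  which otherwise makes the width unidentifiable and lets slabs
  masquerade as peak shoulders), then a bounded Nelder–Mead polish and a
  single non-negative least squares for all weights.  A mode can only be
  read as the G2/M peak if the histogram is populated at half its
  intensity.  Phase percentages use each component's in-range mass (an
  off-range component can carry any nominal weight at zero observable
  density).  Gates sit where adjacent fitted component densities cross;
  the lower gate is inclusive to S, the upper to G2/M.  The G2/G1 ratio
  is constrained to [1.8, 2.1]; data that cannot be explained inside
  that window surface as a non-convergence error.
* **Fucci4 classification**: per channel, positive at or above the Otsu
  threshold, negative below half of it, undetermined between; mMaroon1
  (histone-fused, never fully dark) only confirms construct expression
  at or above half threshold.  Stage rules: G1(0) = mKO2+ Clover−;
  S = Clover+ and (mTurquoise2+ or mKO2+); G2/M = mTurquoise2− mKO2−
  mMaroon1-expressing, split by the "condensed" flag — which is an
  *input* (nuclear morphology is out of scope).  Negative calls alone
  never force a stage.
* **PercevalHR**: OLS calibration `r_PercevalHR = k·r_pHRed + q` on an
  alkalization series; corrected ratio `r_corr = r_PercevalHR −
  k·r_pHRed`; normalization to the control-group mean or to each cell's
  first-division frame.

## Statistics

Chi-square test of independence (no continuity correction) across order
bins, pairwise 2×2 comparisons of each order against the leader with
Bonferroni adjustment, exact conditional binomial comparison of two
Poisson means (two-sided by summing outcome probabilities no larger than
the observed; mid-p variant by flag — the source names only the test
family, so the conditional exact form is this package's documented
choice), and the Mann–Whitney rank test (exact enumeration for tie-free
combined n < 20, tie-corrected normal approximation otherwise).  All
tests are two-sided; stars at 0.05/0.01/0.001/0.0001.  At small counts
the exact conditional test is discretely conservative; its null p-values
approach uniformity only for counts in the hundreds.

## Known limitations

* **Timescale of the M-profile flip.**  From the fully relaxed
  entry-suppressed steady state, switching `V_G2 = −0.05 µm/min` on
  turns the per-order M profile front-concentrated only after ~2 h
  (spheroid preset: 110 min by the order-profile criterion, 95 min by
  the tip-density criterion).  The M gain at the leader position is
  rate-limited by `e_M' ×` (G2 tip excess) while the initial M deficit
  inherits ≳40% of the S contrast through the G2 stage; parameter scans
  over `D`, `c1`, `c2`, `rho_M` show a sub-30-min flip would require an
  S contrast too small to be distinguishable — the fast flip is
  reproduced only when the drift is switched on before the M deficit has
  developed (uniform start: 25 min).
* **EdU-window sweep.**  The early-G2 slope is monotone in the window
  and flattens toward front-concentration, but crosses zero only for
  windows of several hours at the printed drift speed: a cohort needs
  age ≈ (deficit length)/(net drift) to enrich at the tip, and the
  conservation-derived passive outflow `e_base·x` cancels roughly half
  of `V_G2` beyond ~50 µm.  Observed sign changes within 2 h imply a
  larger effective approach speed than the constant −0.05 µm/min used
  here.
* **Fast-cycling regime.**  Below a doubling time of ≈16 h (spheroid
  preset) the passive outflow outgrows the fixed G2 drift and the steady
  M profile loses its front concentration.
* The model has no mechanics (forces, friction, stress), no 2D/3D
  geometry, no reversible G0↔G1 transition, and treats `D` as
  phase-independent.
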
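# strandflow

Cell-cycle phase transport along collectively invading tumor strands.

Solid tumors often invade 3D matrices as quasi-1D multicellular strands.
Along such a strand the cell-cycle phases are distributed unevenly: S-phase
and Ki-67+ proliferating cells are enriched at follower positions, yet
mitotic (M) and G2 cells concentrate at the leader position.  `strandflow`
implements a continuum model that reconciles these observations: phase
fractions `ρ_i(x,t)`, `i ∈ {G0, G1, S, G2, M}`, obey coupled 1D
reaction–advection–diffusion equations

    ∂ρ_i/∂t = ∂/∂x( D ∂ρ_i/∂x ) − ∂((V + V_i) ρ_i)/∂x
              + a_i e_i ρ_{i−1} − b_i e_{i+1} ρ_i + c ρ_i,   Σ_i ρ_i = 1,

on a ray co-moving with the strand tip (x = 0), with

* sequential phase progression at rates `e_i` derived from the observed
  stable phase fractions (`e_base = ln2/t_double`),
* a cell-cycle entry (G0→G1) rate suppressed near the tip,
  `e_G1(x) = c3 (c1 erf(x/c2) + 1)/(c1 + 1)`,
* a passive bulk flow forced by conservation,
  `V(x) = ∫_0^x (e_G0 ρ_M + c) dx' − Σ_i V_i ρ_i`,
* a tip-ward drift of G2 cells only, `V_G2 = −0.05 µm/min`, and
* an age-structured G2 compartment `ψ_G2(x,t,τ)` with a refractory period
  τ′ before mitotic entry at rate
  `e_M' = e_M e_base / [(e_base+e_M) e^{−e_base τ′} − e_M]`,

so that "early" versus "late" G2 cells (age ≤ or > the EdU incubation
window τ0) can be compared with EdU / cyclin B1 / H3S10p / Ki-67 staining
readouts.  The package bundles:

* `strandflow.solver` — a finite-volume integrator for the coupled
  equations (upwind advection, explicit diffusion, exact-characteristic
  age transport);
* `strandflow.synthesizer` — an agent-based stochastic twin that doubles
  as a synthetic-data generator (strand snapshots with marker panels and
  dropout, tracks, division events, EdU pulses);
* `strandflow.analysis` — the strand quantification pipeline (cell
  orders 1–4 and pooled 5–8, per-order marker fractions, relative
  percentages, distance↔order bridge, division frequency, approach
  speeds, invasive index, front/rear slope classification);
* `strandflow.stats` — chi-square independence with Bonferroni pairwise
  comparisons against the leader, exact Poisson-means comparison,
  Mann–Whitney;
* `strandflow.gating` — single-cycle DNA-content histogram
  deconvolution with gates, Fucci4 Otsu/half-threshold classification,
  PercevalHR pH correction;
* `strandflow.experiments` + a `strandflow` CLI — end-to-end recipes
  (G2-advection switch, EdU-window sweep, reduced-advection analogue).

It is aimed at quantitative cell biologists and biophysical modelers who
want to test leader/follower cell-cycle mechanisms against tabular strand
data without any imaging infrastructure.

## Worked example

```python
from strandflow import preset, Grid
from strandflow.experiments import experiment_g2_switch

params = preset("spheroid")                 # documented provisional preset
grid = Grid.for_params(params, dx=2.5, dt=2.5)

rep = experiment_g2_switch(params, grid, t_end=360.0, seed=0)
print("initial M per-order profile:", rep.tables["initial_profiles"]["M"].round(4))
print("initial classification:", rep.slopes["M_initial"]["label"])
print("order-profile flip at t =", rep.flip_time_min, "min")
print("tip-density flip at t =", rep.statistics["tip_density_flip_min"], "min")
print("final classification:", rep.slopes["M_final"]["label"])
```

prints

```
initial M per-order profile: [0.0181 0.0183 0.0188 0.0193 0.0198]
initial classification: rear-concentrated
order-profile flip at t = 100.0 min
tip-density flip at t = 95.0 min
final classification: front-concentrated
```

Read: before the switch, the entry-suppressed steady state has mitotic
cells mildly depleted at the leader position (fractions rise from 1.81%
at order 1 to 1.98% in the pooled 5–8 bin — "rear-concentrated").  After
the tip-ward G2 drift is switched on, G2 cells pile up at the tip and
feed local divisions; the per-order M profile inverts to
front-concentrated after 100 simulated minutes (95 min if scored by tip
versus far-field M density).  Starting instead from a flat M profile
(`init="uniform"`), the inversion registers within ~25 min.

The same model components are scriptable from the shell:

```bash
strandflow simulate --preset spheroid --t-end 1440 --plot --out out/sim
strandflow synthesize --preset spheroid --seed 17 --out out/synth
strandflow analyze --snapshots out/synth/snapshot_t720.csv --out out/report
strandflow run edu-sweep --preset spheroid --out out/sweep
```

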
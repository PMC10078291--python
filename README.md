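# kineticnet

Temporally resolved gene-regulatory networks from kinetic chromatin
accessibility (ATAC-seq) and nascent transcription (PRO-seq) time courses,
with a two-compartment model of RNA polymerase II kinetics.

Conventional regulatory networks drawn from snapshot data miss transiently
acting factors and give every edge the same abstract meaning.  `kineticnet`
targets densely sampled stimulation time courses (for example the first four
hours of induced adipocyte differentiation, sampled at 0, 20, 40, 60, 120,
180 and 240 min with replicated ATAC-seq and PRO-seq): it classifies
accessibility peaks into five kinetic classes, assigns each TF family an
opener/closer direction of effect from single-motif dynamic peaks, and builds
a bipartite directed graph in which a **trans-edge** (TF family → regulatory
element) asserts an inferred change in factor occupancy and a **cis-edge**
(regulatory element → gene) asserts a regulatory effect on transcription.
Every edge carries the time interval over which it acts, plus binding /
dissociation and attenuation attributes, so time-respecting subgraphs and
multiwave signaling cascades fall out of the graph directly.

It is written for computational genomicists who have peak/gene count
matrices and strand-specific nascent-transcription signal, and who want
mechanistic, time-stamped edges rather than co-expression links.

## The pieces

* **Accessibility dynamics** — median-of-ratios normalization, per-feature
  negative-binomial Wald tests between all pairs of time points (BH-corrected,
  with an effect-size floor), and deterministic assignment to
  immediate/transient/gradual increase, transient/gradual decrease, or
  nondynamic.
* **Motif analysis** — log-odds PWM scanning on both strands with exact
  score-distribution p-values (dynamic programming over a 1000-bin score
  lattice, FIMO-style p ≤ 1e-4), motif-density composites around peak
  summits, and direction-of-effect assignment from dynamic peaks containing
  a single family motif.
* **PRO-seq metrics** — pause summits (max sense signal within 1 kb of the
  TSS), 50-bp pause regions, pause indices `PI = pause density / body
  density`, differential transcription, and anchored composite profiles.
* **Actionable distance** — for each factor, the difference between the
  TSS-to-nearest-factor-summit CDFs of dynamic and unchanged genes; the
  plateau of `Δ(d) = CDF_dyn(d) − CDF_unchanged(d)` (99% of its maximum on a
  500-bp grid, permutation-tested) bounds how far the factor acts.
* **Network inference** — the six trans-edge rules (peak, motif, significant
  change, direction matching the factor's function, expression timing,
  cocktail exemption with GR restricted to the first 40 min and SP to ≥ 40
  min) and the cis-edge rules (≤ 10 kb to the gene body, sign-consistent
  covariation over overlapping intervals, factor comparison set and distance
  cap from the CDF analysis), plus attenuation flags, constrained-subnetwork
  counts, and time-respecting downstream reach.
* **Cooperation statistics** — stratified 2×2 tables of genes by dynamic
  status and factor proximity, with Woolf 95% odds-ratio confidence
  intervals (Haldane-corrected).
* **Compartment model** — `dP/dt = k_init − (k_pre + k_rel)·P`,
  `db/dt = (k_rel·P − k_elong·b)/L`; steady state `P* = k_init/(k_pre+k_rel)`,
  `b* = k_rel·P*/k_elong`, residency `τ = 1/(k_pre+k_rel)`; grid fitting of
  fold changes `(f_init, f_rel)` between occupancy snapshots with `k_pre`
  and `k_elong` held fixed.
* **Synthetic data** — a single-chromosome generator with a planted
  six-family program (cocktail-activated AP-1/CEBP/GR-like openers, induced
  KLF-like opener and TWIST2-like closer, a repressed SP-like opener whose
  promoter elements close as the factor dissociates), negative-binomial
  counts, and a serialized TruthSet for benchmarking recovery.

## Worked example

Fit the fold changes in initiation and pause release that map one pause/body
occupancy snapshot onto another:

```python
from kineticnet import RateParams, TwoCompartmentModel, steady_state
from kineticnet.compartment import consistent_base_grid

base = RateParams(k_init=10.0, k_pre=1e-6, k_rel=60 / 29, k_elong=2500.0)
occ0 = steady_state(base)                       # P* ~ 4.83, b* ~ 0.004
occ1 = steady_state(base.scaled(1.07, 1.50))    # after the regulatory change
fit = TwoCompartmentModel(occ0, occ1).fit(grid=consistent_base_grid(occ0))
print(fit.summary())
```

```
Two-compartment Pol II fold-change fit
======================================================
consistent base sets : 20 (tol 0.01)
occ t1 (P, b)        : 4.833, 0.004
occ t2 (P, b)        : 3.448, 0.00428
------------------------------------------------------
f_init :   1.0700   [1.0700, 1.0700] across grid
f_rel  :   1.5000   [1.5000, 1.5000] across grid
------------------------------------------------------
base set: k_init=9.667/min, k_pre=0/min, k_rel=2/min, k_elong=2417 bp/min
pause residency : 30.0 s -> 20.0 s
initiation rate : 9.67 -> 10.3 pol/min
```

A 1.07-fold increase in initiation with a 1.50-fold increase in pause
release reproduces the occupancy change, and with premature termination
negligible the recovered fold changes are identical for *every* base rate
set consistent with the first snapshot (zero spread across the grid) — the
identifiability property the model is built around.  The default
`fit()` scans the full two-orders-of-magnitude base grid instead and
reports the spread of fold changes across all near-consistent sets; the
residency time drops by the factor `f_rel` (29 s to about 19 s at the rates
above) whichever consistent base set is chosen.

Run the full synthetic pipeline (simulate → infer → evaluate against the
planted truth):

```bash
kineticnet run-all --seed 7 --out runs/demo
```

which reports, among other things, planted-edge precision/recall, the
per-factor compartment fits, and the most-connected non-cocktail gene node
(the TWIST2-like repressor under the default program).

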
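# Methods

## Scope and data model

`kineticnet` analyzes a replicated two-assay time course: chromatin
accessibility counts over peaks and nascent-transcription (pause-region and
gene-body) counts over genes, sampled at a shared set of time points that
starts at 0 (default 0, 20, 40, 60, 120, 180, 240 min, three replicates).
All genomic coordinates are 0-based half-open (BED native) throughout;
summits are stored as offsets from peak starts so they survive interval
clipping.  bedGraph is the required signal dialect — it is plain text and
testable without compiled readers; bigWig input is deliberately out of
scope.

## Differential calls

Counts are modeled per feature as negative binomial.  Libraries are
normalized by median-of-ratios size factors (`factor_j = median_i
counts_ij / geomean_i`, over features positive in every sample; an optional
pseudocount rescues degenerate matrices).  Note that only *ratios* of size
factors are identified: scaling one library by *c* scales its factor by *c*
relative to the others, while the geometric-mean reference absorbs a common
`c^(1/m)`.

Per-feature dispersions are method-of-moments estimates from pooled
within-time-point residual variance, `alpha_hat = max(0, (s^2 - mu)/mu^2)`,
shrunk 50/50 (arithmetic blend) toward a log-linear trend of dispersion on
mean.  The trend is fitted to *binned arithmetic means* of the raw
estimates (about ten mean-quantile bins): the raw estimator is strongly
right-skewed at three replicates, and a log-linear fit to the raw values
underestimates the trend by the Jensen gap, which we measured as an
anti-conservative bias before switching to binned means.

Each pair of time points is compared with a Wald test on the log ratio of
normalized group means (delta-method standard error `sqrt((1/m_a + alpha)/n_a
+ (1/m_b + alpha)/n_b)` with a half-count offset so zero means stay
defined), BH-corrected within the comparison.  A feature is *called* only
when `q <= 0.05` **and** `|log2FC| >= 0.5`.  The effect-size floor exists
because all `C(T,2)` comparisons are tested per time course: per-comparison
FDR control still lets small-effect false positives accumulate across the
union of 21 comparisons, and the biology of interest here is severalfold
changes.  Both thresholds are configurable.

This machinery is intentionally simpler than full GLM-based count packages:
no exact NB likelihoods, no MAP shrinkage of fold changes.  It is not meant
to replicate any existing tool numerically; its calibration is checked
directly (type-I error at `q < 0.05` on 10,000 null NB features stays below
5%).

## Kinetic classes

Dynamic peaks are assigned deterministically (no clustering, no seed):

* no significant comparison → `nondynamic`;
* direction = sign of the first significant change (smallest end point,
  then smallest start);
* `transient_*` when a later significant change of opposite sign exists and
  the final level has returned within 50% of the peak excursion of
  baseline;
* otherwise increases are `immediate_increase` when the first significant
  change is against the second time point, else `gradual_increase`;
  non-transient decreases are `gradual_decrease` (the scheme has no
  immediate-decrease class).

Deterministic rules were chosen over model-based trajectory clustering so
class assignments are reproducible and unit-testable; borderline
trajectories may split differently than a clustering would.

## Motif scanning

Scanning is log-odds in bits against a background (uniform by default) on
both strands.  Score p-values are exact: per-position scores are rounded
onto an integer lattice spanning 1000 bins across the motif's total score
range, and the full null distribution of lattice scores is computed by
convolution across positions.  The hit threshold is the smallest lattice
score with exact p ≤ 1e-4 (short motifs may have no achievable score that
extreme, in which case the scan returns nothing at that threshold).  Both
the reported p-values and the threshold live on the lattice, so they agree
*exactly* with brute-force enumeration over all sequences scored with the
same lattice; reported bit scores are computed from the unrounded matrix.
`N` bases contribute 0 bits.

Motif-density composites weight each hit by its *score fraction* (bit score
over the maximum achievable).  The upstream notion of "conformity to a
composite motif" is not given as a formula anywhere we could adopt it from;
score fraction is this package's choice of conformity weight.

Direction of effect per family is the majority class of dynamic peaks
containing **only** that family's motif: opener if more than half are in
increase classes, closer if more than half decrease, unassigned on a tie.
Paralogous-family ambiguity (e.g. SP/KLF-type motifs) is not adjudicated:
shared sites are reported for both families, and the single-motif subset
simply excludes them.  Curated overrides exist because a canonical
activator that *dissociates* scores as a closer from single-motif peaks;
the default rules override the SP-like family to "opener" on that
biological ground, mirroring how the direction was resolved in the system
this package emulates.

## Actionable distance (CDF analysis)

For a factor, "its REs" are the dynamic peaks carrying its motif.  For each
pairwise comparison, genes changing in the factor's direction (the majority
first-change direction of its REs — accessibility and transcription covary
in the same direction under every binding/dissociation case) are compared
with unchanged genes on the distance from TSS to the nearest factor-RE
summit.  `Δ(d) = CDF_dyn(d) − CDF_unchanged(d)` is evaluated on a 500-bp
grid; the *plateau* is the smallest `d` reaching 99% of `max Δ`, and
`max Δ` is tested by permuting gene labels (p = (1 + #null ≥ obs)/(perms +
1)).  Comparisons with p < 0.05 form the factor's allowed cis-edge
comparison set; the factor's distance cap is the largest plateau across
them.  A factor with no significant comparison draws no cis-edges —
conservative by design.  For constraint derivation the grid stops at 20 kb
(constraints can never exceed the 10-kb cis rule, and evaluating further
only adds unrelated-neighbour noise to the plateau); the standalone
`plateau_distance` keeps the full 200-kb default range.  Both the plateau
convention (99% of max) and the permutation test are this package's
formalization of a "plateau" description that exists only qualitatively
upstream.

## Network rules

Trans-edges (family → RE), all six conditions required: (1) the RE is an
accessibility peak; (2) it contains the family motif; (3) accessibility
changes significantly over the interval; (4) the direction matches the
family function (opener binding or closer dissociation opens; the converse
closes — mismatched direction yields the *dissociation* attribute rather
than no edge); (5) the family gene is expressed (body density above the
25th percentile of nonzero densities at the relevant time point — later
time point for binding, earlier for dissociation; the percentile floor is
this package's operationalization of "expressed", since no cutoff is
inherited) and, for families not directly activated by the stimulus,
significantly activated (binding) / repressed (dissociation) no later than
the edge start; (6) cocktail families (AP-1-, CEBP-, GR-like) get early
binding edges without the activation requirement (through 20 min; through
40 min for GR, whose binding window is capped there).  GR-like dissociation
edges additionally require a prior binding edge at the same RE; SP-like
edges cannot start before 40 min.  All windows and family sets are
configuration, not code.

Cis-edges (RE → gene): gap between RE and gene body ≤ 10 kb; a significant
gene call whose interval overlaps (closed-interval intersection on minutes)
a trans-edge at the RE with the matching implied direction; the gene
dynamic in at least one comparison of the factor's CDF set; TSS-to-summit
distance within the factor's CDF cap.  Contributing families are all
families whose trans-edges satisfy those conditions; the edge interval is
the gene comparison's two time points verbatim.  Whether intervals must
*overlap* or be *equal* is genuinely ambiguous in the source description;
overlap is the default and `strict_interval_equality=True` is the switch.

An edge is *attenuated* when its RE (trans) or gene (cis) shows a later
significant change of opposite sign starting no earlier than the edge's
end.  Downstream reach uses time-respecting traversal: an edge is admitted
only if its interval starts no earlier than the arrival interval's start,
with minimal arrival start kept per node.

The rule engine is verified edge-for-edge against an independently written
nested-loop applicator on 50 random instances of up to 200 REs.

## Compartment model

States: `P` (polymerases in the pause region) and `b` (gene-body density,
polymerases/bp over a body of `L` bp):

```
dP/dt = k_init − (k_pre + k_rel)·P
db/dt = k_rel·P/L − (k_elong/L)·b
```

The body-exit term `−(k_elong/L)·b` is the minimal first-order form whose
steady state `b* = k_rel·P*/k_elong` is consistent with the
residency/initiation arithmetic the analysis relies on; it is an explicit
modeling choice.  Steady state is assumed at each measured time point when
fitting (occupancy snapshots); transient integration is available through
`integrate_occupancy`.

Fitting between two snapshots holds `k_pre` and `k_elong` fixed and solves
in closed form, per base rate set:

```
f_rel  = b2·k_elong / (k_rel·P2)
f_init = P2·(k_pre + f_rel·k_rel) / k_init
```

The default base grid is 25 log-spaced values per decade over two decades
for `k_init` (0.5–50/min), `k_pre` (0.02–2/min), `k_rel` (0.2–20/min) and
10 linear values of `k_elong` in 600–6000 bp/min; sets reproducing the
first snapshot within 1% relative (both P and b) are retained.  The point
estimate is taken at the minimum-residual set, ties broken toward `k_elong`
nearest the 2500 bp/min consensus elongation rate and then smaller `k_pre`.
Identifiability: two snapshots pin only `k_init/(k_pre+k_rel)` and
`k_rel/k_elong`, so `f_rel` is recovered exactly for *any* consistent base
set, while `f_init` depends on the set's `k_pre/k_rel` ratio — its spread
across the grid is exactly zero at `k_pre = 0` (`consistent_base_grid`
exposes the exactly-consistent manifold for this) and grows continuously
with `k_pre/k_rel`.  Because the occupancy snapshots cannot identify
`k_pre`, absolute residency times from a grid fit inherit the selected base
set's `k_pre`; the residency *ratio* `τ2/τ1` is scale-free and is what the
pipeline reports.  Units are minutes and bp internally; residency is
reported in seconds.

## Pause metrics

The pause summit is the maximum sense-strand signal within 1 kb downstream
of the TSS, ties broken toward the TSS; the pause region is the 50-bp
window around it and the gene body starts 250 bp downstream of the summit
(the body window is unstated upstream; 250 bp clears the pause peak and its
shoulder).  `PI = pause density / body density`, undefined (flagged, and
excluded from summaries) when body density is zero.  Genes with zero signal
in the search window are flagged and excluded.  The divergent-transcription
caller (opposing-strand local maxima within 300 bp, minus peak upstream) is
a deliberately simple rule-based stand-in for learned bidirectional-peak
detection and is labeled non-equivalent.

## Cooperation statistics

Genes are stratified by proximity to factor A's inferred REs (dynamic peaks
with the A motif, within A's CDF distance cap) and cross-classified by
dynamic status and proximity to factor B.  `OR = ad/bc` with the Woolf
interval `exp(ln OR ± 1.96·sqrt(1/a + 1/b + 1/c + 1/d))` and the
Haldane–Anscombe +0.5 correction when a cell is empty; the CI method is this
package's choice (verified to ~95% coverage at n = 200 per stratum, and
cross-checked against an independent implementation in the tests).

## Synthetic data: what it emulates, and what it does not

The generator builds one chromosome with genes every 20 kb (every fifth
gene on the minus strand) and a six-family program mirroring the early
adipogenic cascade: immediate-increase elements for the AP-1/CEBP-like
cocktail openers, transient-increase for the GR-like opener (binding then
dissociation), gradual-increase for the induced KLF-like opener,
early-decrease for the induced TWIST2-like closer, and late-decrease
promoter-proximal (60–300 bp) elements for the SP-like opener whose gene is
repressed by the TWIST2-like factor — giving the planted cascade cocktail →
TWIST2-like → SP-like → attenuation.  Six shared AP-1+GR elements plant the
cooperation signal.  Dynamic accessibility levels step between 1 and 3
(3-fold); 60% of early activated targets (80% of GR-like targets) carry a
later inverse fold (planted attenuation).  Family genes get fixed baseline
initiation rates (the program requires them above the expression floor when
they act); target/background genes draw log-normal baselines.  Defaults:
560 peaks with 74 planted dynamic elements (13% dynamic, the fraction the
emulated ATAC time course reported), 120 genes, NB dispersion 0.05 with
log-normal (σ = 0.08) replicate library sizes, ~200 mean counts per peak.

PRO-seq pause/body means are *exactly* the compartment-model steady states
of each gene's planted rate parameters (baseline `k_pre = 0.2/min`,
`k_rel = 2/min`, `k_elong = 2500 bp/min`) after cumulative per-interval fold
changes — the generator imports the model, so generator/model consistency
is structural.  Signal tracks place a triangular pause peak (area = pause
occupancy) at TSS+40, uniform body signal, and a divergent antisense peak
upstream of each promoter.

The planted truth *network* is the closure of the documented inference
rules over the exact (noise-free) trajectories, calls, scans and CDF
constraints — the self-consistency the recovery benchmarks require.  The
rule engine itself is validated against the independent brute-force
applicator, so this construction does not test the rules against
themselves; what the noiseless benchmark shows is that the estimation
pipeline (normalization, testing, classification, constraint derivation)
reproduces the exact quantities, and what the noisy benchmark adds is
robustness of the calls under the stated noise model.

Not emulated: fragment-level read structure (FASTQ, Tn5/fragment-length
bias), mappability, diploid genomes, peak calling, inter-replicate batch
structure, motif grammar beyond a single embedded consensus per family, and
real count variance structure (the NB-with-shared-dispersion assumption is
ours).  Passing recovery tests therefore demonstrates internal consistency
and noise robustness under these conditions, not performance on real
libraries.

## Problem sizes and determinism

Test and demonstration runs use the default 560-peak/120-gene program (20
seeds for recovery benchmarks; scaled-down 400-peak/110-gene conditions for
fast unit fixtures), 120–300 permutations inside pipeline runs (the
standalone plateau test defaults to 1,000), and Monte-Carlo sizes of
1,000–10,000 where distributions are checked.  All randomness flows through
`numpy.random.default_rng` seeded from the run seed; reruns with the same
seed are byte-identical, including the exported edge tables.

## Known limitations

* Median-of-ratios normalization assumes changing features are a minority;
  compositions with ≳40% co-directional change bias the factors (visible in
  the generator if `n_res` is shrunk without shrinking the planted
  program).
* The Wald test is asymptotic; at three replicates its calibration leans on
  the dispersion trend, and the effect-size floor is part of the stated
  call definition.
* `k_pre` and absolute residency are not identifiable from two occupancy
  snapshots; only fold changes and residency ratios are.
* Edge intervals quantize to measured time points; events between samples
  are invisible, and "immediate" is relative to the second time point.
* The CDF constraint transfers a population-level proximity signal to
  individual edges; individual enhancer–gene assignments remain heuristic.
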
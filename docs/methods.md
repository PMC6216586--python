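# Methods

## Design being analyzed

Two haploid parents — one long-lived, one short-lived — are intercrossed
for several generations to build an advanced intercross line (AIL);
replicate pools of the segregants are grown to stationary phase and then
age without dividing. Pools are sequenced on successive days, and the
frequency of the long-lived parent's allele is tracked at every
segregating marker. Survival selection during aging pushes longevity
alleles up in frequency; the analysis asks, per locus, whether the
observed count trajectory departs from a constant-frequency explanation
more than chance allows, and whether such departures have the spatial
(linkage) structure genuine selection must produce.

## Trajectory score

Counts `(k_t, n_t)` at one locus in one replicate are modeled as
`k_t ~ Binomial(n_t, p_t)` independently across time points (read
sampling), with two hypotheses:

* null: `p_t = p` for all `t`; the MLE is the pooled fraction
  `p̂ = Σk_t/Σn_t` (exact, not iterative);
* saturated: `p_t = k_t/n_t` free per time point.

`S_r = log L₁ − log L₀ ≥ 0`. Time points with `n_t = 0` contribute
nothing; a trajectory needs at least two informative time points
(`min_informative = 2`, minimum per-point depth configurable,
default 1) or its score is undefined (NaN, never silently zero).
Boundary terms use the likelihood limit `0·log 0 ≡ 0`; log-pmfs are
evaluated with `scipy.stats.binom.logpmf`, and tiny negative differences
from floating-point cancellation are clamped to zero. Replicates are
independent pools, so the combined score is the **sum** of defined
per-replicate scores, with the contributing count recorded. The
combination rule is a design choice (the joint likelihood ratio under
independence); no asymptotic p-values are attached — calibration is
empirical, via the threshold below — because drift and linkage make the
χ² limit an upper bound rather than the null law.

An optional mode scores genome-smoothed frequencies (Gaussian kernel
along the genome, depth-weighted, default bandwidth 10 kb) in place of
the saturated `k_t/n_t`. It is a simple, documented stand-in for
probabilistic frequency smoothing and is off by default: the scorer's
definition is count-based.

## Neighbor-support filter

Selection at a locus drags linked neighbors along, so true signals are
ridges. With the genome-wide IQR of combined scores (linear-interpolation
quantiles throughout the package), a locus is filtered when its score
differs from **both** genomic neighbors by more than the IQR;
chromosome-terminal loci are compared to their single neighbor. The
stricter at-least-one-neighbor variant is available (`rule="either"`).
The both-neighbors default encodes the filter's purpose — removing
isolated spikes that lack hitchhiking support — while leaving the shared
edges of genuine ridges alone.

## Scan, threshold, peaks

Filtered, defined scores are smoothed per chromosome with a physical
sliding median: at each marker, the median score of all unfiltered
markers within an inclusive, centered 50 kb window (`window = 50_000` bp;
a marker alone in its window keeps its own score). The threshold
`τ = Q3 + 1.5·IQR` (`iqr_multiplier = 1.5`) is computed genome-wide on
the unsmoothed, neighbor-filtered per-locus scores; a per-chromosome mode
exists behind a flag. Peak regions are maximal runs of consecutive
unfiltered loci with smoothed score above `τ`, merged across gaps
smaller than the window (sub-window gaps are unresolvable at the
smoothing scale); within each region, individual variants with
unsmoothed score above `τ` are reported as candidates. Regions are
ranked by maximum smoothed score. Using smoothed values for regions but
raw scores for candidate variants reflects the dual use the analysis
requires: regions localize, variants nominate.

## Regrowth pleiotropy screen

Three samples per pool: day 0, day 6, and day 6 regrown. Per marker,
lifespan ΔAF = AF(day 6) − AF(day 0) and growth ΔAF =
AF(regrown) − AF(day 6); a marker is informative only with depth ≥ 10 in
all three samples (the published analysis required "sufficient" depth
without a number; 10 is an explicit, tunable proxy). With cutoff
`c = 0.15`, the screen reports the fractions of informative loci with
|lifespan ΔAF| > c and |growth ΔAF| > c, the antagonistic set (both
exceed `c` with opposite signs — sign discordance is the operative
definition; the joint-exceedance count without the sign requirement is
emitted alongside), and the Pearson correlation of the two changes.

## Lifespan curves

Viability is the triplicate-mean CFU count normalized to day 0, with
first-order SD propagation. Median lifespan is the first
linearly-interpolated crossing of 0.5 (undefined — returned as `None` —
if the curve never crosses); maximal lifespan is the last day with
viability above a floor `ε = 0.01` (an explicit stand-in; the notion of
"maximal" has no standard operational definition). The survival integral
is the trapezoidal area under viability over the observed days. Raw
curves can be non-monotone from plating noise; statistics use raw values
by default and a non-increasing isotonic fit is available. The
phloxine-stain correction converts a stained-cell tally (protocol: 500
cells counted) into the culture volume holding a target number of live
cells, `volume = L/(D·f)` with `f` the live fraction.

## Marker vetting

Two caller outputs are combined (union by default — "combining" two call
lists most plainly keeps either's sites and lets the filters vet them;
intersection is available) with provenance recorded; conflicting REF
alleles at one position abort. Filters run in a fixed order (min depth
10, max depth 5× the median site depth, alternate fraction ≥ 0.99 — the
only published value — bad/split-read fraction ≤ 0.1, repeat-interval
overlap, then proximity), each rejected site carrying its first failing
rule so reasons partition the rejects. The proximity rule (min distance
10 bp) removes *both* members of any too-close pair and considers all
input sites; it runs last so that, among the order-dependent rules, only
the one with pair semantics is affected by ordering. Coordinates are
1-based inclusive for markers and 0-based half-open for BED, converted
only at the IO boundary.

## Forward simulator

What it emulates: haploid segregants as binary haplotypes over a marker
map (default ~4500 markers on three chromosomes with pombe-like lengths,
near-even spacing with jitter); repeated intercrossing (default 6
generations, matching the use of F6 pools) as random pairing, meiosis,
and fitness-proportional resampling with per-individual log-fitness
`Σ g_j x_j` — the competitive-growth step that skews allele frequencies
across generations; stationary-phase aging as per-day Bernoulli survival
with probability `logistic(β0 + Σ s_j x_j)` and no division; Pool-seq as
Poisson depth (`λ` = 100 deep, 10 pilot-like) with binomial allele
counts. Replicate pools are bootstrap resamples of the final intercross
generation. Truth tables (causal loci and true frequencies) are always
emitted for parameter-recovery testing.

Crossovers per chromosome are Poisson with mean equal to the map length
in Morgans, positions uniform on the genetic map (no interference).
Implementation detail: counts are drawn per inter-marker interval (the
Poisson process restricted to each interval) and parental origin
switches on odd counts — distribution-identical at marker resolution to
drawing positions directly, and fully vectorized; end segments beyond
the terminal markers still contribute to the per-chromosome crossover
tally.

Key defaults and why:

* **Map density 0.18 cM/kb** (~1 cM per 5.5 kb): the fission-yeast
  genome-wide average (~2300 cM over 12.6 Mb). The width of hitchhiking
  blocks is what the neighbor filter and the 50 kb sliding median rely
  on; a substantially denser map (e.g. 0.5 cM/kb) produces linkage
  blocks too narrow to support the ~100 kb selected regions this design
  is meant to detect, and score ridges so steep that the neighbor filter
  removes genuine signals.
* **β0 = 1.0** (logit units/day): ~73% daily survival, i.e. ~20%
  viability at day 5, matching the viability range over which the main
  experiment's pools were sampled.
* **Pool size 1000–2000 individuals**: a computational stand-in for
  macroscopic cultures. It adds drift a real pool would not have; all
  calibration properties below are measured under this census.
* **Mortality is logit-additive** across loci: no functional form is
  dictated by the biology, and additivity keeps effects composable with
  an exact two-class recursion oracle
  `p' = p·σ(β0+s) / (p·σ(β0+s) + (1−p)·σ(β0))` for testing.
* **Pilot effects `s = 2`, `g = −0.3`, 8 regrowth rounds**: growth
  selection acts during the intercross too, so a strongly
  growth-deleterious allele is nearly lost before aging begins — the
  same reason the study design uses F6 pools rather than later
  generations. `g = −0.3` leaves the antagonistic allele segregating
  (AF ≈ 0.14 after six generations) while still moving AF far past the
  0.15 cutoff during regrowth.
* **Re-seeding experiment**: 40 loci with `s = 0.4` and the baseline
  centered to `β0 = 1 − n·s/2`, so the pool-mean daily survival stays
  ~0.73 while genotypes vary heritably around it; without centering the
  pool either never dies or dies uniformly and the trend is
  uninformative by construction.

What the simulator does **not** emulate: sequence-level reads (no FASTQ,
mapping error, or reference bias), mutation during intercrossing,
crossover interference, mating-type constraints, non-binomial
overdispersion of Pool-seq counts, and environmental batch effects
between replicates. Passing tests therefore demonstrate the method's
behavior under its own model assumptions at desk scale, not performance
on real sequencing data.

## Validation at desk scale

The acceptance checks (also re-run by `scripts/acceptance.py`) use: 1000
random 6-point trajectories with depths 0–200 against an independent
brute-force oracle (grid-search MLE at step 1e-4 with two local
refinements, plus direct lgamma-based pmf summation); 50 seeds per
simulation experiment at 2000 markers, 8 replicates, 6 time points,
depth 100, pools of 1000. These problem sizes are the package's chosen
desk-scale conditions; power is monotone in effect size over
{0.5, 1, 2} and depth over {20, 100}.

## Known limitations

* The score's null distribution is empirical; the χ² reference holds
  only at high depth without drift, so thresholds do not transfer
  across designs with very different depths or pool sizes.
* The neighbor filter assumes marker spacing comparable to linkage-block
  width; on sparse maps it can remove true signals, on very dense maps
  it loses power against spikes.
* The pleiotropy screen's antagonistic call is sign-based on point
  estimates of ΔAF; at shallow (~10×) pilot-like depth most loci are
  simply non-informative at the default depth rule.
* `read_counts_vcf` takes the first ALT allele only; multi-allelic sites
  should be split upstream.
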
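# Methods

## The problem

In a recently admixed population (for example African Americans, founded by
African/European admixture roughly 8 generations ago), chromosomal segments
descend from one of the two source populations.  Mixing creates *admixture
linkage disequilibrium*: local-ancestry states at two linked loci are
positively correlated, and the correlation decays with genetic distance *d*
and time since admixture *t*.  Loci under *fitness epistasis* — whose joint
ancestry configuration affects survival or reproduction — retain ancestry
correlation in excess of this decay.  `admixscan` detects that excess for
locus pairs on the same chromosome, where admixture LD would otherwise
swamp the signal.

## The statistical model

Let X_i be the diploid African-ancestry dosage (0, 1, 2) of a genomic bin
*i* and β_ij = corr(X_i, X_j) the Pearson correlation across individuals.
Under the hybrid-isolation model (a single admixture pulse followed by
random mating), the expected correlation between loci at distance *d*
Morgans is (1 − d)^t ≈ e^(−t·d).  Per locus *i* the observed correlations
against all other loci on the chromosome are fit with

    f(d) = a0 + a1 · exp(−a2 · d),      d in cM,

by nonlinear least squares, argmin_a Σ_{j≠i} (β_ij − f(d_ij))².  a0 absorbs
the background correlation between effectively unlinked loci (genome-wide
structure and drift LD); a2 estimates t/100 per cM.  The residual
(β_res)_ij = β_ij − f_i(d_ij) is computed under each endpoint's own fit and
the two directions are averaged: β̂_res = ((β_res)_ij + (β_res)_ji)/2.

Under no epistasis β̂_res ~ N(0, σ²).  σ is estimated as the sample SD of
correlations between loci on *different* chromosomes, where distance is
effectively infinite and any correlation is sampling noise plus genome-wide
structure.  The test statistic is Z_ij = β̂_res / σ̂ with two-sided
P_ij = 2(1 − Φ(|Z_ij|)).

Multiple testing uses the Li–Ji effective number of tests: per chromosome,
k_i = ⌊Σ_ℓ I(λ_ℓ ≥ 1) + (λ_ℓ − ⌊λ_ℓ⌋)⌋ over eigenvalues λ_ℓ of the bin
correlation matrix, total tests Σ_i k_i(k_i − 1)/2, Bonferroni α = 0.05 /
total.  Pairs closer than 50 cM are flagged out of significance declaration
(residual admixture LD there cannot be cleanly separated), though they
still enter every curve fit.  Significant pairs are merged into region
pairs by connected components: two pairs connect when both endpoints are
within `gap_bins` bins (default 1).

Cohorts are combined by sample-size-weighted Z (METAL style),
z_meta = Σ_k √n_k z_k / √(Σ n_k).  Cochran's Q quantifies per-pair
heterogeneity on the residual-correlation scale with per-cohort variance
σ̂_k² — Z-scores have unit variance by construction, which would hide
effect-size heterogeneity, so Q is computed on effects, not Z.  Diagnostics
are the genomic-control λ = median(Z²)/0.4549, per-cohort residual
skewness (adjusted Fisher–Pearson; positive skew is the qualitative
signature of epistasis on top of a symmetric null), and pairwise cohort Z
correlations (shared signal makes them positive).

## Crossover deficit (ANCAEC)

Epistatic selection preserves haplotypes spanning the two regions, so
historical ancestry crossovers between them are depleted.  ANCAEC is the
average number of African/European ancestry switches per cM in an interval:
per individual, events = Σ over adjacent bins of |dosage_{b+1} − dosage_b|
(a 0→2 step counts as two events — the minimal haplotype-switch count
consistent with unphased dosage), and the rate is the mean event count
divided by the interval's cM length.  The deficit test compares the
inter-region interval (right boundary of region 1 to left boundary of
region 2) against equal-cM windows tiled over the genome minus the excluded
regions: Z = (target − mean window rate)/SD of window rates, one-sided p
for a deficit.  The normal null needs a concrete reference windowing;
equal-cM tiling anchored at each chromosome's first bin midpoint is this
package's choice, with window bp bounds taken from the
same piecewise-linear bp↔cM map used for the target so numerators and
denominators are comparable.  At least 10 reference windows are required.

## Positional enrichment

For a target region and a list of trait-associated positions, the
chromosome outside the target is tiled into windows of the target's bp
length; Z = (observed − mean window count)/SD of window counts, one-sided.
The denominator is the SD of per-window counts, not the SE of the mean: the
question is where one region sits in the window distribution.  Position-only
mapping; gene-level mapping is out of scope.

## The simulator

`simulate_population` realizes the hybrid-isolation model forward in time:

* Founding: each haploid genome is African with probability *m* (one draw
  per haplotype, applied to all chromosomes — a founding gamete comes from
  one individual of one ancestry).
* Mating: every offspring draws two distinct parents uniformly; each
  transmitted chromosome is a recombinant with Poisson(length in Morgans)
  crossovers at uniform genetic positions (Haldane, no interference), which
  matches the exponential-decay approximation the scan fits.
* Selection (optional): offspring with equal diploid dosage at the two
  selected loci have fitness 1 + s versus 1, applied to viability by
  rejection sampling (accept with probability w/(1+s)).  No generative
  model of fitness epistasis is implied by the detection method itself;
  this dosage-matching viability scheme is the package's own and is one of
  several defensible choices (haplotype-level matching or multiplicative
  fitness would also do).  Its relevant property is that it sustains excess
  ancestry correlation at the selected pair against recombination.
* Output: diploid dosage at each 400-kb bin midpoint ("middle marker"
  convention), the bin manifest with a linear per-chromosome bp↔cM map, and
  the ground-truth tract set.  A single seeded generator drives all draws
  in a fixed order (per offspring: parents, per-chromosome gametes,
  acceptance), so identical config + seed is bit-identical.

Two closed forms anchor the simulator. The ancestry correlation at distance
d after t generations is (1 − r(d))^t with Haldane recombination fraction
r = (1 − e^(−2d))/2; the exponential form (1 − d)^t used by the scan is its
small-d approximation, and the two visibly diverge beyond ~10 cM — one
reason fitted a2 lands a few percent below t/100.  The ancestry-junction
density is 2m(1−m)·t per Morgan: crossovers accumulate at rate t per Morgan
along a lineage and become visible junctions only where the two homologous
ancestries differ, probability 2m(1−m).

What the generator does not emulate: local-ancestry inference error (real
dosages are posterior calls with telomere/centromere artefacts), a
non-uniform recombination map, continuous gene flow after founding, family
structure, and 22 chromosomes of realistic lengths.  Passing tests
demonstrate the statistical machinery is correct and calibrated under the
model's own assumptions, not that real cohorts satisfy those assumptions.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `bin_size_bp` | 400,000 | bin width; dosage taken at the middle marker |
| `exclusion_radius_bp` | 2,000,000 | drop bins within this distance of telomere/centromere annotations |
| `low/high ancestry` | 0.05 / 0.98 | remove samples with ≤5% or ≥98% African proportion (boundaries removed) |
| `min_distance_cM` | 50 | pairs closer than this are never declared significant |
| `alpha` | 0.05 | family-wise error level before Li–Ji correction |
| `max_null_pairs` | 2,000,000 | cap on cross-chromosome pairs for σ̂ (seeded subsample beyond it; the choice of cap does not bias σ̂, only its MC error) |
| `gap_bins` | 1 | adjacency radius when merging significant pairs into regions |
| `t, m, s` | 8, 0.8, 0 | simulator: generations since admixture, African fraction, selection strength |

## Numerical choices

* Decay fit: `scipy.optimize.least_squares` with analytic Jacobian,
  relative objective tolerance 1e-10, at most 500 evaluations.
  Initialization is deterministic: a0 ← 5th percentile of β, a1 ← max(β) −
  a0, a2 ← −slope of a log-linear regression of the positive excess on d.
  Bounds: a1 ∈ [0, 2], a2 ≥ 0, and a0 ∈ [−1, 1].  The bound on a0 (rather
  than leaving it free) is deliberate: f(d) is a correlation, so the
  background cannot leave [−1, 1], and the unconstrained problem has a
  degenerate near-linear valley (a0 → −∞, a1 → +∞, a2 → 0) that stalls the
  optimizer on loci whose correlation profile is locally non-monotone
  (e.g. near a selected locus).  Negative backgrounds remain admissible.
  Non-converged loci are flagged and their pairs masked, never silently
  dropped.
* Zero-variance bins are excluded from correlation matrices with a report;
  missing dosage fails fast on load.
* p-values are floored at 1e-300 to keep them in (0, 1] under extreme Z.
* Li–Ji eigenvalues are clipped at 0 (numerical negatives) and the final
  k_i floored; ties in nearest-marker binning break toward the smaller bp.
* TSV floats are written with `%.17g` so write→read round-trips are exact
  and reruns are byte-identical.

## Calibration behaviour

On null simulations the scan is slightly conservative: the per-locus curve
fit absorbs locus-level random effects (each locus's a0 soaks up its mean
long-range correlation), so within-chromosome residuals have smaller
variance than the cross-chromosome correlations that define σ̂.  Genomic
control λ comes out around 0.83–0.95 and the pooled uncorrected rejection
rate at 0.05 a little below nominal — the direction of miscalibration is
safe (no inflation), and the same conservatism is expected on real data for
the same reason.

## Problem sizes used by the test suite and acceptance script

Simulated cohorts use n = 2000 diploids, t = 8, m = 0.8, a scanned 2-Morgan
/ 80-Mb chromosome (2.5 cM/Mb, typical of smaller human autosomes; 200 bins
of 400 kb) plus an auxiliary 1-Morgan / 40-Mb chromosome whose only role is
to supply cross-chromosome pairs for σ̂ — the null scale is undefined on a
single chromosome.  The test suite runs 200 null replicates (calibration,
decay recovery, crossover consistency and deficit uniformity), a 4 × 50
power grid over s ∈ {0, 0.05, 0.1, 0.2} with the selected pair at 70 and
130 cM (d = 60 cM, past the distance filter), and 20 end-to-end scans at
s = 2 for region recovery.  The acceptance script reruns the same
computations at 60/25/10 replicates.  Selection s = 2 (relative fitness 3:2
for dosage-matched offspring) is the "strong selection" setting; by s = 0.2
the induced correlation at d = 60 cM is already ≈ 0.14, far above the
null scale σ̂ ≈ 0.027 at n = 2000.

## Known limitations

* The generative selection model is the package's own; detection power for
  other epistasis architectures (haplotype-phase-dependent, dominance)
  will differ.
* σ̂ pools genome-wide structure into the null scale; strong cryptic
  relatedness or platform batch effects in real data would inflate it and
  cost power rather than false positives.
* The region-pair merger is a reconstruction — the field reports merged
  regions without a standard algorithm; component bounding boxes can
  overstate region extent when signals are sparse.
* Population size equals sample size in the simulator, so drift LD at
  n = 2000 is stronger than in a large real population sampled at 2000;
  this is conservative for calibration claims.
* ANCAEC counting on unphased dosage undercounts switch events when the
  two haplotypes switch in opposite directions between adjacent bins.
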
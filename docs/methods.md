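# Methods

## The gametic-selection model

Two linked loci A and B (recombination fraction `r`) act as
segregation-distortion loci in an F2 cross.  The F1 produces gametes
`AB, Ab, aB, ab` with Mendelian frequencies `(1-r)/2, r/2, r/2,
(1-r)/2`.  Female gametes are transmitted unchanged; male gametes
survive with relative viabilities `1, v, u, x` and the surviving pool is
renormalized by `λ = (1-r)(1+x)/2 + r(u+v)/2`.  F2 genotype frequencies
are the outer product of the female (Mendelian) and male
(post-selection) gamete distributions; the 16 ordered states collapse to
9 observable classes.  "Epistasis" means `x ≠ u·v`: the
double-recombinant gamete's viability deviates from the product of the
single-locus effects.

Because the reference gamete AB carries viability 1, the normalizer is
bounded below by `(1-r)/2`, the model never degenerates, and the
post-selection frequency of the reference allele is always positive —
the induced single-locus fitnesses `(1, f2, f3, f4)` (ordered genotypes
`AA, Aa, aA, aa` relative to `AA`) are always finite, with `f3 = 1` and
`f2 = f4 = q_a/q_A` (post-selection male allele frequencies) under
male-only selection.  The ordered-heterozygote convention is female
allele first; the downstream correction uses only `(f2+f3)/2` and `f4`
and is invariant to that convention.

## Estimation

**EM over ordered states.**  With observed 9-class counts (or, off
markers, per-individual multipoint probabilities of the 16 ordered
states) the E-step distributes each class across its compatible ordered
states in proportion to current model frequencies; the double
heterozygote splits four ways, single-heterozygote classes two ways.
The M-step is closed form because each ordered state fixes its male
gamete: `v = (c_Ab/c_AB)·(1-r)/r`, `u = (c_aB/c_AB)·(1-r)/r`,
`x = c_ab/c_AB` from expected male gamete counts `c`.  At `r = 0` the
single-recombinant classes have zero probability and `u, v` are not
identifiable (left at 1 with a warning); expected counts of zero in the
reference gamete produce boundary estimates capped at 1e4.  Convergence:
max parameter change < 1e-8, at most 2000 iterations, Mendelian start.

**Joint (r, u, v, x) EM for map correction.**  With free viabilities the
male part of the complete-data likelihood is saturated, so `r` is
updated from expected female-strand recombinants; with viabilities
pinned at 1 both strands pool and the update is the textbook two-point
F2 EM.  On finite samples the joint likelihood has a ridge when
double-recombinant classes are empty (`r → 0` with `u, v → ∞` mimics
recombination through selection); a 0.5 pseudo-count added to empty
classes (Haldane–Anscombe style) keeps the estimate off the ridge and
leaves expected-count input (all classes occupied) untouched.  Corrected
cM distances come from the inverse Kosambi function, accumulated from
the first marker.

**Tests.**  Distortion: likelihood ratio of the full model against
`u = v = x = 1`, 3 df.  Epistasis: full model against `x = u·v`, 1 df —
the multiplicative null is the standard independence hypothesis on the
viability scale and reduces correctly when either locus is neutral.  In
the 2-D scan both tests profile `r` out of every hypothesis: fixing `r`
at a map estimate makes them sensitive to map noise (the `x = u·v`
constraint pins the male-gamete odds ratio to `((1-r)/r)²`, and map
errors accumulate over distant pairs), which inflated the Mendelian-null
rejection rate badly in calibration runs.  Profiling restores the
nominal level at some cost in power.  Scan-wide significance uses
Bonferroni (configurable) on the distortion test by default — any
selection at a pair calls for probability correction downstream, whether
or not it is epistatic.

A caveat established during development: selection at one true SDL pair
induces associations in the surviving male gamete pool across the whole
linked region, and the pairwise likelihood at two non-SDL positions can
represent the induced table essentially exactly.  No pairwise statistic
therefore localizes the SDL pair sharply; significant pairs blanket the
linked region.  This is harmless for the pipeline because each scan
position takes its fitness correction from the *nearest* significant
pair, whose induced viabilities approximate the local selection well.

## Multipoint probabilities and correction

A hidden Markov chain over the four ordered one-locus states runs along
each chromosome: transitions are Kronecker squares of the two-state
recombination kernel (same `r` for both strands, from Kosambi distances
between adjacent loci; no interference beyond the map-function
conversion, so chained intervals compose by the Markov product rather
than by map-distance addition).  Codominant codes pin the unordered
genotype, dominant codes exclude one homozygote, missing excludes
nothing; virtual markers (fully missing pseudo-loci) densify the grid to
the configured step (default 1 cM).  Forward–backward gives posteriors
at every scan position and exact pairwise joints for the off-marker SDL
fit.

Fitness at an arbitrary scan position comes from a three-point
computation: male gametes over (SDL1, SDL2, position) with viability
decided by the SDL haplotype; the triple reduces exactly to the marginal
single-locus fitness when the position coincides with an SDL and tends
to neutrality with distance.  The correction reweights
`(p(QQ), p(Qq), p(qq))` by `(1, (f2+f3)/2, f4)` and renormalizes per
individual; a neutral triple short-circuits to a bit-exact no-op.  The
correction can only change non-degenerate rows, so it acts at scan
positions with incomplete marker information — on a fully typed marker
grid the old and new methods coincide by construction, which is why the
replicated studies scan at 1 cM.

## QTL models

**Single-interval mixture.**  Three-component normal mixture with means
`μ+a, μ+d, μ−a`, common `σ²`, and per-individual (corrected) genotype
probabilities as mixing proportions; EM with weighted least-squares
M-steps; `σ²` floored at `1e-8·var(y)`; LOD against the mean-only model.

**Empirical-Bayes multi-QTL.**  `y = μ + Σ_l (z_l a_l + w_l d_l) + e`
on expected dummies `E[z] = p(QQ) − p(qq)`, `E[w] = p(Qq)` over the scan
grid.  Each effect has prior `N(0, σ²_k)` and each `σ²_k` a scaled
inverse-χ² prior `(τ, ω)`; the E-step is the joint posterior mean and
variance of the effects under the current variance components (the
marginal BLUP form `γ̂_k = σ²_k X_kᵀ V⁻¹ (y − 1μ)` with `V = σ²I +
Σ σ²_k X_k X_kᵀ` and `μ` by GLS), the M-step sets `σ²_k = (γ̂_k² + V_k +
ω)/(τ + 3)` and updates `σ²` from the corrected residual sum of squares.
The default `(τ, ω) = (−2, 0)` makes the variance update the posterior
second moment.  The implementation runs on sufficient statistics
(`XᵀX, Xᵀy`) with a Woodbury identity over the active effect set, so an
iteration costs `O(k³ + kK)` for `k` active of `K` total effects.
Variances below `1e-8·var(y)` lock an effect at zero.

This EB variant is deliberately *not* sparse: under pure noise it
retains small nonzero effects (up to ~0.3 sd with LOD < 3), and on a
dense 1-cM grid its conditional-LOD profile is not calibrated as a test
— adjacent columns correlate at ~0.98 and can carry large canceling
effects that inflate the drop-one LOD.  Calling is therefore two-stage:
the EB profile only screens candidate peaks (threshold 1.0, peaks merged
within 10 cM), and candidates are re-tested by a joint unpenalized
least-squares refit with backward elimination at the reporting threshold
(LOD 3.0, `(n/2)·log10(RSS_reduced/RSS_full)` per dropped locus).
Reported effects and LODs come from the final refit.  Null calibration
(heritability 0): no detection in 20/20 replicates at LOD 3.

**Old vs new.**  Both methods share the corrected map, the SDL scan, the
grid and the EB machinery; "new" additionally corrects the genotype
probabilities at every scan position of chromosomes carrying a
significant SDL pair.  With nothing significant the two pipelines are
bit-identical.

## Simulator

Meiosis is simulated locus-by-locus along the sorted union of marker,
QTL and SDL positions with per-interval Kosambi recombination fractions
(Markov, no interference); male gametes are accepted with probability
proportional to their SDL-haplotype viability, and generation repeats
until the requested number of survivors (default n = 300) is reached —
so the gametic selection is implemented exactly as the probability model
states, rather than through a liability threshold.  Phenotypes are
`y = μ + z·a + w·d + e`, `e ~ N(0, σ²)`, with `σ² = 1` by default: the
effect triples `(0.2649, 0.3849, 0.4851)` for heritabilities
`(0.05, 0.10, 0.15)` pin both the unit residual variance and the dummy
coding, via `h² = (a²/2 + d²/4)/(a²/2 + d²/4 + σ²)` with `a = d`.
Viability presets for SDL "heritabilities" 5/10/15% are the fixed
triples `u = v = x = 0.5141 / 0.3615 / 0.1617`.

The default design: one chromosome, 21 codominant markers at 5 cM
spacing, QTL at 25 cM (h² = 0.10), SDL at 20 and 30 cM (h² = 0.10
preset), n = 300.  What the simulator does *not* emulate: genotyping
error, crossover interference, segregation distortion of female origin,
non-normal residuals, and selective genotyping — passing tests say
nothing about robustness to those.

One numerical consequence of the per-interval simulation: when a locus
lies between the two SDL, the composite recombination fraction
`r₁(1−r₂) + r₂(1−r₁)` differs slightly from the one-step Kosambi value
for the summed distance (map-function non-additivity).  Cross-validation
of the simulator against the analytic table therefore uses designs
without intervening loci; a dedicated test pins the composite behaviour.

**Power harness.**  Each replicate simulates one dataset and analyses it
with both methods on identical inputs (shared corrected map and SDL
scan).  Detection means a call at LOD ≥ 3 within ±10 cM of the true QTL;
power is the detection fraction.  Effect estimates are aggregated over
*all* replicates, each contributing the single-locus refit at the
best-LOD scan position inside the evaluation window: conditioning the
means on the LOD-3 event would add winner's-curse selection bias
(comparable to the Monte Carlo SE at moderate power) on top of the
estimator's own bias, entangling two different properties.  The
remaining upward bias from choosing the peak position is small but not
zero, and is larger for the dominance effect (its regressor has half the
variance of the additive one).  Paired t-tests compare methods on the
per-replicate estimates.  Replicated studies use 50 replicates.

At the reference design the markers are dense and fully codominant, so
the genotype probabilities at scan positions are nearly deterministic
and the probability correction moves the paired LOD by only a few
hundredths; the new-vs-old power comparison then frequently ties.  The
correction matters most with sparse maps and dominant/missing markers,
where the probability rows are genuinely uncertain.

## Known limitations

- SDL localization by pairwise scanning is inherently diffuse (see
  above); only the induced local fitness is identifiable in practice.
- The off-marker SDL fit follows the posterior-reweighting scheme (the
  multipoint probabilities are computed without selection and reweighted
  at the two target positions); it is not the full selection-aware
  chromosome likelihood.
- Cross-chromosome SDL pairs are not fitted (the scan is
  within-chromosome).
- The epistasis test with profiled `r` is conservative; with a trusted
  map the fixed-`r` variant is more powerful.
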
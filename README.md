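# epiqtl

Multi-QTL mapping for F2 populations that *uses* distorted markers
instead of discarding them.

Marker segregation distortion — genotype ratios deviating from the
Mendelian 1:2:1 — is ubiquitous in real mapping populations and is often
driven by **epistatic segregation-distortion loci (SDL)**: pairs of
linked loci whose joint genotype decides the viability of male gametes.
Ignoring the distortion biases both the genetic map and the QTL effect
estimates.  `epiqtl` implements a three-stage pipeline for quantitative
trait mapping in F2 crosses:

1. **Detect epistatic SDL and correct the map.**  For a linked locus
   pair, male gametes `AB, Ab, aB, ab` survive with relative viabilities
   `1, v, u, x`; female gametes are untouched.  The post-selection F2
   genotype frequencies follow from renormalizing the Mendelian gamete
   pool by `λ = (1-r)(1+x)/2 + r(u+v)/2`.  The viabilities are estimated
   by an EM algorithm over the 16 ordered (female gamete × male gamete)
   states; a joint EM over `(r, u, v, x)` re-estimates map distances
   from distorted data, and likelihood-ratio tests flag distortion
   (H0: `u = v = x = 1`, 3 df) and epistasis (H0: `x = u·v`, 1 df) for
   every position pair of a 2-D scan.

2. **Correct the QTL genotype probabilities.**  Multipoint conditional
   probabilities `p_j(QQ), p_j(Qq), p_j(qq)` are computed by a hidden
   Markov model over the four ordered one-locus states (Kosambi map
   function; codominant, dominant and missing marker codes supported;
   virtual markers densify the scan grid).  A fitted SDL pair implies
   relative fitnesses `(1, f2, f3, f4)` of the ordered genotypes at any
   scan position; the probabilities are reweighted as
   `p*(QQ) : p*(Qq) : p*(qq) = p(QQ) : p(Qq)·(f2+f3)/2 : p(qq)·f4`.

3. **Map QTL.**  The multi-QTL model
   `y_j = μ + Σ_l (z_jl a_l + w_jl d_l) + e_j` (dummy coding
   `z ∈ {1, 0, −1}`, `w ∈ {0, 1, 0}`) is fitted by an empirical-Bayes EM
   with a normal prior on each effect and a scaled inverse-χ² prior on
   each effect variance; candidate peaks from the LOD profile are
   re-tested by a joint least-squares refit at LOD ≥ 3.0.  Running the
   pipeline with ("new") and without ("old") the probability correction
   quantifies what the distortion model buys.

A seeded simulator generates F2 data under exactly this gametic-selection
model (QTL effects from target heritabilities, selection applied to male
gametes) and a replicated power/bias harness compares the two methods on
identical data.

## Worked example

```
$ epiqtl simulate --seed 1 --out demo        # default reference design
$ epiqtl qtl-scan --geno demo.geno.tsv --map demo.map.tsv \
      --pheno demo.pheno.tsv --method new --out demo_new
1 QTL called -> demo_new.qtl.tsv
$ cat demo_new.qtl.tsv
chrom   pos_cM  a       d       lod     method
1       25.172350       0.324190        0.315463        4.438757        new
```

The default design places one QTL at 25 cM (heritability 0.10, so
`a = d = 0.3849` at unit residual variance) and two SDL at 20 and 30 cM
with viabilities `u = v = x = 0.3615` on a 21-marker, 5-cM-spaced
chromosome with n = 300.  The single call recovers the simulated QTL:
position 25.2 cM (truth 25.0), additive effect 0.32 and dominance 0.32
(truth 0.3849 each, so both within one standard error at this sample
size), LOD 4.4 against the 3.0 threshold.  `demo_new.summary.json`
records the configuration, the significant SDL pairs used for
correction, and the EM likelihood trace.

The library mirrors the CLI one-to-one, e.g.:

```python
from epiqtl import SimDesign, simulate_f2, run_method
genotypes, y, lmap, truth = simulate_f2(SimDesign(sdl_h2=0.15), seed=1)
result = run_method(y, genotypes, lmap, method="new")
```

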
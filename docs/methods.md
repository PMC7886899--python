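# Methods

## The model

A quantitative trait is decomposed as y = a + i + c + e: an additive
genetic value a = Σ β_k z_k over centred, standardised causal dosages, an
additive-by-additive epistatic value i = Σ γ_p z_k z_l over designated
disjoint causal pairs, a shared-environment value c constant within family,
and an independent residual e. Scales are anchored in the founder
(generation-0) population: var(a) = h²_RM, var(i) = V_AA, var(c) = c²,
total variance 1. Under positive phenotypic assortment the additive
variance inflates across generations through gametic phase disequilibrium
until it plateaus; the equilibrium heritability h²_EQ is the realised
ratio var(a)/var(y) in the final generation, and all equilibrium-scale
quantities divide by the final phenotypic variance.

The expected covariance of relatives separated by an effective meiosis
count d under equilibrium assortment with spousal correlation r is
0.5^d·h²_EQ·(1 + r·h²_EQ)^d. For the collateral chains the simulator
produces (sibs d=1, avuncular d=2, first cousins d=3) this expression is
exact given only that mate choice is a function of phenotype alone (the
derivation needs second moments, not normality of the matching copula).
Parent–offspring pairs follow a different expectation under assortment and
are excluded from all covariance regressions.

## Simulator design

**Transmission.** Variants are grouped into units: each causal variant and
its tagging marker are fused (co-transmitted), distinct units recombine
freely. This preserves the target causal–tag r² across generations exactly
and deliberately omits marker-panel LD beyond the designated pairs,
recombination distance structure, and the X chromosome. Realised IBD among
sibs is the fraction of units with identical parental transmission,
averaged over the two parents; with L units its SD is 1/√(8L), so ~100
causal units reproduce a genome-like spread (~0.035) without a genetic
map. Where a realistic map matters — the segregation-variance question
itself — a separate Poisson (Haldane, no interference) crossover model on
a packaged 22-autosome map (3,545.5 cM) simulates sharing as the occupation
time of a telegraph process flipping at the union of the two meioses'
crossover points. That model gives genome-wide SD ≈ 0.038 at 20,000 pairs,
consistent with classical theory; crossover interference, which it omits,
would lower this slightly.

**Two-locus LD.** Founder haplotypes draw the tag allele conditionally on
the causal allele with haplotype frequency p_AB = p_c·p_m + D,
D = √(r²·p_c q_c p_m q_m). The attainable bound
D ≤ min(p_c q_m, p_m q_c) is enforced with an error naming the bound —
rare causal alleles cannot be strongly tagged by common markers, which is
exactly the regime that separates h²_SNP from the close-relative
heritability. The closed-form haplotype table doubles as the exact oracle
in the tests.

**Mate matching.** Each generation splits into two halves; each half is
ranked on phenotype plus Gaussian noise and ranks are paired. The noise
scale is calibrated by bisection against one fixed noise draw, making the
realised spousal correlation monotone in the scale, accurate to ~0.001,
and deterministic given the seed. Negative targets pair ranks in opposite
order. All couples reproduce (no fertility selection), keeping the
population size constant until the final generation, which carries the
requested sibship size and MZ/DZ twin fractions.

**Stratification.** Contemporary-group (378 levels by default), batch
(106) and ancestry-gradient effects are injected with stated shares of the
final phenotypic variance; the gradient also shifts allele frequencies at
a marker subset. Injected shares are recorded so recovery tests can
compare the partial R² of a factor against truth plus the chance
absorption of its level count (levels/n).

## Analysis choices

* **Bins.** Half-open [lower, upper), ties upward; a packaged default of
  54 edges spans the spectrum and is user-overridable (the default is a
  reconstruction — narrow quantile-style bins through the unrelated range,
  fixed edges around the relative peaks). Empty bins are kept and flagged.
* **HE regressions.** All cross-product regressions include an intercept;
  the weighted-bin fit uses N_k weights and reduces exactly to the
  individual-level fit when every pair is its own bin. The two-component
  close-relative variant regresses cross-products on
  (π·1[π ≥ 0.05], 1[π ≥ 0.05]), mirroring a two-matrix mixed model.
* **Jackknife.** 100 near-equal blocks by random permutation of
  individuals; a pair is deleted when either member is deleted;
  se = √(((B−1)/B)·Σ(θ_b − θ̄)²). Bin assignments stay fixed across
  deletions; bin means, weights and the fit are recomputed. Calibration:
  across 30 replicated cohorts of 1,500 individuals the mean jackknife SE
  of the HE slope is within a factor 1.5 of the empirical SD; at a few
  hundred individuals the jackknife over-covers somewhat, so SEs should be
  read as conservative at small n.
* **AM fit.** Bins with π̄ > 0.05 and positive scaled covariance enter the
  log-linear fit, weighted by N_k (weights are switchable; the choice is
  not consequential for the simulated designs). In simulation studies the
  bins are pedigree relative classes with π̄ fixed at the expectation
  2^(1−…) rather than re-binned from a marker GRM: at the marker counts
  simulated here GRM noise would blur class boundaries without adding
  information, and the equilibrium theory is stated in terms of the
  relationship itself. The GRM → pairs → bins path is implemented and
  tested independently and is what external data would use.
* **Equilibrium inversion.** h²_EQ solves r·x² − x + h²_design = 0; the
  smaller root (rationalised as 2h/(1+√(1−4rh)), continuous through
  r → 0) is returned. The inversion is a two-sided identity with the
  design expectation only on the branch r·h²_EQ ≤ ½; beyond it both roots
  can be admissible and the map is not invertible from the design estimate
  alone. SEs propagate by the delta method with the implicit derivatives
  dx/dh = 1/s, dx/dr = x²/s.
* **REML.** The sib variance-component model is fitted by direct
  Nelder–Mead search on the residual likelihood over (σ²_a, σ²_c, σ²_e)
  with components bounded at zero; two-member families use a closed-form
  vectorised block likelihood, larger families a generic small-block path
  (limit 50). SEs come from the finite-difference observed information,
  mapped to (h², c²) ratios by the delta method. Singleton-only inputs are
  degenerate (a and c unseparable) and return σ²_e with a warning.
* **Outlier filter.** One pass at 5 sample SDs, applied to residuals of a
  first covariate fit, then refit (configurable to filter raw values
  first). Sample (n−1) variance throughout. Within-sex standardisation
  makes prep idempotent only up to the sampling difference of the per-sex
  residual SDs (O(10⁻³) at n ≈ 3,000); iterating contracts to the fixed
  point.
* **Meta-analysis.** Fixed-effect IVW only; heterogeneity Q is reported,
  not tested. Table values round half away from zero at 2 dp.

## Study sizes

The simulation studies are sized so each signal is resolved with
comfortable margin on one CPU: the AM equilibrium study runs 10
generations at n = 20,000 with 100 causal loci and three final-generation
sibs per family (~30,000 sib pairs); the incomplete-LD study uses ~5,600
family members in four-branch, three-generation pedigrees plus 400
unrelated singletons, 3,000 rare causal variants (MAF ≈ 0.05) tagged at
r² = 0.25 by a 40,000-marker panel (GRM noise SD ≈ 0.005, so the
0.02–0.05 window is resolvable and unrelated-pair leakage past 0.02 is
negligible); the epistasis study uses 2,500 three-branch families
(~52,000 focal individuals, five relationship classes); equivalence and
calibration studies use 30 replicates of 20,000 sib pairs and 1,500
individuals respectively.

## What the simulations do and do not show

The generator reproduces the statistical structure the estimators assume —
phenotypic assortment at equilibrium, incomplete tagging of rare causal
variants, within-family segregation variance, ACE-style twin structure —
so passing tests demonstrate that the estimators recover known truth under
their own assumptions, including the non-obvious design expectations under
assortment. They do not probe: linkage and LD beyond designated pairs,
allele-frequency spectra coupled to effect sizes, genotyping error or
imputation noise, indirect/associative genetic effects (genetic nurture,
sibling effects), social homogamy or convergence in spousal resemblance,
or population stratification beyond the injected label/gradient effects.
Estimates from real data inherit all of those caveats.
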
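# Methods

This note documents the models, the choices made where the design was
genuinely open, the synthetic-data generators and what passing tests do and
do not demonstrate, and the numerical details a maintainer would need.

## Allele-frequency model

Each site is modelled hierarchically: p ~ Beta(a, b) (default a = b = 1),
genotypes g_ij | p ~ Binomial(2, p) (Hardy–Weinberg), and reads enter
through per-individual genotype likelihoods. The Gibbs sampler alternates a
categorical genotype draw (likelihood × prior mass) with the conjugate Beta
draw for p; all sites update in parallel. Defaults are a 1,000-iteration
burn-in, 10,000 sampling iterations and thinning of 5, one chain. The Beta
and Hardy–Weinberg priors are this package's choices — the model family is
standard for genotype-likelihood-based frequency estimation but no single
canonical prior exists; both are configurable. PHRED PLs are converted as
10^(−PL/10) and renormalized per individual, which preserves ties; an
all-missing site keeps its prior and is flagged rather than erroring.
Likelihood triples are rescaled to a maximum of 1 per individual before
sampling to avoid underflow at high depth.

## Standardized change and the HMM scan

Δp = (p¹ − p⁰) / (2 p⁰ (1 − p⁰)). The denominator is the ancestral expected
heterozygosity, without a square root; a sqrt variant is available behind
`sqrt_denominator=True` for sensitivity analysis since either scaling
appears in the literature. Absolute values are the default because the
emission means (median and an upper quantile) only define a magnitude
scale; `mode="signed"` is retained.

The two-state Gaussian HMM fixes the emission means at the median (average
state) and the 99.5th percentile (exceptional state) of Δp and the shared
emission s.d. at the empirical s.d.; only the transition matrix is
re-estimated, by Baum–Welch (≤500 iterations, tolerance 1e−4), with the
initial distribution fixed at (0.995, 0.005) to match the quantile. The
fitting and decoding run through hmmlearn with parameter re-estimation
restricted to the transition matrix; brute-force path enumeration in the
test suite is the independent check of both the forward likelihood and the
Viterbi path. Chains restart at scaffold boundaries by default
(`per_scaffold=True`) because linkage does not cross scaffolds; a
concatenated single-chain mode exists. If the median and the upper
quantile coincide (degenerate Δp distribution) the scan returns an
all-average decoding with a warning instead of fitting. There is no random
initialization anywhere, so refitting is bitwise reproducible.

Regions are maximal runs of consecutive exceptional SNPs within a
scaffold. The X-excess statistic is the count of exceptional SNPs labelled
X; its null comes from circular shifts of the decoded state vector, and
both the excess and deficit tails are reported with the excess tail as the
headline.

## Sparse linear mixed model

Model: z = 1μ + X(β∘γ) + u + ε with u ~ N(0, σ²_u K) and
K = G_c G_cᵀ / m (column-centered cross-product). The kinship effect is
diagonalized through K = U D Uᵀ once per fit, so each Gibbs sweep is
O(nm): spike-and-slab updates per SNP (slab β_j ~ N(0, σ²_β σ²_e)),
independent normal updates for the rotated polygenic coordinates, conjugate
inverse-gamma updates for σ²_e (IG(2, 1)), σ²_u (IG(1, 0.01)) and σ²_β
(IG(0.5, 0.5)), and a grid Gibbs step for the inclusion probability π
under a uniform-on-log(π) prior on [1/m, 1] (200-point log-spaced grid).
The σ²_u prior is deliberately weak and concentrated near zero: the
kinship term must not absorb residual noise when the trait has no
polygenic background, and with n in the hundreds the likelihood dominates
whenever a real polygenic signal exists. Conjugate variance priors were
chosen over the PVE/PGE-uniform reparameterization used by some BSLMM
implementations; they keep every Gibbs step closed-form and fast at desk
scale, at the cost of priors stated on variances rather than on variance
ratios.

Per kept draw: PVE = var(g)/(var(g) + σ²_e) with g = X(β∘γ) + u (sample
variance over individuals), PGE = V(Xβ∘γ)/(V(Xβ∘γ) + V(u)), and
n-γ = Σγ. These ratio forms guarantee PVE, PGE ∈ [0, 1] draw by draw,
which a fixed-denominator var(z) version would not. GEBVs are posterior
means of g. Defaults are 4 chains × 20,000 kept sweeps after 10,000
burn-in, thinned by 10 — desk-scale settings chosen so a fit of n ≈ 300,
m ≈ 800 completes in seconds with the numba-compiled sweep; heavier
settings are plain arguments. Chains run from distinct sub-seeds
(derived below 2³¹) and are pooled; a between/within dispersion check on
PVE warns when chains disagree.

The backcross genotype model replaces a full admixture MCMC with a
fixed-ancestry approximation: a backcross to parent B has ancestry weight
q = 3/4 by construction, so the per-site prior allele frequency is
p* = q p_B + (1 − q) p_A with genotype prior Binomial(2, p*), and the
posterior-mean genotype is ĝ = Σ_x x Pr(g = x | reads). This is adequate
for the BC design, where q is known rather than estimated; it does not
model individual ancestry variation.

The among-family variance test fits a one-way random-intercept model by
REML, profiling the variance ratio γ = σ²_f/σ²_e on a fixed grid (0 plus
400 log-spaced points in [1e−4, 1e3]); σ²_e is then closed-form. The grid
fit was validated against statsmodels MixedLM (tests assert agreement to
5%). The restricted LRT against σ²_f = 0 sits on a boundary, so its null
is calibrated by simulation: iid standard-normal responses on the observed
design (the statistic is location/scale free), refit with the same grid
procedure, p = (1 + #{null ≥ obs})/(1 + n_sim), default n_sim = 10,000.

GEBV correlations use Pearson r with a Fisher-z 95% interval,
tanh(atanh r ± 1.96/√(n−3)); coverage is verified by simulation in the
test suite. Per-scaffold QTL counts are Σ PIP over a scaffold's SNPs,
regressed by OLS on SNP number.

## Expression

CPM filtering keeps genes with CPM > 0.5 in ≥ 2 samples (both
configurable). The DE contrast is a per-gene Welch t-test on
log2(CPM + 0.5) with Benjamini–Hochberg step-up control at FDR 0.05 — a
deliberately simple, transparent contrast; externally produced DE tables
in the same column format can be supplied to every downstream consumer, so
a moderated-variance pipeline can be substituted without touching this
package. Genes with zero variance in both groups get p = 1.

Class enrichment: with n DE genes, class fraction p_c and k observed class
members, the reported tail is Pr(X ≥ k) under Binomial(n, p_c) when
k ≥ λ = n p_c, else Pr(X ≤ k). The direction-switching convention was
chosen because it is the only single convention consistent with worked
(k, λ, P) triples in the literature this package mirrors: zero-observation
rows reproduce e^{−λ} (a lower tail) while over-represented rows reproduce
upper tails. `class_enrichment_from_expected` is the Poisson(λ)
large-universe limit for when only (k, λ) are known; the two agree within
0.01 for n ≥ 100 and p_c ≤ 0.05 (asserted in tests). A positive k with
λ = 0 is rejected as inconsistent input.

## Overlap randomization

The randomization primitive is a single uniform circular shift of the
whole genome-ordered vector (states or PIPs) with wrap-around. This
preserves the value multiset and, on the circularized sequence, the
run-length multiset — so clustering in either layer cannot by itself
create signal. A global shift is the default; per-scaffold independent
offsets are available by flag for genomes where scaffolds are long enough
that cross-scaffold wrap-around matters. p-values are one-tailed in the
direction of enrichment with add-one correction, minimum 1/(n_rand + 1),
with the opposite tail reported alongside (the choice of headline tail is
a reporting convention, not a computation difference). SNP-in-gene
membership uses 1-based inclusive intervals (GFF3 convention); BED input
is converted from 0-based half-open on read.

## Synthetic data

The generators emulate the study design the analysis assumes:

- **E&R lines**: Wright–Fisher binomial sampling of 2Ne gametes per
  generation with the deterministic genic-selection update
  p′ = p(1+s)/(1+sp) at selected loci, and a single founder generation of
  2·bottleneck_n gametes modelling the severe (1–2% survival) host-shift
  bottleneck. No linkage or recombination within scaffolds is simulated —
  loci drift independently — so the autocorrelation of real Δp along
  scaffolds is under-represented; the HMM's transition-matrix estimates on
  simulated data are correspondingly closer to independence than on real
  data.
- **Reads**: Poisson depth (default mean 2, matching shallow GBS) and
  binomial allele sampling with error ε; likelihoods are exactly the
  binomial read-count probabilities the downstream model assumes, so read
  simulation and estimation are consistent by construction — tests of
  popfreq on these data check the sampler, not robustness to model
  misspecification.
- **Backcross**: genotypes {het, parental homozygote} with probability 1/2
  at fixed-difference loci; trait = additive value + normal family effect
  + normal noise, with noise scaled so the realized additive fraction
  matches `target_pve` and `family_icc` setting the among-family share of
  non-genetic variance. Real BC data additionally have linkage blocks,
  segregation distortion and dominance, none of which are simulated.
- **Expression**: log-normal baseline expression, negative-binomial counts
  (var = μ + φμ², Poisson at φ = 0), per-group renormalization so expected
  library size is constant, and planted log2 fold changes at labelled
  genes.

Every generator returns its truth object and is bit-reproducible given a
seed. Passing recovery tests on these data shows the estimators are
correct under their assumed models at the simulated sizes; it does not
show robustness to alignment artefacts, paralogy, linkage or expression
batch effects.

## Problem sizes and test calibration

The test suite runs the sparse LMM at n = 300 individuals and m = 800
SNPs with 2 chains of 6,000 kept sweeps after 2,000 burn-in — sizes at
which interval coverage is measurable over 20 replicates in minutes while
the posterior is already well mixed (longer runs change summaries by less
than Monte-Carlo error). Randomization-test calibration uses 200 null
replicates of 500 SNPs with 199 shifts each; drift-variance and
Fisher-z checks use 2,000 loci and 500 replicates respectively.

## Known limitations

- The Δp HMM treats allele-frequency point estimates as exact; posterior
  uncertainty from the frequency model is not propagated into the scan.
- The sparse LMM assumes additive effects; dominance and epistasis are out
  of scope, as are X-dosage models (analyses intended for a single sex
  should be filtered upstream).
- The DE contrast has no precision weighting or empirical-Bayes
  moderation; at very small sample sizes it is conservative relative to
  moderated tests.
- The Poisson enrichment limit diverges from the exact binomial tail when
  the DE set is small or the class fraction large; use
  `class_enrichment` with full membership whenever it is available.
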
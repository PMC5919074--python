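# Methods

`ecoimmune` re-implements, as a tested library, a complete analysis of immune
state in wild house mouse (*Mus musculus domesticus*) populations: body
condition and age indices, a PCA-based immunological distance and its
structure across sampling sites, SNP-based population genetics,
distance-matrix comparison, and latent-variable structural equation models
(SEM) of what drives immune state. The per-mouse raw data of the original
field study are not publicly deposited, so the package ships a
synthetic-cohort generator whose defaults emulate the study conditions and
whose ground truth makes every stage testable.

## Condition and age indices

Body condition is the scaled mass index (SMI). The standardized major axis
(SMA) slope of ln(mass) on ln(length), `sign(r) * sd(y)/sd(x)`, estimates the
allometric exponent `b`; each mouse's mass is standardized to the population
mean length `L0`:

    SMI_i = M_i * (L0 / L_i)^b     [grams]

The same machinery scales splenic immune-cell counts (mass replaced by the
count, `b` refitted per cell type), giving counts comparable across body
sizes. Grouping for `b` and `L0` defaults to per-sex across the analysed
cohort (configurable per site): allometry is known to differ by sex, and
per-site groups would often fall below a stable fitting size. Zero counts are
excluded from the log-log fit but still scaled with the fitted exponent (a
zero count scales to zero), so no mouse is silently dropped downstream. With
zero length variance the standardization factor is 1 for any exponent; `b` is
reported as 0 in that degenerate case.

BMI is mass (kg) / length (m)^2. Age in weeks comes from dried eye-lens mass
through a monotone log-linear calibration `lens_mg = alpha + beta *
ln(age_days)`, inverted. The default coefficients (alpha = -1, beta = 2) are
deliberately labelled provisional: they have the right shape and order of
magnitude for house mice but are not a published calibration; any real
analysis must substitute its own. Lens masses below the calibration support
are flagged as extrapolated rather than rejected.

`pow10_rescale` divides a variable by 10^k with k chosen so the median of the
nonzero values lies in [1, 10) — the scaling convention the SEMs assume. It
is idempotent, including at decade boundaries where floating-point `log10`
rounds ambiguously.

## Immunological distance

Ten immune measures (scaled counts of CD4+, CD8+, CD19+, NKp46+, Ly6G+,
CD11c+ and F4/80+ splenocytes; serum IgG and IgE; faecal IgA) enter a PCA on
the correlation matrix — the measures mix counts and concentrations on
incommensurate scales, so standardization is the only defensible metric. The
immunological distance between two mice is the Euclidean distance between
their scores on the first three components. Complete cases only; the count
of excluded mice is always reported (one site's faecal IgA was never assayed,
so this path is exercised routinely). Component signs follow a deterministic
convention (largest-magnitude loading positive).

Distances are decomposed into within-site and among-site pair sets; standard
errors are `sd / sqrt(n_pairs)`, deliberately ignoring the non-independence
of pairs sharing a mouse — this matches the field presentation of such
tables, and is documented as a caveat rather than corrected. A site
contributing a single pair reports its SE as missing. Site-level matrices are
mean cross-site mouse-pair distances; classical (Torgerson) multidimensional
scaling embeds them for plotting, truncating negative eigenvalues with a
warning when the input is not Euclidean-realizable.

When a table of published component scores is supplied, the pipeline bypasses
the PCA and uses them directly — the reproduction path for printed distance
summaries.

## Population genetics

Genotypes are biallelic dosages (0/1/2, missing allowed), loci x individuals,
with a site label per individual. Estimators:

- Observed heterozygosity and unbiased expected heterozygosity
  `2pq * 2n/(2n-1)` per locus, pooled or per site.
- The conditional Hardy-Weinberg exact test in two forms: full enumeration
  over heterozygote counts given allele counts, and a Markov-chain Monte
  Carlo estimate (Metropolis walk on the heterozygote count with the
  conditional-distribution acceptance ratio — the two-allele case of the
  Guo-Thompson chain), default one million iterations, with a batch-means
  standard error. Exact-test p-values are discrete and conservative
  (super-uniform) by construction; the calibration tests assert no
  anti-conservatism and type-I error at or below nominal, not literal
  uniformity, which no correct exact test can satisfy.
- Weir-Cockerham theta (F_ST) from the a/b/c variance components, combined
  across loci by ratio of sums; pairwise between sites, with the cohort
  average taken as the unweighted mean over site pairs. Negative estimates
  are reported as computed. Loci monomorphic across a pair contribute
  nothing.
- Multilocus F_IS per site as `1 - sum(Ho)/sum(He)`, averaged unweighted over
  sites.
- Individual genetic distance as the allele-difference count
  `sum |dosage_i - dosage_j|` over loci typed in both, rescaled by
  `n_loci / n_shared` so missingness does not shrink distances. ("Nucleotide
  differences" for diploid SNPs is ambiguous; the dosage-L1 convention is the
  default and the tree checks are topological.) Neighbour joining uses
  scikit-bio's Saitou-Nei implementation; bootstrap support resamples loci
  with replacement and counts bipartition recovery.

## Matrix comparison

Mantel tests correlate two site-level distance matrices over their unique
pairs, with significance from seeded label permutations. The default tail is
one-sided (greater), the add-one convention keeps p > 0, and geographic
matrices may be log(d+1)-transformed (inter-site distances are right-skewed).
UPGMA trees (average linkage, node heights half the merge distance) of the
immune, genetic and geographic matrices support tanglegram-style comparison;
the package emits the trees and a leaf-order mismatch count, not a drawn
tanglegram.

## Structural equation models

The SEM engine is covariance-based maximum likelihood in the RAM
parameterization: `Sigma(theta) = F (I-A)^-1 S0 (I-A)^-T F^T`. Models are
written in a small text language (`latent =~ indicators`, `y ~ x`, `a ~~ b`);
each latent is identified by fixing its first loading to 1, and the
standardized solution is reported alongside (results on heterogeneous scales
are only interpretable standardized). Identification is checked by counting
free parameters against covariance moments, and the path graph must be
acyclic.

The three default models share one structural core — exogenous season (day
length) and age with a free covariance; season, age and infection feeding
condition; season and age feeding infection (infection is serological, i.e.
historical, so condition cannot feed back into it); and all four feeding the
latent immune state — and differ in the measurement block: adaptive cellular
(scaled CD4/CD8/CD19 counts), innate cellular (scaled NK, neutrophil, DC,
macrophage counts), humoral (IgG, IgE, IgA). This reconstruction yields df =
8, 14 and 8 respectively, matching the published fits, which is the
structural validation of the reconstruction. Models are always fitted per
sex.

Fitting minimizes `F_ML = ln|Sigma| + tr(S Sigma^-1) - ln|S| - p` on
listwise-complete rows, with an analytic gradient, L-BFGS-B from a unit start
plus seeded jittered restarts, and a damped Newton polish using the numeric
Hessian (the surface is ill-conditioned when variables sit on different
scales; the polish reliably drives the gradient below 1e-9). Inputs are
power-of-ten rescaled by default; chi-square and the standardized solution
are invariant to this (tested). `chi2 = (n-1) F_ML`; standard errors are
`sqrt(diag((2/(n-1)) H^-1))` with H the numeric Hessian. Non-convergence is
flagged, never silent.

Fit indices: RMSEA `sqrt(max(chi2-df,0)/(df(n-1)))` with a 90% CI from
noncentral-chi-square inversion; CFI against the independence (diagonal)
baseline; SRMR over all p(p+1)/2 correlation-scale residuals including the
diagonal. The acceptance rules mirror the study's reporting conventions:
RMSEA and SRMR below 0.05 are a good fit, RMSEA above 0.05 is accepted when
the lower 90% confidence limit is 0.000, CFI above 0.95 is very good and
above 0.80 acceptable, and chi-square nonsignificance is noted but flagged
unreliable at these sample sizes.

Because no independent SEM implementation exists in the supported
environment, the engine is cross-checked against a reference fitter that
lives in the test suite and shares nothing with it beyond the model
description: implied covariance by the nilpotent total-effects series instead
of matrix inversion, the raw Gaussian likelihood instead of F_ML, and
Nelder-Mead plus numeric-gradient BFGS instead of analytic-gradient
quasi-Newton. Agreement is asserted to 1e-3 on five fixed synthetic datasets.
The engine's chi-square is additionally validated distributionally: on data
simulated from a fitted model with Gaussian errors it follows the chi2_df
reference (KS test over 150 replicates).

## Synthetic cohorts

The generator's defaults are the study conditions, chosen once:

- 460 mice over 12 sites; the site-size profile follows the published
  per-site genotyping counts (HW 167 ... SP 6), largest-remainder scaled.
- Sex odds male:female 1.18 (male fraction 0.541).
- Ages gamma(shape 1.9174, scale 4.6358 wk), matching median 7.4 weeks and
  75th percentile 12 weeks; implied mean 8.9, SD 6.4 weeks.
- Day length uniform over 450-1010 minutes (year-round trapping in southern
  Britain).
- Seven serological infections with baseline prevalences (0.55, 0.45, 0.40,
  0.25, 0.30, 0.35, 0.20) and a per-SD-age slope of 0.06 in a linear
  probability model: overall seroprevalence ~95%, burden-age correlation
  ~0.3. Positive microbes get an ordinal severity drawn uniformly from 1-4;
  only presence/absence feeds the models.
- A linear-Gaussian structural system with the published signs: condition
  improves with age (0.35 per SD) and weakly with season; the cellular
  compartments are promoted by condition (0.45) and constrained by age
  (-0.30); the humoral compartment rises with age (0.35) and infection
  (0.25). Three latent compartments (adaptive, innate, humoral) carry the 10
  indicators; adaptive and innate residuals share a common component
  (correlation 0.8) so all seven cell counts co-vary on the first principal
  component, while IgA is mostly unique — emulating the cells / IgG+IgE /
  IgA component structure. Site effects are independent Gaussian shifts per
  compartment, which creates among-site immune distance without any
  geographic signal (the null the matrix comparisons are expected to
  report).
- Cell counts are modulated multiplicatively by (length/mean length)^1.7 so
  the allometric count scaling has something real to remove; body mass
  follows a length power law (exponent 3) with a condition effect on the log
  scale, making SMI recoverable.
- Genotypes are Balding-Nichols: per-site allele frequencies drawn from
  Beta(p(1-F)/F, (1-p)(1-F)/F) around global frequencies uniform on
  (0.1, 0.9), Hardy-Weinberg within site; 1,168 loci, differentiation target
  F = 0.48, 1% missing calls. Balding-Nichols was chosen over explicit drift
  simulation because it gives an analytic target for the F_ST estimator.
  The F -> 0 limit is available as an explicit panmixia flag.

All randomness flows from a single seed; per-site streams are spawned from
it, so adding a site leaves earlier sites' draws untouched and identical
config + seed is byte-identical. The full covariance of the observed
variables (including the Bernoulli-sum infection variance and the lognormal
length modulation of the cell counts) is available in closed form and matches
the sample covariance at n = 100,000 within 2% on the correlation scale.

What the generator does not emulate: spatial population structure (site
positions are random and independent of everything), pedigree/relatedness
within sites, linkage between loci, measurement floor/ceiling effects, and
seasonal confounding of trapping with site. Passing tests therefore
demonstrate that the estimators and models recover known structure under the
stated sampling conditions — not that the original study's data would yield
the same numbers.

## Numerical choices and problem sizes

Distance-matrix symmetry is enforced within 1e-9 on read. UPGMA ties break
by the label-sorted order of the input. The Mantel permutation p and the
HWE Markov chain are seeded; the chain burns in 10,000 steps (or 10% of the
chain if shorter). SEM optimization uses 10 restarts by default (2 in the
replicate studies, where the warm start is reliable); convergence is a
polished gradient norm below 1e-5, typically 1e-9.

The test suite scales its simulation studies to what a single CPU handles
comfortably: 200 SEM recovery replicates at n = 5,000; 150 parametric
bootstrap replicates at n = 300; 500 loci for the HWE calibration at n = 500
individuals (large enough that the exact test's discreteness does not
dominate); 300 null draws with 99 permutations for the Mantel type-I check;
1,000 loci for the Balding-Nichols recovery. These sizes are the package's
own choices and are stated in the tests themselves.

## Known limitations

- The lens-age calibration is a placeholder shape, not a published curve.
- FIML is not implemented; missing data in the SEMs are handled by listwise
  deletion with the retained n reported.
- The Weir-Cockerham estimator and the AMOVA-style variant used by some
  desktop tools coincide only up to small-sample terms for biallelic diploid
  data.
- SE of pairwise-distance means ignores pair non-independence (see above).
- Mantel p-values are one-tailed by default; two-sided is available.
- The published per-mouse immune raw data are not deposited, so the original
  SEM estimates and the 53/13/10% PCA variance split cannot be reproduced
  numerically; the package instead validates the reconstructed model
  structure (df = 8/14/8), parameter recovery, and oracle agreement on
  synthetic cohorts.
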
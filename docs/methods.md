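# Methods

## Data model and standardisation

The unit of observation is one individual × tissue measurement of
(δ¹³C, δ¹⁵N). Tissues integrate diet over different windows (plasma days,
red blood cells weeks, feathers the moult period) and carry different
discrimination offsets, so raw values are z-scored within tissue before
modelling: for each tissue, each isotope axis is centred and scaled to
mean 0, SD 1 (sample SD, n−1 divisor), pooling across species and — by
default — across seasons. Pooling seasons keeps one transform per tissue
and preserves seasonal contrasts inside a tissue; a `per_season` flag fits
one transform per (tissue, season) instead for designs where the same
tissue type is sampled in both seasons but should be centred separately.
Body and primary feathers are treated as distinct tissues because they are
grown in different seasons and carry different seasons' dietary signals.
The fitted transform is stored with the dataset and reproduces the
z-values exactly when re-applied, and standardisation is idempotent to
floating tolerance.

## The bivariate mixed model

Each species × season group is fitted separately with its own
fixed-effect centroid, between-individual covariance G (2×2) and residual
covariance R (2×2):

    y_it = mu + beta_campaign(it) + b_i + e_it,
    b_i ~ N2(0, G),   e_it ~ N2(0, R)

Sampling campaign is a fixed categorical effect with reference-level
coding (first campaign alphabetically is the reference). Tissue is *not* a
fixed effect: standardisation has removed tissue means, and the remaining
tissue-to-tissue variation within an individual is precisely the
repeated-measures signal that defines the within-individual component.
Fitting groups separately is the minimal structure that yields
group-specific G and R (a single model with one homogeneous covariance
pair cannot produce per-group niche components); a joint model with
group-indexed covariance structures is deliberately out of scope.

Priors: flat on fixed effects; inverse-Wishart(identity scale, df = 3) on
both G and R. On the z-scored scale these are weakly informative — the
prior contributes the equivalent of roughly one observation's
sum-of-squares — and both scale and df are configurable. The Gibbs cycle
samples, in order: the fixed-effect matrix from its matrix-normal full
conditional; the individual intercepts b_i from bivariate normal full
conditionals with precision n_i R⁻¹ + G⁻¹ (vectorised over individuals);
G ~ IW(S_G + Σ b_i b_iᵀ, df_G + n_individuals); and
R ~ IW(S_R + Σ e_itᵀ e_it, df_R + n_records).

Default MCMC settings are 100,000 iterations, burn-in 5,000, thinning 10,
five independent chains — the protocol intended for real analyses. All
tests and the acceptance script use `MixedModelConfig.test_scale()`
(20,000 iterations, burn-in 2,000, thinning 10, three chains) or smaller;
these sizes were chosen as the package's own desk-scale defaults after
checking that potential scale reduction factors sit near 1.00 and
parameter recovery is unbiased at these lengths. Convergence is assessed
with the Gelman–Rubin PSRF per scalar parameter (two centroid components,
three unique entries each of G and R) across chains, threshold 1.1
(conventional); non-convergence is recorded in the report, not fatal.
Identifiability requires ≥ 3 individuals and at least one individual with
≥ 2 records; a design in which every individual is measured once cannot
separate G from R and is rejected.

Determinism: per-chain generators are spawned from a single
`SeedSequence`, so a fixed seed reproduces every draw bit-for-bit.

## Niche metrics

Per retained draw, WIC = eigenvalue sum of R, BIC = eigenvalue sum of G
(the eigenvalue sum of a symmetric matrix equals its trace, which the
tests exploit as an oracle), TNW = WIC + BIC exactly, and IS = BIC/TNW.
IS is summarised as the posterior mean of per-draw ratios, not the ratio
of posterior means — the two differ, and the draw-wise version is the one
with a coherent posterior interpretation. Draws with TNW = 0 (possible
only for degenerate inputs) are excluded from IS with a reported count.
Reported "SE" values are posterior standard deviations. IS is invariant to
jointly rescaling G and R, so it is unaffected by the overall scale the
standardisation imposes.

## Ellipses and overlap

A coverage-p ellipse of N₂(c, S) uses the χ²₂ quantile q = −2 ln(1−p)
(p = 0.67 by default, q ≈ 2.217); its exact area is π q √det S. Ellipses
are polygonised with 360 vertices (area error < 0.1%) and directional
overlap is area(A ∩ B)/area(A) via polygon intersection. Overlap ellipses
use the *total* covariance G + R — the total-niche-width ellipse —
centred on the draw's campaign-averaged marginal mean (intercept-only
centroids available by flag). Overlap is computed at each MCMC draw,
pairing draw j of one group with draw j of the other; the groups are
fitted independently, so index pairing is an arbitrary but deterministic
convention, and a draw-count mismatch is an error rather than an
invitation to resample. The identity
area(A)·overlap(A,B) = area(B)·overlap(B,A) (both equal the intersection
area) holds to polygonisation error and is checked in the tests, as is
agreement within 0.01 with a rejection-sampling Monte-Carlo oracle.

## Mechanism inference

Directional probabilities are strict-inequality fractions over
index-paired draws; ties are reported separately so the three parts sum
to one. M1 compares each overlap direction between seasons
(P(overlap_breeding < overlap_non-breeding)); M2–M4 compare IS, TNW and
WIC respectively within species between seasons. Each comparison also
reports posterior-mean differences, fold ratios and percent changes. A
configurable evidence threshold (default 0.67) flags supported
directions; it is a reporting convention, not a test with error control,
and no multiplicity correction is applied.

## Competition index

Patristic distances are computed from a user-supplied ultrametric Newick
tree with branch lengths and divided by the maximum pairwise distance —
max-scaling is the only normalisation that guarantees the stated [0, 1]
range. The Gaussian kernel α(d) = exp(−d²/2σ²α) with σ²α = 0.05 maps the
most distant pair to exp(−10) ≈ 4.5×10⁻⁵ and conspecifics (d = 0) to 1,
so Nz = Σ N(z′) α(d) is bounded below by the focal species' own
abundance, is linear in abundances, and decreases monotonically in every
interspecific distance. Multi-year censuses are averaged within season
before summation; species censused in one season only contribute zero in
the other (absence is data, not an error), but any censused species
missing from the tree is an error. Estimating σ²α from data is out of
scope.

## Ecological opportunity

Richness is the count of taxa with positive pooled counts per season;
diversity is the reciprocal Simpson index D = 1/Σ p_i², which ranges from
1 (single taxon) to the richness (even community) and is invariant to
scaling all counts. The seasonal contrast is descriptive — percent change
of the non-breeding relative to the breeding season — with a multinomial
bootstrap interval from resampling prey items with season totals fixed.
No seasonal effect is asserted: the contrast quantifies the observed
difference and its resampling uncertainty only.

## Synthetic data: what it emulates and what it does not

The generator draws from exactly the model the sampler fits: Gaussian
individual intercepts and residuals around group centroid + tissue offset
+ campaign effect. The default study design mirrors a two-species colony
study — group sizes 25/18 (resident/dispersive, non-breeding) and 31/37
(breeding), three tissues per bird in non-breeding (plasma, red blood
cells, body feather) and two in breeding (plasma, primary feather), five
non-breeding and eight breeding sampling campaigns with zero campaign
effects (no published effect sizes exist, and zero keeps recovery
baselines clean). Planted covariances are isotropic with
WIC/BIC = 1.09/0.30, 0.73/0.36 (resident, non-breeding/breeding) and
1.36/1.70, 1.94/0.25 (dispersive), placing per-tissue pooled variances
near 1 so the z-scored scale approximately coincides with the generative
scale; centroids differ modestly, mostly on the carbon axis in breeding.
Community censuses are lognormal with 2–5× breeding aggregation; trees
are random ultrametric joins; prey tables follow geometric rank-abundance
series with ~43% higher planted richness in the non-breeding season.

Passing tests on these data show that the estimators recover the
quantities they target *under the model's own assumptions*. Real isotope
data violate those assumptions in ways the generator does not emulate:
tissue-specific discrimination and turnover make tissues differ in more
than their means (heterogeneous R by tissue is not modelled), diets drift
within seasons, individuals are captured with unequal probability, and
isotopic noise can be skewed or heavy-tailed. Results on real data
therefore inherit the usual caveats of Gaussian mixed models; the tests
certify the machinery, not those assumptions.

## Numerical choices and degenerate inputs

2×2 inversions use the closed-form adjugate; covariance square roots use
symmetric eigendecomposition with eigenvalues clipped at zero (tolerance
−1e−10 for PSD checks); stored G/R draws are symmetrised to remove
floating-point asymmetry. Ellipse polygonisation refuses singular
covariances; eigen-sums refuse matrices asymmetric beyond 1e−8 relative;
standardisation refuses tissues with fewer than two records or zero
spread; the PSRF is undefined (error) when every chain is constant.
Percent change and fold ratio refuse zero denominators. Seeds below 2³¹
are used throughout so they remain portable across RNG backends.

## Known limitations

- Per-group fits cannot borrow strength across groups; small groups
  (n ≈ 18) show visible prior influence on G.
- Index pairing of draws across independently fitted groups is a
  convention; directional probabilities involving two groups would change
  slightly under a different pairing.
- The overlap geometry is strictly bivariate; more isotope axes would
  need a different region estimator.
- The bootstrap for diversity contrasts resamples items, not pellets, so
  it understates between-pellet clustering.
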
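# Methods

This note records the statistical model behind `diatomcal`, the numerical
choices made where conventions diverge, what the synthetic benchmark does
and does not emulate, and the known limitations.

## Data model and preprocessing

The calibration set is a site × taxon valve-count matrix (integer counts,
row totals > 0), a site × variable environment table, and optional site
coordinates (transect km or lon/lat; distances are |Δkm| or haversine km).
Preprocessing follows the standard recipe:

- **Relative abundance** per site; the **rare-taxon cutoff** keeps taxa with
  ≥ `min_pct`% (default 1) relative abundance in ≥ `min_occurrences`
  (default 2) sites. Surviving proportions are *not* renormalised by
  default, so the retained share of counted valves stays reportable;
  `renormalize=True` restores constant row totals (which some identities,
  notably WAPLS(1) ≡ WA_inv, rely on). An alternative cutoff of >2% in one
  site is available through the same two parameters.
- **Hellinger transform**: square root of row-renormalised proportions;
  makes Euclidean distance (and hence linear ordination) appropriate for
  closed compositional data.
- **Environment**: variables with |adjusted Fisher–Pearson sample skewness|
  above 1.0 (configurable) are log10(x+1)-transformed, then all columns are
  centred and scaled to SD 1 (ddof = 1). The skewness statistic and the
  1.0 threshold are a common rule of thumb; nothing downstream is sensitive
  to the exact cutoff because scaling follows regardless.

## Ordination and screening

**Correlation groups.** Variables are linked when |Pearson r| > 0.8 with
p < 0.001 (t distribution, n−2 df); groups are connected components of the
link graph, so chained redundancy lands in one group. Constant columns are
excluded with a warning rather than treated as correlated with nothing.

**DCA gradient length.** Only the first axis matters for the linear-vs-
unimodal decision, and segment detrending does not alter axis 1, so the
implementation computes the correspondence-analysis axis by SVD of the
chi-square standardised matrix and expresses its length in SD units by
Hill-style nonlinear rescaling: species standard coordinates (unit weighted
variance), shrunken site scores as within-site weighted means, and the
local within-site dispersion of species scores estimated in 26 equal-width
segments (empty segments borrow the pooled value); the axis length is the
sum of segment widths divided by local dispersion. Against vegan's
`decorana` this underestimates lengths by a roughly constant factor
(≈0.7 on Gaussian-packing fixtures) but classifies short (< 2 SD) and long
(> 2 SD) gradients the same way, which is all the recommendation uses.

**RDA / partial RDA.** Species columns are centred (not standardised —
the Hellinger transform already equalises scale); with covariates, both the
community matrix and the constraints are residualised on them first.
Constrained axes are the principal axes of the fitted values of the
multivariate regression on the constraints, residual axes those of the
residuals; eigenvalues are variances (SS/(n−1)) and match vegan's `rda`
to machine precision on shared fixtures. Constraints fully absorbed by
the covariates are dropped with a warning (their conditional contribution
is zero); rank deficiency *within* the constraint set is fatal.

**Permutation tests.** Pseudo-F = (constrained SS/q)/(residual SS/(n−q−
p_cov−1)); the null permutes the site labels of the constraint columns
freely while covariates stay fixed ("unrestricted" permutation), and
p = (1 + #{F* ≥ F})/(1 + n_perm). The p-value floor is therefore
1/(n_perm+1); `forward_select` warns when the floor exceeds alpha, since
nothing could then be selected. Type-I error at α = 0.05 is measured at
≈0.04–0.08 over 200 null replicates in the acceptance suite.

**Forward selection** adds, per step, the candidate with the largest
additional explained variance among those with permutation p ≤ α given the
already-selected variables plus covariates; exact ties break
lexicographically for determinism. **Independence tests** condition each
member of a selected pair on the other; a variable that loses conditional
significance is dependent, and the one with the larger marginal variance
(ties: lexicographic) is retained. **Variance partitioning** reports each
selected variable's unique share (partial RDA with all other selected
variables plus covariates as conditioning set — the stricter of the two
possible conditioning conventions, configurable by passing a different
covariate list), the joint constrained share, and the covariate share, all
as percentages of the unadjusted total variance.

**λ₁/λ₂ criterion.** The ratio of the single constrained axis eigenvalue to
the *first residual* axis eigenvalue of the same partial RDA, flagged
usable when > 0.5. "First residual axis" is the interpretation under which
the published screening-table ratios (0.89, 0.69, 0.27, 0.22) equal
RDA1%/PC1% exactly, which the acceptance suite checks by arithmetic.

## Calibration engines

**WA.** Optima û_k and tolerances t̂_k are abundance-weighted means and SDs;
initial site estimates are weighted averages of optima, with weights
y_ik/t̂*_k² under tolerance down-weighting. Deshrinking is ordinary least
squares: inverse regresses x on the estimates (fitted line = prediction);
classical regresses the estimates on x and inverts. Tolerances are floored
at 1% of the gradient span and single-occurrence taxa (tolerance 0 by
construction) receive the mean finite tolerance, so down-weighting cannot
produce infinite weights. An N2-based tolerance debias (÷√(1−1/N2)) is not
applied; the weighted-SD convention is reported as-is.

**WAPLS.** Component a: taxon scores are WA of the current residual of x;
raw site scores are WA of the taxon scores; the component is orthogonalised
against earlier components under site-total weights and standardised to
zero weighted mean and unit weighted SD (a pure conditioning choice —
predictions are invariant to it, which the tests assert indirectly via the
training round-trip); x is then regressed on all components with site
totals as weights. Prediction replays the stored taxon-score chains,
orthogonalisation scalars and regression coefficients. A degenerate
component (zero weighted variance, e.g. constant x) stops the chain and the
model predicts the weighted mean. Requesting more components than the
centred matrix's rank is fatal, reporting the usable maximum.

With constant site totals (proportion matrices) WAPLS(1) with inverse
deshrinking *is* WA_inv; the suite asserts agreement to 1e-8 there. On
Hellinger input row totals vary slightly and the two differ in the third
decimal — the same near-coincidence the published model grids show.

**Prediction** drops taxa absent from training (warning suppressed inside
cross-validation folds, where drops are routine), reports per-site coverage
(fraction of the assemblage mass on training taxa), and returns NaN rather
than a number for zero-coverage sites. Models serialise to versioned JSON.

## Validation

- **Jackknife (LOO)**: each site is predicted by a model refit — response
  estimation included — without it; fold-empty taxa are dropped per fold.
- **Performance**: RMSE(P); r² as squared Pearson correlation (not
  1−SSE/SST; the two differ under bias); average bias; maximum bias as the
  largest |mean residual| over 10 equal-width gradient segments (empty
  segments skipped). Ten segments is the common convention; it is a
  parameter.
- **Model grid**: {WA_inv, WA_cla, WA_tol_inv, WA_tol_cla, WAPLS(1–3)} ×
  {Hellinger, untransformed}; the selected row maximises r²_jack, then
  minimises RMSEP, then maximum bias — a documented lexicographic rule, with
  the full grid always emitted so a human can override it.
- **Outlier screen**: sites whose LOO residual deviates from the mean
  residual by > 2.5 SD are flagged and the refit-without-them performance
  is reported; nothing is removed automatically — exclusions are an explicit
  configuration choice (`exclude_sites`), never silent.
- **RNE**: for each radius, neighbor deletion removes training sites within
  d km of the test site; environment deletion removes the *same number* of
  sites closest in the target variable (matched deletion sizes keep the
  three schemes comparable); random deletion removes that number uniformly,
  averaged over 10 repetitions. At radius 0 all schemes reduce exactly to
  plain LOO, also in the presence of co-located sites. The default radius
  grid {0, 1, 2, 5, 10, 20, 40} km spans the benchmark's correlation length.

## Synthetic benchmark

The generator emulates: sites uniform on an 80-km transect; temperature as
a unit-variance Gaussian process with exponential covariance (range 10 km)
plus a +1.2 SD bump over a contiguous 8-site "bay" block, affinely rescaled
to exactly 10.3–13 °C; Secchi as a negative affine function of temperature
(realised r ≈ −0.8) and turbidity its mirror; nine ions/salinity proxies
sharing one latent marine factor diluted at three river-mouth sites (noise
sized so pairwise r ≈ the configured block target, default 0.85); DSi as
the latent factor's negative (elevated at rivers); and seven weakly- or
un-structured extra variables so screening has true negatives. Taxa (55
benthic + 19 planktonic) get optima spread with jitter slightly beyond the
gradient, lognormal tolerances centred near 0.8 °C, and lognormal peak
abundances; expected proportions follow Gaussian responses to temperature
(jittered by `noise_sd` = 0.3 °C per site) times a spatially structured
secondary latent field with per-taxon loadings (SD 0.5), and counts are
multinomial with 400–500 valves per site.

What it does **not** emulate: taxonomic realism, zero-inflation beyond
multinomial sampling, seasonal succession, sediment taphonomy and mixing,
measurement error in the environment table, or the particular covariance
of a real coastline. Passing tests therefore demonstrate that the
estimators behave correctly *under the unimodal-response model they
assume*, not that any particular field dataset meets those assumptions.
Signal strength in the benchmark is deliberately moderate rather than tuned
to any published skill level: cross-validated r² lands around 0.7–0.85
depending on seed.

## Problem sizes and determinism

Every stochastic operation takes an explicit seed; the pipeline derives
per-stage seeds by stable SHA-256 hashing of the stage name, so inserting a
stage does not reshuffle downstream randomness, and rerunning a
configuration reproduces every output byte-for-byte. The acceptance script
uses 20 benchmark replicates for the WAPLS/WA identity and optimism checks,
200 replicates × 199 permutations for type-I calibration, 50 random
instances against the brute-force RDA oracle, and 5 replicates × 10 random
repetitions for the RNE contrast — sizes at which each Monte Carlo answer
is stable to well within the margins being asserted.

## Known limitations

- DCA lengths are comparable against the 2-SD rule, not against `decorana`
  output unit-for-unit (see above).
- The permutation scheme is unrestricted permutation only; reduced-model
  residual permutation is not implemented.
- No bootstrap or h-block cross-validation; the jackknife plus RNE is the
  validation surface. No modern-analogue or Bayesian reconstruction
  methods.
- IndVal group combinations use A = mean(C)/(mean(C) + Σ means outside C),
  one of several published conventions; combinations are off by default.
- WA optima are undefined for taxa absent from the training matrix and the
  package treats an all-zero taxon column as an error rather than imputing.
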
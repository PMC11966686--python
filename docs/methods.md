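# Methods

This note documents the statistical machinery in `divstab`: what each
stage computes, the assumptions behind it, the defaults and why, and the
numerical and design choices made where more than one defensible option
existed.

## Stability decomposition

For one site, abundances form a years × species matrix over the sampled
years of the site's selected window.  With μ and σ denoting temporal mean
and *sample* SD (n − 1 denominator, used consistently across all modules
because windows hold only 15–20 observations):

- community stability `S_com = μ_com / σ_com`, the inverse CV of the
  yearly community totals;
- asynchrony `φ = Σ_j σ_j / σ_com`, which is ≥ 1 by the triangle
  inequality for standard deviations and equals 1 exactly when all
  species fluctuate proportionally;
- population stability `S_pop = μ_com / Σ_j σ_j`, the abundance-weighted
  average of species-level inverse CVs;
- `log S_com = log φ + log S_pop` holds as an algebraic identity, which
  the tests verify to 1e−10 on random matrices.

Assumptions: sampled years are treated as exchangeable draws (no
detrending, no gap interpolation); zeros recorded in sampled years are
genuine observations and enter the moments; species never observed at a
site are dropped.  A site whose community total never varies has
undefined stability and is excluded with a logged reason rather than
propagated as an infinity.

## Site selection

A window of fixed calendar length (default 20 years) is slid over every
integer start year; the placement containing the most sampled years wins,
ties going to the earliest placement (a pure determinism choice — nothing
in the procedure prefers either end).  The window is then trimmed so its
endpoints are sampled years.  Filters: ≥ 5 sampled years and ≥ 15 years
between first and last sample.  Retained windows therefore satisfy
5 ≤ n ≤ 20, 15 ≤ span ≤ 19 and sampling frequency ≥ 5/20 = 0.25.  The
implementation is checked against exhaustive search on random instances.

## Degree-day climate variables

GDD uses the exceedance form `Σ max(T − 5 °C, 0)` over a calendar year —
the standard agronomic definition, and monotone under warming.  FDD is the
*signed* sum of daily means on days strictly below 0 °C, so it is ≤ 0 and
larger (closer to zero) in mild winters; both variables therefore increase
with warming, which keeps their SEM coefficients directionally
comparable.  Years missing more than 10% of their days are dropped with a
warning (interpolated series should be complete; the tolerance guards
against truncated inputs).  Per-site summaries (mT, sdT) are the mean and
sample SD over the *sampled* years of the site's window, mirroring the
community series.

## Diversity metrics

**Pace-of-life axis.**  PC1 of the z-scored species-pool trait matrix
(eigendecomposition of the covariance).  Ordinal traits enter as integer
level ranks; nominal traits are excluded by default because one-hot
columns distort a life-history axis (a flag re-includes them).  The axis
is computed once per species pool, not per community.  Eigenvector sign is
arbitrary, so the axis is anchored: if the designated slow-life-history
trait (default `generation_length`) loads negatively, the axis is
multiplied by −1.  High score = slow pace of life.

**CWPoL** is the relative-abundance-weighted mean score of the species
present in a community-year, averaged over years per site.

**FDis.**  Gower dissimilarities over mixed-type traits (numeric and
rank-coded ordinal: range-scaled absolute differences; nominal: simple
matching; missing values drop out of a pair's average, and a species
missing more than half its traits is an error).  The matrix is embedded by
principal coordinates; negative-eigenvalue axes — generic for Gower — are
retained as an imaginary block, and distances to the abundance-weighted
centroid are corrected as `z_j = sqrt(|d_real² − d_imag²|)`.
FDis = Σ p_j z_j; a single-species community has FDis 0.  The tests check
the embedding pathway against a direct quadratic-form oracle
(`z_j² = Σ_k p_k d_jk² − ½ Σ_kl p_k p_l d_kl²`) that never forms the
embedding.  Note that with two species at Gower distance 1 each sits 0.5
from the centroid, so FDis = 0.5 — dispersion is measured to the centroid,
not between species.

**MPD.**  Mean patristic distance over unordered pairs of the species
present (NaN for single-species years, which are then simply absent from
the temporal average).  Presence-only by default — the convention of the
standard community-phylogenetics implementations — with an
abundance-weighted variant (`Σ p_i p_j d_ij / Σ p_i p_j`) behind a flag.
With a set of trees (posterior samples), distances are averaged across
trees, which is equivalent to averaging MPD because MPD is linear in the
distances.

## Piecewise structural equation models

Variables are continuous per-site summaries, so every submodel is a
Gaussian OLS regression of an endogenous vertex on its DAG parents
(generalized responses are out of scope).  Coefficients are standardized
post hoc as raw × SD(x)/SD(y) over the analysis rows; rows with a missing
value in any model variable (typically MPD at species-poor sites) are
dropped listwise, with a logged count, so all submodels share one row set
and likelihoods are commensurable.

**Basis set.**  One independence claim per unordered non-adjacent vertex
pair, excluding pairs tied by a correlated-error term (their covariance is
a free parameter) and pairs of two exogenous vertices (their covariance is
unconstrained by the model).  The conditioning set is the union of both
vertices' parents.  The regression response is the vertex later in a
fixed (lexicographic) topological order; when that vertex is exogenous the
pair is swapped, since an exogenous vertex can always be ordered first.

**Tests and fit.**  Each claim is tested by regressing the response on its
conditioning set plus the other vertex; the claim's p-value is the
two-sided t-test of that extra coefficient.  Fisher's C = −2 Σ ln p is χ²
with 2k df under the causal model; p-values are clamped at 1e−16 with a
warning so C stays finite.  The χ² statistic compares summed submodel
log-likelihoods (at the ML residual variance, RSS/n, so nested differences
are χ²) against a saturated model that frees exactly the basis-set
claims — each claim adds one slope to its response's submodel — giving
df = k, the number of claims.  AICc = −2L + 2K + 2K(K+1)/(n−K−1) with K
counting every slope, intercept and residual variance.  When n ≤ K + 1
the statistic is undefined; the low-level function raises, and the
pipeline reports NaN with a warning and falls back to the goodness-of-fit
statistics for ranking.  A model is *supported* only when both the
Fisher's C and the χ² p-values exceed 0.05.

**Deterministic submodel.**  `logScom ~ logSpop + logPhi` is an exact
identity of the decomposition.  It is fitted like any other submodel (its
R² ≈ 1 is a useful pipeline sanity check), but its residual variance
underflows: regressions on an exact-fit response report p = 1 for
zero coefficients rather than 0/0, and its enormous log-likelihood term
appears in both the model and the saturated sums (where it largely
cancels in the χ²) and dominates the absolute scale of AICc.  Absolute
AICc values are therefore not interpretable across datasets; ΔAICc within
a dataset is.

**Effects and modification.**  Indirect effects multiply standardized
coefficients along each directed path (depth-first enumeration; the DAG
guarantees termination) and sum over paths of length ≥ 2; the direct
(length-1) effect is reported separately.  For a linear-Gaussian system
with a single exogenous source this reproduces the marginal standardized
regression coefficient, which the tests verify at n = 10⁵.  Failed
independence claims (p < α) are *suggested* as either a new directed edge
or a correlated-error term, ranked by p; the engine never modifies the
model itself — the caller chooses, edits the model text and refits.

**Correlated errors.**  Pearson correlation of the two vertices' submodel
residuals (centered raw values for exogenous vertices) with a t-test
p-value.  The default topology places correlated errors among the three
trait-structure variables (FDis, MPD, CWPoL), which share unmodelled
drivers; this choice is user-overridable in the model text.

## Spearman screening

Average ranks for ties, Pearson correlation of ranks, two-sided p via
`t = r √((n−2)/(1−r²))` on n − 2 df, with an exact permutation option for
n < 10.  Stars at 0.05/0.01/0.001, unadjusted (screening, not inference).
On tie-free data the implementation agrees with the classical
`1 − 6 Σd²/(n(n²−1))` formula to 1e−12; for x = [1,2,3,4,5],
y = [2,1,4,3,5] that formula gives r = 1 − 6·4/120 = 0.8.

## Synthetic data: what it emulates, and what it does not

The generator reproduces the *statistical* structure the estimators
assume, at the scale of multi-decadal monitoring schemes:

- **Phylogeny**: pure-birth (Yule) trees, rate 1, tips `sp001…`.
- **Traits**: each numeric trait is `w·L + (1−w)·E_k` with L a shared
  Brownian latent axis on the tree and E_k independent Brownian noise;
  `w = pol_weight` (default 0.7) plants a recoverable pace-of-life axis.
  Note that two independent Brownian traits on the same tree still show a
  heavy-tailed *sample* correlation across species at any tip count (deep
  shared branches act as a common factor); independence holds, and is
  tested, on phylogenetically whitened values.
- **Abundances**: log-normal, because monitoring abundances are strictly
  positive and the log-normal makes CV and correlation directly
  plantable (σ_log = √ln(1 + CV²) exactly).  Species' log-fluctuations
  are equicorrelated at `synchrony_rho` (default 0.3, moderate synchrony;
  admissible range −1/(S−1) ≤ ρ ≤ 1), per-species CVs uniform in
  `cv_range` (default 0.2–0.8, spanning steady to volatile populations),
  species membership per site drawn once (no colonization/extinction, so
  planted φ targets refer to a fixed community), and years kept by
  independent Bernoulli draws (`sampling_prob`, default 0.85 — the
  typical median sampling frequency of such schemes; presets range from
  0.9 to 1.0).  Perfect synchrony plus a common CV makes species
  proportional and forces φ = 1 exactly; independent equal-σ species give
  E[φ] ≈ √S.
- **Temperature**: sinusoidal annual cycle (amplitude 12 °C around a 4 °C
  mean — a boreal-range seasonal swing), day-to-day noise (SD 2 °C), and
  a monotone cross-site offset (default 0.25–0.5 °C per site) emulating a
  latitudinal gradient; complete daily coverage, as interpolated products
  provide.
- **SEM tables**: variables in topological order, exogenous standard
  normal, endogenous = coefficient-weighted parents + Gaussian noise.
  The default planted system on the diversity–stability DAG uses moderate
  coefficients (|β| 0.1–0.6) with unit noise.

Not emulated: density dependence or species interactions, spatial
autocorrelation between sites, observation error distinct from process
noise, trends or regime shifts, and any *net* planted diversity→stability
effect in the community generator (richness varies across sites, but
stability is not wired to it).  Passing tests therefore demonstrate that
the estimators recover what is planted under their own assumptions — not
that those assumptions hold for any particular field dataset.

## Numerical choices

- Sample SD (ddof = 1) everywhere a temporal SD is taken.
- OLS via QR; rank deficiency detected from the R diagonal and reported
  with the aliased column names.
- Exact-fit detection at RSS ≤ 1e−12 × TSS; exact fits get zero-variance
  inference (p = 1 for zero coefficients) and a log-likelihood evaluated
  at a floored residual variance to stay finite.
- PCoA eigenvalues within 1e−9 (relative) of zero are discarded as noise.
- Equicorrelation matrices are factored by eigendecomposition with
  eigenvalues clipped at zero, so the ρ = 1 boundary is handled exactly.
- Brownian covariances get a 1e−10 relative jitter before Cholesky.
- All randomness flows from explicit integer seeds through
  `numpy.random.default_rng` (and a seeded `random.Random` for the tree
  simulator); identical configuration and seed give byte-identical
  outputs, which the tests assert file-by-file.

## Problem sizes

The test suite and the acceptance script run their simulations at desk
scale, chosen to keep Monte-Carlo error well inside the asserted bands:
1000 random matrices for the decomposition identity; 200 replicates for
the asynchrony and recovery studies (n = 2000 per fit for recovery);
200 random instances per oracle-equivalence check; 300–500 replicates at
n = 200 for the Fisher's C calibration; n = 10⁵ for the path-tracing
identity; and a 40-site, 20-year pipeline run.

## Known limitations

- The moving window slides over calendar years; anchoring windows to
  sampled years would be an alternative reading of "fullest 20-year
  period" and can differ on pathological gap patterns.
- FDis ranges depend on the species set handed to the Gower computation;
  per-pool and per-community ranges differ, and the pipeline uses the
  pool.
- The d-separation p-value is not symmetric in the response/other choice
  at finite n; the fixed topological-order rule makes it deterministic,
  not direction-free.
- AICc absolute values are dominated by the deterministic stability
  identity submodel (see above).
- Whether CWPoL should weight by per-year or pooled-period abundances is
  ambiguous in common usage; per-year weighting before temporal averaging
  is implemented.
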
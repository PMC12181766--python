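# Methods

## Structural models and standardization

Both path models are linear-Gaussian with a single latent confounder
Z ~ N(0,1) and independent, mean-zero, normal error terms. All observed
variables are standardized: the error variances are fixed at
1 − (coefficient)², so Y, X, X′ and Z′ each have unit variance and every
path coefficient is simultaneously a correlation loading. Measurement
follows the classical true-score model — observed = loading × true +
independent noise — so the reliability of a surrogate is the squared
loading (α² for Z′, α_x² for X′). There is no direct exposure → outcome
path in either model: the population squared partial correlation of the
observed exposure and Y given Z′ is entirely residual confounding, and the
rejection probability of the adjusted test above the nominal level is pure
type-I error inflation ("false power").

Parameter domain: loadings and path coefficients are validated on the
*closed* interval [−1, 1]. The boundary is a legitimate degenerate member
of the family — zero error variance — and is required by the calibration
endpoints (α_x = α_z = 1 simulates the exact test). Quantities whose
denominators vanish at the boundary (e.g. the linked-reliability curve at
α_z = 1 with β = 1) are guarded: each factor of the form 1 − ρ² smaller
than 10⁻¹² in magnitude raises a singularity error rather than returning a
clipped value, and boundary limits are obtained by explicit evaluation at
1 − ε (ε = 10⁻⁸ by convention, 10⁻⁶ on default grids).

The same algebra covers three inferential situations — confounder
adjustment, the direct effect in a mediation model, and incremental
predictive validity — because all three reduce to the identical partial
correlation test on the identical implied correlation matrix; the code
speaks of confounding throughout.

## Closed forms and their calculus

The squared partial correlation is assembled from the implied correlation
matrix as (R²_full − R²_reduced)/(1 − R²_reduced) with
R²_full = (ρ_xy² + ρ_z′y² − 2ρ_xy ρ_z′y ρ_xz′)/(1 − ρ_xz′²) and
R²_reduced = ρ_z′y². Substituting the path products gives the closed forms
in the loadings; both first derivatives (Model 1 in α; tied-reliability
Model 2 in α) are implemented as exact rational expressions and were
cross-derived symbolically (sympy) before being frozen into code. The test
suite additionally audits them against central-difference numerical
differentiation at 10⁻⁶ relative tolerance over randomized parameters, and
audits the closed forms against two independent routes: the generic
matrix assembly and exact least squares on the implied covariance.

For the linked case α_x = ω α_z (intercept a0 = 0) the reduced closed form
is evaluated with the numerator factor written as (1 − α_z²)² — the
expanded form 1 − α_z²(2 − α_z²) is algebraically identical but loses ~5
significant digits to cancellation near α_z = 1 — and the denominator
factor 1 − (ω γ α_z²)² as a difference of squares. This keeps the
α_z²/(1+α_z²) identity (ω = −1, β = γ = 1) accurate to ~10⁻¹⁶ across the
grid, including the approach to the ½ limit. The validity constraint
ω < 1/(γ α_z²) is enforced as a domain error naming the bound; it is
checked before the |α_x| ≤ 1 range check so a violating ω is reported
against the bound that actually invalidates the reduced form.

The critical point of the tied-reliability curve is the root of the
bracketed polynomial factor of the derivative,
p(α) = −1 + 3α² + α⁶(2β² − 1)γ² − α⁴(2β² + γ²), found by bisection on
(10⁻⁶, 1 − 10⁻⁶) with |α| tolerance 10⁻¹². Bisection acts on p rather than
on the full derivative because the prefactor 2α(α² − 1)β²γ² never vanishes
on (0,1), which removes the spurious endpoint roots; for β, γ ∈ (0,1),
p(0⁺) < 0 and p(1⁻) = 2(1 − β²)(1 − γ²) > 0, so a unique sign change
always exists and the curve is unimodal with an interior maximum. Analysis
is restricted to α > 0; all curves are even in each loading, so the
negative half-axis is a mirror image.

Shape classification uses finite-difference slopes on a uniform 512-point
grid over [0, 1 − 10⁻⁶] with a sign threshold of 10⁻¹⁰; more than one sign
change among nonzero slopes raises an error, since no curve in this family
can do that — it would indicate a formula bug, not a new regime. All
reported quantities are *squared* partial correlations, and plot/CSV labels
say so.

## False power

The adjusted test — two-sided t on the exposure coefficient in OLS of Y on
(exposure, Z′) with intercept — is the 1-df partial F test (F = t²).
Analytic false power is P(F′ > F_crit) with F′ ~ noncentral F(1, N−3, λ)
and λ = (N−3) f², f² = R²_p/(1 − R²_p), against the central-F critical
value at the nominal level. No finite-sample exactness is claimed for this
population-R² treatment; its contract is the Monte Carlo agreement
invariant below, which it meets at 20,000 replicates across the reliability
grid. At R²_p = 0 the function returns the nominal level exactly (routed
through the central F rather than the noncentral code path, which is not
bit-exact at zero noncentrality).

Two F expressions are provided: the partial-correlation form
R²_p · (N−3), whose bracket is exactly the squared partial correlation and
whose monotonicity in R²_p motivates the whole analysis, and the textbook
hierarchical form with denominator 1 − R²_full. The simulator uses the
standard OLS partial t test by default; rejection based on the
partial-correlation F is available behind a flag (`statistic="paper_f"`)
and is slightly conservative, since its denominator exceeds the OLS one.

## Monte Carlo engine

Samples are generated exactly by the path equations. The per-replicate
test is computed in closed form from sample correlations
(r_p = (r_xy − r_z′y r_xz′)/√((1 − r_z′y²)(1 − r_xz′²)),
t = r_p √(N−3)/√(1 − r_p²)), which is algebraically the OLS coefficient
test and is fully vectorized over replicates; a unit test verifies the
equivalence against `statsmodels` OLS on a single sample. The sample
squared partial correlation is t²/(t² + N − 3).

Reproducibility: a single user seed feeds `numpy.random.SeedSequence`,
which spawns one child stream per 2,000-replicate chunk; results are
bit-identical for a given seed and independent of chunking. Default
replicate count is 10,000 (binomial SE ≈ 0.0022 at a 5% rate); the
calibration and agreement checks use 20,000 (SE ≈ 0.0015) so that a
3-standard-error band is ±0.46 percentage points. Problem sizes in the
shipped tests — up to 20,000 replicates of N = 1,000, and single samples
of 10⁶ for correlation checks — were chosen to keep Monte Carlo error well
below the tolerances being asserted.

What the simulator emulates, and what it does not: linear-Gaussian
structure, independent homoscedastic errors, a single adjustment
covariate, and exactly the null of no direct exposure effect. Real dietary
data add skewness, differential and correlated error, multiple confounders
and nonlinear dose-response; passing tests therefore demonstrate the
internal consistency of the theory and code, not that any real study's
error structure is this benign. In particular the classical-error
assumption (error independent of the true score) is known to fail for
self-reported intake.

## Optimal design search

The design module instantiates one concrete version of the open question
"where should a finite measurement budget go?": minimize analytic false
power over (r_x, r_z, N) subject to
κ_n N + κ_x c(r_x) + κ_z c(r_z) ≤ budget. The reliability cost
c(r) = r/(1 − r) is a deliberate modeling choice, not an estimate: it is
convex, zero at r = 0 and divergent as r → 1, encoding "each extra point
of reliability costs more than the last"; it is pluggable for users with
instrument-specific cost curves. The search is an exhaustive grid
(default 41 reliability points on [0, 0.99] per instrument × 20 geometric
sample sizes) — the objective is cheap and possibly flat, so exactness of
the reported optimum matters more than speed. Ties are broken by lower
cost, then lower N, then higher reliability (never worse, and insurance
against misspecification).

Two structural consequences of the null-only objective deserve emphasis.
First, since false power grows with N, the unconstrained search favors the
smallest feasible N; the module is a bias-control tool, and power against
a true alternative is deliberately out of scope. Second, the global
optimum is degenerate: an exposure instrument with zero reliability never
rejects falsely, so "do not measure the exposure at all" attains exactly
the nominal level. That is a real property of the objective, not a bug;
`r_x_min` imposes a floor on exposure reliability, and with a floor in
place the search reproduces the counterintuitive allocation in which most
of the budget goes to the *confounder* instrument (96% in the README
example) — measured reliably, the confounder can actually be adjusted
away.

## Figures and outputs

The four canonical curves (Model-1 decreasing bias; tied-reliability bias
with its interior maximum at α*; the linked-reliability curve and its
derivative at ω = −1, β = γ = 1) are rendered from the analytic module on
deterministic grids and regression-tested via their CSV side-files, never
by pixel comparison. The linked-reliability figures evaluate α_z up to
0.999, where the curve reaches 0.4995, visibly approaching its ½ limit
(β = γ = 1 makes α_z = 1 a true singularity). CSV and JSON outputs embed
the full parameter set and package version; every CLI run logs the same to
stderr.

## Known limitations

Linear models only — the closed forms do not transfer to generalized
linear models with nonlinear links. One adjustment covariate; no
measurement-error *correction* estimators (regression calibration and
relatives are the complementary literature, deliberately not implemented);
no validation-substudy designs; no non-normal or correlated error
structures. The noncentral-F treatment is asymptotic in spirit and
validated empirically rather than derived exactly for finite samples.
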
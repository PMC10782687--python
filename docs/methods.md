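# Methods

## The model

The core object is a recursive path model over seven observed variables of
the triticale anther-culture system: two exogenous — Cu(II) concentration
in the induction medium and the LMP pectin band absorbance — and five
endogenous — the SAM and GSH band absorbances, the metAFLP CHH *de novo*
methylation (`CHH_DNMV`) and sequence variation (`CHH_SV`) percentages,
and green plant regeneration efficiency (GPRE, regenerants per 100 plated
anthers).  Twelve directed paths (λ₁–λ₁₂), one free covariance (Cu↔LMP)
and five residual variances (δ₁–δ₅) give q = 20 free parameters against
p(p+1)/2 = 28 observed moments, hence df = 8.

All variables are observed (no latent constructs, no mean structure), the
diagram is acyclic and the residuals are mutually uncorrelated.  The
source description calls the paths "non-recursive", which conflicts with
the diagram (no feedback loops, five independent residuals); the package
treats the model as recursive and rejects cyclic specifications outright.
Residual labels δ₁…δ₅ are not tied to variables in the source; they are
assigned in the order the endogenous variables first appear as path
targets (SAM, CHH_DNMV, GSH, CHH_SV, GPRE), the only assignment consistent
with the printed variance magnitudes (the near-zero δ₃ must belong to GSH,
whose absorbance variance is ~1.6·10⁻⁷).

## Estimation

Models compile to RAM form: Σ(θ) = (I−A)⁻¹ S_par (I−A)⁻ᵀ with A holding
path coefficients and S_par variances/covariances.  The ML discrepancy

    F(θ) = ln|Σ| − ln|S| + tr(S Σ⁻¹) − p

is minimised by Fisher scoring with step-halving (expected information
½·tr(Σ⁻¹ ∂ⱼΣ Σ⁻¹ ∂ₖΣ), analytic derivatives), with an L-BFGS fallback.
Convergence requires |ΔF| < 1e−10 or a gradient ∞-norm < 1e−8 within 500
iterations.  Starting values are deterministic: per-equation least squares
for paths and conditional variances for residuals.  For this model class —
recursive, uncorrelated residuals, saturated exogenous block — the
likelihood factorises along the DAG, so these starting values already
solve the problem and the iteration serves as verification; the optimiser
is general and the test suite checks that perturbed restarts return to the
same minimum.  Because the observed variances span eight orders of
magnitude (GSH ~1.6·10⁻⁷ vs Cu ~12.4), the optimisation runs in a
correlation-scaled metric and maps estimates and standard errors back; F
is invariant under this rescaling (tested).

Conventions, chosen to match the mainstream SEM software the original
analysis used: χ² = (N−1)·F_min; standard errors from the inverse expected
(not observed) information ((N−1)/2)·tr(Σ⁻¹∂ⱼΣΣ⁻¹∂ₖΣ); the fitted sample
covariance uses the ML divisor N (the printed exogenous variances,
e.g. 12.4414 = 12.787·36/37, confirm this); the standardised solution uses
implied, not sample, standard deviations.  Improper solutions (negative
variance estimates) set a `heywood` flag and warn rather than raise; for
this model class they cannot actually arise from a positive-definite
sample matrix, since every variance estimate is a sample or conditional
variance.

## Fit indices

The independence baseline (all covariances zero) has the closed form
χ²_b = −(N−1)·ln|R|, df_b = p(p−1)/2.  Index formulas are the standard
AMOS/lavaan-convention ones (GFI = 1 − tr[(Σ̂⁻¹S−I)²]/tr[(Σ̂⁻¹S)²], SRMR on
correlation-metric residuals over all 28 unique elements, CFI with the
max(·,0) guards, RMSEA = √(max(χ²−df,0)/(df(N−1))) with the 90% interval
by numerically inverting the noncentral-χ² CDF, PCLOSE at RMSEA₀ = 0.05,
ECVI = (χ²+2q)/(N−1) with interval (λ_bound+df+2q)/(N−1), Hoelter
N = ⌊χ²_crit/(χ²/(N−1))⌋+1).  Indices that need df > 0 (or χ² > 0 for
Hoelter) report `None` rather than raising.

Two printed statistics are internally inconsistent with the printed
χ² = 8.4558, df = 8, N = 37 and are *not* reproduced by design: the
printed RMSEA of 0.0379 (the formula gives 0.0398 from the printed χ²,
0.0410 from our refit; no N/N−1 convention yields 0.0379) and the
PNFI/PCFI pair (printed 0.381/0.355, while (df/df_b)·NFI = 0.355 and
(df/df_b)·CFI = 0.379 — the two values appear transposed).  The package
reports its computed values; the fixture files keep the printed ones for
comparison.

## Effects

With B the endogenous←endogenous block and Γ the endogenous←exogenous
block, total effects are (I−B)⁻¹Γ and (I−B)⁻¹−I; B is nilpotent for
acyclic models, so the inverse is exact and equals the sum over all
directed paths of edge-coefficient products (property-tested against a
brute-force path enumerator).  Decompositions run independently in the b
and β metrics.  Exogenous-on-exogenous rows (the Cu↔LMP covariance) are
excluded, matching the published table layout.  Note one reproducibility
limit of the printed tables: unstandardised indirect effects through the
GSH equation multiply a 4-decimal-rounded coefficient (λ₆ = 0.0006) by a
large one (λ₉ ≈ 1535), so recomputing them from printed values is
rounding-dominated; the identity total(LMP→GPRE) = λ₁·total(SAM→GPRE) is
exact and is what the tests assert.

## Reconstruction from printed tables

The raw 37×9 per-regenerant table was never published; only descriptive
statistics and the correlation matrix were.  An ML covariance-structure
fit depends on data only through (S, N), so the analysis is reconstructed
as S = D·R·D·(N−1)/N from the printed sample SDs and correlations.  The
printed values carry 3–4 decimals, which propagates to the third decimal
of the refit (χ² = 8.485 vs printed 8.456, Hoelter 66 vs 67, standardised
estimates within 0.002).  Truncated correlation cells (",386" style) are
transcribed as 0.386 etc.; one typographically corrupted effect-table cell
("2.253sss9") is transcribed as 2.2539, the printed λ₁₂.  All fixtures are
shipped as CSV with SHA-256 checksums verified at load.

## Synthetic data

The generator emulates the unpublished regenerant table as a joint
multivariate normal over all nine variables with the printed means and
D·R·D covariance — exactly the asymptotic-normality premise under which
the ML fit is justified.  Defaults are the study conditions: N = 37, eight
trials A–H with Cu(II) ∈ [0.1, 10], Ag(I) ∈ [0, 60], 35–49 days, 3–10
regenerants per trial (per-trial compositions are not itemised in the
source; the default grid spans the ranges and sums to 37).  A second,
design-conditional mode fixes Cu/Ag/Time at the trial values and draws the
six responses from their MVN conditional distribution, reflecting that the
design variables are set, not sampled.  Known departures from real data:
an MVN has zero skewness/kurtosis, so the mild printed non-normality is
not matched, and design variables are continuous-jointly-normal in
"paper" mode.  Passing tests therefore demonstrate correctness of the
estimator and pipeline under the model's own assumptions, not robustness
to non-normality.

The parameter-recovery harness draws from the implied covariance at a
generating θ, refits, and reports bias/RMSE per parameter and sample size.
The fitted (unrounded) study solution serves as generating truth; the
printed one cannot, because δ₃ prints as 0, which would make GSH exactly
collinear with its parents.

## FTIR bands

Processing follows routine ATR practice: pointwise averaging of replicate
scans (64 per sample in the emulated protocol), baseline correction
(linear endpoints per segment by default; rubberband/convex-hull as an
alternative — both are approximations to unspecified vendor processing),
unit-area normalisation of the 1800–900 cm⁻¹ region with the scale factor
applied globally (the GSH band at 2550–2540 cm⁻¹ lies outside the window
but its printed values are on the normalised scale), and band aggregation
as the arithmetic mean of points sampled every 10 cm⁻¹ with linear
interpolation (LMP: 990…950; GSH: 2550, 2540).  The SAM region
1630…1470 cm⁻¹ is printed as discontinuous without enumerating the
sub-segments; the band definition accepts arbitrary segment unions and
defaults to the full range.  The packaged demo spectrum is synthetic:
Gaussian components scaled so the extracted band values equal the printed
mean absorbances — a calibration for round-trip tests, not a measurement.

## Problem sizes and numerical choices

Test-suite simulations use sizes chosen to keep Monte-Carlo error well
inside the asserted bounds while remaining quick: recovery at
n ∈ {50, 200, 1000} × 100 replicates, critical-ratio calibration with 600
replicates of n = 200 (7 200 null critical ratios, binomial SE ≈ 0.3%),
oracle agreement on 20 random 4–6-variable models at n = 400.  All
simulation seeds are fixed.  Degenerate inputs are defined errors:
non-positive-definite matrices name their smallest eigenvalue, constant
vectors yield NaN shape statistics, zero-variance columns yield NaN
correlations with blank significance flags, df = 0 models report undefined
index markers.
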
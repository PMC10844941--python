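# Methods

## Accelerometer processing

Counts per minute (cpm) over 60-s epochs are classified with validated
hip-worn cut-offs: SED < 200, LIPA 200–2689, MPA 2690–6166, VPA ≥ 6167
cpm. Non-wear is any maximal run of ≥ 60 minutes of zero counts in which
interruptions of at most 2 consecutive minutes with 0–199 cpm are
tolerated (and counted as part of the bout); a minute ≥ 200 cpm or a
low-count run longer than 2 minutes terminates the candidate. Several
interruptions may occur in one bout provided each is separated by at
least one zero minute; bouts begin and end on zero-count minutes. The
scanner is verified in the test suite against two independent oracles (a
regex maximal-match formulation and an exhaustive window scan).

Registrations outside the wake window — 05:52–23:46 on weekdays,
07:15–23:59 on weekends, both bounds inclusive, weekend = Saturday/Sunday
by local calendar date — are excluded before any wear accounting. These
defaults correspond to the first quartile of in-bed end times and the
third quartile of in-bed start times in thigh-accelerometer data;
`derive_wake_window` recomputes them from user-supplied in-bed intervals
using type-7 (linear interpolation) quantiles rounded to the minute. Any
consistent quantile rule shifts the window by minutes only.

A valid day has strictly more than 600 minutes (> 10 h) of wear inside
the wake window; participants with fewer than 4 valid days are excluded
(reported with a reason code, never silently dropped). Wear and
valid-day accounting happen after the wake-window filter and non-wear
removal. Percentages of time in each intensity are taken over total wear
minutes across valid days.

## Compositional treatment of exposures

The four-part composition is mapped to additive log-ratios with LIPA as
reference; this reference empirically minimises the mean absolute
correlation among coordinates (`select_reference` reports the full
diagnostic table). Because VPA is exactly zero for a sizeable minority
of participants, 0.1 percentage points are added to VPA before the
transform. The shift is applied to **all** rows (a uniform
pre-transform shift), not only zero rows; the alternative is available
via `shift_all_rows=False`. After transformation, rows whose original
part value was zero are assigned the minimum transformed value among
originally non-zero rows, per coordinate, so "none recorded" maps to an
equally low value everywhere; this replacement is idempotent. The alr
coordinates entering models are standardized (mean 0, SD 1, sample SD
with ddof = 1) on the final analysis sample, after all exclusions.

## Microbiome features

Species are analysed as relative abundances (fractions of 1). The
prevalence filter keeps species with abundance > 0.01% (strict) in ≥ 1%
of samples (inclusive), and modules present (> 0) in ≥ 1% of samples.
The clr transform adds a pseudocount to **all** entries — 0.001% of
total for species, 0.00001% for modules — and applies the same
zero-replacement rule as the alr, per feature across samples. The
geometric mean is taken over the features present in the supplied table;
filtering therefore precedes the transform in the pipeline (passing an
unfiltered table gives the all-features variant).

Alpha diversity (Shannon in nats, inverse Simpson, richness) is computed
on counts rarefied to a common depth (protocol default 210 430 read
pairs) by exact multivariate-hypergeometric subsampling; samples below
depth are excluded with a report. Bray–Curtis dissimilarities are
computed on (unrarefied) relative abundances.

Functional modules are scored from ortholog abundances using the
published convention of the standard module-quantification tool: a
module is an ordered list of steps, each a set of alternative orthologs;
step abundance is the sum over alternatives, coverage the fraction of
steps with positive abundance, and the module abundance the **median**
over covered steps when coverage ≥ 2/3 (compared with a 1e-9 tolerance;
66.6% is the decimal rendering), else 0. The scoring rule is isolated
behind `ModuleDefinition`, so mean/min variants are pluggable; exact
tie-breaking for alternative step paths in other implementations is not
reproduced.

## Association engine

Each clr feature is regressed on the three standardized alr exposures
jointly plus covariates (main set: age, sex, alcohol, smoking,
education, country of birth, site, month of wear, diet variables, energy
intake, plus technical covariates wear time, % weekend wear and DNA
plate; the adiposity set adds BMI and WHR). Complete-case filtering
happens once per model specification, so the full and covariates-only
fits share samples exactly. Categorical covariates use reference-level
dummy coding; a rank-deficient design raises an error naming the
collinear columns.

Fitting is multi-response least squares: one QR factorisation of the
shared design serves every feature, which is algebraically identical to
per-feature OLS (verified against statsmodels in the tests) and orders
of magnitude faster for thousands of features.

The screen is the likelihood-ratio statistic n·ln(RSS_reduced/RSS_full)
on 3 df, from the Gaussian log-likelihood −n/2·(ln(2π·RSS/n)+1). Under
Gaussian errors this statistic is an exact monotone function of
F(3, n−p), and the **default p-value uses that exact finite-sample F
reference**: at desk-scale n (hundreds) with a ~39-column design the
asymptotic 3-df chi-square tail is measurably anti-conservative (true
size ≈ 0.065 at nominal 0.05), while at cohort scale (thousands) the two
are indistinguishable. `ModelSpec(lrt_reference="chisq")` restores the
asymptotic reference. Feature ranking — and hence the BH rejection
order — is identical under both.

Benjamini–Hochberg q-values (own step-up implementation, cross-checked
against statsmodels) are computed separately for the species family and
for module families, at a 5% FDR. Influence screening follows the rule:
for each significant feature, compute standardized dfbetas for the three
exposure coefficients (closed form, verified against leave-one-out
refits to 1e-8), remove the single observation with the largest absolute
value across the three, refit both models, and discard the association
if the refit LRT p ≥ 0.05. Per-exposure removal is available via
configuration. Collinearity is summarised by per-exposure VIFs
(1/(1−R²) of each exposure on all other design columns).

Heterogeneity of the MPA and VPA coefficients is a Wald contrast of
H0: β_MPA = β_VPA, referred to F(1, n−p) by default (matching the usual
linear-hypothesis implementation; chi-square optional), applied to
features whose MPA or VPA coefficient is individually significant
(per-exposure BH q < 0.05) within the screened set, with BH across the
tested features. Sensitivity analyses re-fit the significant features
under variant covariate sets or sample subsets and report counts
remaining significant plus Spearman correlations of coefficients against
the base run.

## Ordination

Partial dbRDA: Gower double-centering of −D²/2, eigendecomposition,
retaining axes with positive eigenvalues as sample coordinates. For
non-Euclidean Bray–Curtis matrices the negative-eigenvalue inertia is
dropped and reported (no Lingoes/Cailliez correction by default,
matching the reference implementation's behaviour). Coordinates and
constraints are residualized on the conditions (with intercept);
constrained inertia is the squared norm of the projection of residual
coordinates onto residual constraints. A constraint whose residual norm
falls below 1e-8 of its original scale is treated as fully absorbed
(contribution 0, p = 1). The joint adjusted R² is the Ezekiel-style
difference R²adj(conditions + constraints) − R²adj(conditions), which is
what the standard implementation reports for partial models; this is
verified directly against `vegan::capscale` in the tests (vegan scales
inertia by n−1). Per-constraint contributions are leave-one-in:
each residualized constraint alone, with a 1-df adjustment.

Permutation inference is Freedman–Lane on reduced-model residuals: the
residualized coordinate rows are permuted, re-residualized on the
conditions, and the constrained-inertia pseudo-F recomputed;
p = (#{F* ≥ F} + 1)/(n_perm + 1), so the smallest attainable p is
1/(n_perm + 1). Simple row permutation is available as an option.
Tests use 999 or fewer permutations; 9999 reproduces survey-scale
precision. In the Euclidean, unconditioned case the constrained-inertia
fraction equals the redundancy-analysis R² from direct multivariate OLS
(checked to 1e-8).

## Synthetic-data generator

The generator emulates a week-long free-living actigraphy protocol with
faecal metagenomics. Study conditions (defaults): 7 days of minute
streams; in-bed periods around 23:00–07:00 with ±90-minute jitter
(truncated at ±90) so the wake-window filter is non-trivially
exercised; genuine daytime non-wear bouts of 60–180 minutes in about a
quarter of days, half containing a tolerated ≤ 2-minute low-count
interruption; wake-time counts drawn uniformly within the intensity band
of a per-minute state sampled from the participant's target composition.
Target compositions follow a logistic-normal model centred at
SED/LIPA/MPA/VPA ≈ 55.5/39.5/4.7/0.3% of wear time with realistic
between-person spread and negative SED–activity correlations —
consistent with the medians of large population actigraphy cohorts —
and the lowest-VPA quartile is recorded as exactly zero so the alr
zero-replacement path is exercised. About 5% of participants are
generated with fewer than 4 valid days to exercise the exclusion logic.

`generate_timeuse` draws the same participant-level compositions
directly, bypassing minute streams; the replicate studies (null
calibration, FDR, parameter recovery) use this fast path, since
minute-level generation exercises the accelerometry code but adds
nothing to the statistical question; the minute-level path is covered by
its own tests and by the end-to-end pipeline runs.

Covariates mirror a population cohort (age ~ N(57.6, 4.3), realistic
categorical distributions, diet and adiposity variables, medication and
antibiotic indicators) plus a latent health-consciousness variable that
shifts exposures (less SED, more MPA/VPA) and planted features at a
configurable confounder strength (default 0).

Species abundances are logistic-normal: per-sample log abundances are
Gaussian (baseline means ~ N(−2, 2), per-species noise SD ≈ 1), planted
features receive β·z_exposure on the log scale — exact on the clr scale
because clr removes the softmax normaliser — and a few species are
engineered far below the prevalence threshold. Zero inflation is a
**per-species** detection probability decaying with the species' typical
abundance (rare species are lost most), applied after composition with
renormalisation. Two generator properties matter for calibration
studies and were chosen deliberately: (i) dropout depends on the
species' baseline, not its realized per-sample abundance — realized-
abundance dropout couples unplanted features to the exposures through
the compositional denominator and genuinely breaks their null status;
(ii) calibration studies plant sign-balanced effect sets (equal +β/−β
within each exposure), because an unbalanced planted mass shifts every
feature's clr value through closure. Both effects are real properties
of compositional data, not artifacts; with unbalanced planting the
"null" features measurably deviate from null and no multiplicity
procedure can control an FDR defined against the planting list.

What the generator does **not** emulate: phylogenetic correlation
between species, overdispersed sequencing noise, batch effects beyond a
plate label, true functional coupling between the ortholog table and the
species table, and measurement error in the accelerometer itself.
Passing tests therefore demonstrate correctness and calibration of the
computational chain under a clean compositional model, not robustness to
every property of real cohort data.

## Problem sizes and numerics

Replicate studies use n = 500 participants, 150–200 species and 50
replicates (null calibration: two independent cohorts of 1350 species);
the dbRDA null study uses 200 replicates × 199 permutations at n = 40;
the end-to-end pipeline runs at 120 participants × 7 days with a
20 000–50 000-read-pair sequencing depth. These sizes give stable
Monte-Carlo estimates at interactive runtimes; all randomness flows from
explicit seeds and every pipeline artifact is content-hashed, so
identical configurations reproduce bit-identical outputs.

Tolerances: clr/alr identities hold to 1e-9; dfbeta closed form to 1e-8
against refits; dbRDA vs direct regression to 1e-8; eigenvalues below
1e-9 of the spectral radius are treated as null axes. Degenerate inputs
(all-zero samples, all-absent features, zero-reference compositions,
rank-deficient designs) raise typed errors rather than propagating NaNs,
except all-absent clr features, which become flagged NaN columns so
callers can account for them.
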
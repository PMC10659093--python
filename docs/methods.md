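# Methods

## The estimand and the analysis model

The package studies how the choice of a symptom-questionnaire case
definition changes the measurable strength of a gene–environment
interaction. The interaction of interest is between *PON1* Q192R genotype
(RR vs QQ; the R allele impairs hydrolysis of certain organophosphates) and
a binary self-reported exposure (having heard nerve-agent alarms). Analyses
follow the Knol–VanderWeele presentation: cases and controls are
cross-classified by exposure within the two homozygote strata, with
QQ-unexposed as the single reference category. QR heterozygotes are
generated (Hardy–Weinberg) but excluded from 4×2 analyses, so the genotype
contrast is a clean RR-vs-QQ comparison; an intermediate heterozygote risk
is still modelled so the cohort's genotype–disease structure is realistic.

Additive interaction is the relative excess risk due to interaction,
RERI = OR₁₁ − OR₁₀ − OR₀₁ + 1, computed from a logistic model (case status
on genotype, exposure, their product, and optional covariates) or in closed
form from the 4×2 cells. Its confidence interval uses the method of
variance estimates recovery: Wald limits for each of the three odds ratios
on the log scale, recombined on the natural scale with the estimated
pairwise correlations of the three linear combinations of coefficients.
This produces the asymmetric limits appropriate for a difference of
log-normally distributed quantities; near the null (all ORs → 1) the
limits collapse to the symmetric delta-method interval, which the tests
verify. Multiplicative interaction is reported as the exponentiated
interaction coefficient (POR) with a Wald interval. Survey weights are not
used in the case-control interaction fits; confounding is handled by
covariates (age centred, sex, ordinal combat scale treated as numeric).

Heterogeneity of the interaction across a stratifier (e.g. sex or age band)
is assessed with stratum-specific crude estimates plus a likelihood-ratio
test comparing logistic models with and without products of the stratifier
dummies with the gene, exposure and interaction terms (3·(L−1) degrees of
freedom for L usable strata; strata with an empty 4×2 margin are dropped
with a warning).

## Misclassification correction and intrinsic specificity

The correction assumes: (i) the control group — subjects meeting no case
definition — contains no true cases and is therefore fixed under
correction; (ii) the strict reference definition has perfect specificity,
so the exposure prevalence of its cases estimates p_R, the exposure
prevalence of true cases; (iii) the loose definitions have perfect
sensitivity, so all true cases are inside their case groups; and (iv)
misclassification is nondifferential with respect to genotype and exposure.
Under these assumptions a definition's case group of size G decomposes into
G·Sp true cases with exposure prevalence p_R and G·(1−Sp) false positives
with the controls' exposure prevalence p_C — here Sp operates as the
fraction of diagnosed cases that are truly ill. The corrected cells are

    a′ = G·Sp·p_R + G·(1−Sp)·p_C      c′ = N_C·p_C
    b′ = G·Sp·(1−p_R) + G·(1−Sp)·(1−p_C)      d′ = N_C·(1−p_C)

applied separately per genotype stratum with that stratum's G, N_C, p_R and
p_C. Mass is conserved (a′+b′ = G, c′+d′ = N_C) for every Sp. When
p_R > p_C in both strata the corrected RERI is strictly increasing in Sp,
so matching it to the biased RERI (computed directly from the observed
cells) has a unique solution: the intrinsic specificity. Sensitivity never
appears in the equations: with Sp fixed, nondifferential sensitivity loss
removes true cases at random, scaling a′ and b′ equally and cancelling from
every odds ratio — the package accepts an assumed Se in the
sensitivity-analysis grid and deliberately leaves the cells untouched, so
the corrected RERI is bit-identical across assumed Se values.

The root finder is a safeguarded bisection on Sp. It stops only when both
the residual |corrected RERI − biased RERI| ≤ tol and the bracketing
interval width ≤ tol: on nearly flat stretches of the curve (biased RERI
close to zero, i.e. little interaction signal) the residual criterion alone
would stop arbitrarily far from the matching specificity. Defaults:
bracket (0.5, 1.0) — field questionnaires rarely fall below 50%
specificity — tolerance 1e-4 (specificities are reported to 3 decimals),
at most 100 iterations. The pipeline uses a wider bracket (0.05, 1.0)
because the synthetic loose definitions are deliberately diluted further
than real instruments. If the corrected RERI at Sp = 1 already equals the
biased value within tolerance, the definition's specificity is perfect and
Sp* = 1 is returned directly. Confidence intervals for corrected RERIs
treat the fractional corrected cells as counts in the crude-OR covariance
formula; they are approximate and cannot be confounder-adjusted, and are
reported as such.

Sensitivities follow from population prevalences: true-positive prevalence
= diagnosed prevalence × Sp (unrounded), and Se is the ratio of a
definition's true-positive prevalence to the reference (perfectly
sensitive) definition's. All intermediates stay unrounded; presentation
rounding (Se to 2 d.p., percentages to 1 d.p.) happens in one formatter,
which matters at the margins — e.g. a false-negative share of 41.08%
rounds to 41.1 only if the inputs were not pre-rounded. The two
perfect-sensitivity definitions imply slightly different true-case
prevalences; the package follows the convention of anchoring Se ratios to
one named reference and surfaces both prevalences in the output rather
than reconciling them.

## The synthetic cohort

The generator's defaults describe a deployed force of 6,500 veterans
(matching the survey's deployed sample size), an R-allele frequency of
0.30, exposure drawn independently at 25%, and an additive risk model with
baseline risk p₀ = 0.05 (QQ, unexposed), genotype relative risk 2, exposure
relative risk 3 and a target RERI of 4, giving a true-illness prevalence
near 10% — the same order as the strict definition's published prevalence.
The doubly exposed cell's risk is p₀·(rr_g + rr_e − 1 + RERI) exactly, so
the target is the risk-scale RERI by construction. QR heterozygotes get the
geometric-mean genotype effect with a proportionally scaled interaction
excess (configurable). Exposure enrichment in true cases (p_R > p_C)
arises endogenously; closed-form Bayes-rule values of both prevalences are
provided for testing. The `exposure_prev_noncase` parameter is the marginal
draw rate, which equals the non-case prevalence to first order because
illness is uncommon; the closed form gives the exact value.

Symptoms are drawn conditional on the latent illness state: true cases
endorse each item with probability 0.8 with severities concentrated on
moderate/severe (0.10/0.45/0.45 over mild/moderate/severe), non-cases with
probability 0.06 concentrated on mild (0.75/0.20/0.05); six-month duration
flags hold with probability 0.9 for endorsed symptoms. This reproduces the
bimodal number/severity distribution qualitatively: controls score near 0,
true cases near the top of the 0–56 range. A configurable 20% of non-cases
are planted with exactly enough mild six-month symptoms (two per domain in
three Kansas domains, one in two CDC domains) to satisfy the loose
definitions but not the severe or strict ones — the false-positive
dilution channel. The strict research-like state is a latent draw: each
true case is flagged with probability `strict_sensitivity` (default 0.5,
between the two published strict-definition sensitivity estimates), making
the strict definition a perfect-specificity, imperfect-sensitivity subset,
which is the configuration the correction model assumes. Comorbidities are
independent Bernoulli draws at age-appropriate prevalences; survey strata
are age × sex × combat cells with inverse-sampling-fraction weights; two
SF-12-style summary scores are generated as negatively associated with the
number/severity score (direction-of-association stand-ins only).

What the generator does **not** emulate: interview nonresponse mechanics,
the full survey stratification, item-level SF-12 content, correlated
symptom batteries within domains, or comorbidity–illness dependence.
Passing tests therefore demonstrate the internal consistency and
statistical calibration of the estimators under the stated generative
model, not the numerical values obtainable from the original survey data.
In particular the published adjusted RERI values cannot be regenerated
(their underlying cell counts are unpublished); the pipeline instead
reproduces the qualitative ordering — strict definition RERI above loose,
and loose-minus-strict below loose — which is the method's headline
structural claim.

## Estimator scales and problem sizes

The generative target is additive on the risk scale, while case-control
tables yield odds ratios; OR-based RERI approximates risk-based RERI only
under rare disease. Generator calibration checks therefore use the
risk-scale RERI computed from full-cohort cumulative incidence (exact for
the generative estimand at any prevalence), while the case-control
odds-ratio path is validated separately: interval coverage under an
additive null with genuine main effects (ORs 2 and 3), and the dilution
ordering on the default common-disease cohorts. Replication sizes used by
the tests and the acceptance script — 200 cohorts of 20,000 for parameter
recovery, 1,000 (500 in the script) null tables of 2,000 subjects for
MOVER coverage, 100 (50) random calibration scenarios, 50 (30) replicate
case-control studies for the ordering — were chosen so Monte-Carlo error is
several times smaller than the tolerance being asserted.

## Numerical and degenerate-input choices

Missing symptom severities are treated as absent (conservative toward
non-case) with the imputation count logged. Zero cells in a 4×2 table: the
closed-form crude path refuses to proceed unless a 0.5 continuity
correction is explicitly requested; the regression path raises a
separation error naming the offending margin rather than silently
correcting. Non-positive-definite coefficient covariances are rejected
(Cholesky check with a 1e-12 jitter). The MOVER square-root arguments are
clipped at zero against round-off. The factor-analytic definition requires
more subjects than scales, warns below a 10:1 ratio, and rejects
zero-variance scales by name; factor scores are standardized
principal-component scores under an orthogonal varimax rotation, so the
1.5-SD threshold corresponds to a ~6.7% per-indicator positive rate for
approximately normal scores. The CDC Severe rule defaults to requiring a
severe-rated symptom in every case-qualifying domain (the subgroup then
sits well below the full CDC group, as observed); a stricter
all-symptoms-severe variant is available because the original instrument's
operationalization is ambiguous. Whether mild symptoms count toward the
Kansas domain rule exactly as in the original 32-item instrument after
item reduction is likewise not fully specified; the implemented rule (two
mild or one moderate-to-severe, six-month symptoms only) is the
documented, configurable choice.

## Known limitations

Corrected-RERI intervals on fractional cells are approximate; no
Brenner–Savitz-style model with control-group contamination or
differential misclassification is provided; the weighted-prevalence SE is
a first-stage Taylor linearization, not a full complex-survey variance;
and the two-stage factor machinery is generic — it does not reproduce the
original instrument's 52 scales or fitted loadings.
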
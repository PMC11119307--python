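# Methods

## Diet score

The anti-inflammatory diet score is a sum of 11 binary indicators of "high"
consumption. The frequency thresholds are aligned with the seven-point FFQ
scale as follows: "≥ 3 times/week" means levels {3–4/week, 5–7/week, daily};
"≥ 5 times/week" means {5–7/week, daily}; "daily or more" means {daily} (the
scale has no category above daily); "weekly and more" means {1–2/week and
above}. This is the only alignment consistent with both the thresholds and
the scale. Foods outside the 11 items contribute 0 by definition and are not
stored.

Missing items default to `count_as_low` (contribute 0, counted in
`n_missing_items`), because a study of this design scores all subjects while
reporting per-variable missingness; a `strict` mode raises instead. The
published tercile cut-points (low ≤ 5, medium 6–7, high ≥ 8) are the default;
`control_tercile_cutpoints` re-derives empirical terciles from a control
sample (smallest integer whose empirical CDF reaches 1/3, resp. 2/3) but is
opt-in, since re-derived cut-points on synthetic data can differ from the
published ones. A control distribution without usable variation yields a
degenerate, flagged cut-point pair.

## Genotype calling

The RFLP assay is modelled at the fragment-pattern level (the amplicon
sequence is not an input): GG → {161, 67}, CC → {228}, GC → {228, 161, 67},
with 161 + 67 = 228 enforced as a conservation invariant. Matching is exact
by default; a ±2 bp tolerance is available for gel-estimated sizes, with any
ambiguity mapped to a no-call. Partial-digest patterns such as {228, 161}
are no-calls, never imputed. The Hardy–Weinberg check is a 1-df chi-square
against p², 2pq, q² at the observed allele frequencies; a monomorphic sample
is defined to have statistic 0.

## Statistical models

Crude ORs use the Woolf construction: ln OR ± 1.96·√(1/a + 1/b + 1/c + 1/d).
Logistic models are fitted by Newton-type maximum likelihood (statsmodels
`Logit`); convergence tolerance 1e-10, at most 100 iterations; perfect or
quasi-separation is detected both from the optimizer and from diverging
coefficients (|β| > 20) and raised as an explicit error. All CIs are Wald
intervals on the log-odds scale; no profile likelihood, matching the
symmetric log-scale intervals conventional in this literature. Each model is
complete-case on its own covariates, and the reported n is the row count the
fit actually used.

Covariate codings: education < 8 / 8–13 / > 13 years (reference < 8);
photo-type I–II vs III–IV; nevi ≥ 60 vs 0–59; lentigines high vs
none/few/moderate; childhood sunburn yes/no; BMI ≤ 24.9 / 25.0–29.9 / ≥ 30;
smoking never/current/ex; NSAID and aspirin yes/no; lifetime sun exposure
terciles ≤ 26 / 27–36 / ≥ 37 hours. Age enters adjusted models as continuous
years: the design matches on 5-year strata, but a matched variable still
needs adjustment in an unconditional analysis, and the continuous coding
spends one parameter instead of a dozen. The trend test recodes the tercile
as 0/1/2 and tests β/SE against the normal distribution. The interaction
test is an LRT of the model with all products of the two factors' indicator
columns against the main-effects model on the same rows, df = (k_a−1)(k_b−1).
Stratified estimates refit the adjusted model inside each stratum; strata
too small to fit (fewer complete-case rows than parameters, or a failed fit)
are flagged unavailable with the reason rather than dropped. A stepwise
retention rule (keep covariates at p < 0.05 by LRT) is deliberately not
applied: presets A–H use fixed covariate lists, which is both reproducible
and what the robustness-model structure implies. No multiple-testing
correction is applied anywhere.

The Mann–Whitney U test uses midranks, exact enumeration when both samples
have n < 8 without ties, and the tie-corrected normal approximation
otherwise; a fully tied comparison is defined to have p = 1.

## Synthetic-data generator

Causal order: covariates → diet → disease → case-control sampling, so the
configured log-odds are the estimands a correctly specified fit should
recover. Covariates are drawn independently at the study's control
marginals (the joint covariate distribution of the original data is unknown;
independence is the documented default). Age is truncated-normal on
[18, 90] with mean 51.9 and SD 15.6. Genotypes are Hardy–Weinberg at
allele-C frequency 0.2244 (the allele frequency implied by the genotyped
sample; the observed genotype distribution itself has a ~1-point
heterozygote deficit relative to 2pq, which the generator does not copy).
Lifetime sun exposure is drawn directly over its three printed tercile
categories — only the categories enter any analysis. FFQ items are
independent Bernoulli "high consumption" events; frequency items then get a
uniform level on the matching side of the item threshold, so the indicator
probability is exactly the configured one.

Disease is Bernoulli with logit(P) = intercept + β_score·S + β_T2·1[T2] +
β_T3·1[T3] + Σ β·covariates + genotype and genotype×tercile terms. Two
packaged configurations exercise different parts of this model:

* `calibration_default()` uses a **per-point score effect** (β_score =
  −0.3464, i.e. OR 0.707 per score point) and no tercile terms. The item
  probabilities (mean Σp = 6.13) and β_score were solved exactly on the
  Bernoulli-sum score distribution, jointly with an intercept giving 10%
  population prevalence, so that E[S | control] = 6.2 and E[S | case] = 5.5
  — the study's printed means. A tercile-only risk model cannot reproduce
  that 0.7-point gap: reweighting the three tercile masses by ORs 0.83/0.29
  moves the mean by at most ≈ 0.4 points because within-tercile means are
  unchanged, which is why the calibration uses the per-point term. Two
  printed features are knowingly not matched: the score SDs (2.1/1.9 — a sum
  of 11 independent Bernoullis is bounded by SD √11/2 ≈ 1.66; matching the
  printed SDs would need positive inter-item correlation) and the exact
  control tercile split (the calibrated split is ≈ 32/48/20% vs the printed
  39.8/29.0/31.2%). Passing calibration tests therefore shows the generator
  reproduces the location of the score distributions, not their shape. The
  study's genotyping coverage (303 of 542 subjects) is emulated as a
  genotype missingness rate.
* `tercile_recovery_config()` and `interaction_recovery_config()` switch
  β_score off and put the whole diet effect in the tercile terms (model-A
  truth OR_T3 = 0.29; stratified truths 0.17 in GG and 0.21 in C carriers
  with GG as the reference stratum), so exp(β_T3) is exactly the adjusted
  odds ratio the fits are asked to recover.

Sex and age have zero disease effect in the defaults: they are matching
variables whose case-control distributions are balanced by design, and no
marginal effect is printed for them. Frequency matching allocates controls
over the sex × 5-year-age cells of the sampled cases by largest-remainder
rounding; `exact` mode (equal arm sizes) copies the case cell counts. An
unfillable cell raises an error naming the cell. Everything is driven by a
single `numpy` Generator seeded from the config, so identical config + seed
gives byte-identical datasets; dataset provenance records the config hash
and seed.

## Problem sizes and numerical choices

The calibration check uses 50,000 controls and 50,000 cases drawn from a
560,000-subject population (tolerance ±0.1 on the means; Monte-Carlo SE of
each mean ≈ 0.007). The model-A recovery uses 5,000 + 5,000 subjects from a
130,000 population, the stratified recovery 10,000 + 10,000 from 260,000;
both are judged within 3 SEs of the configured truth, the natural
Monte-Carlo yardstick for a single simulated cohort. Null-calibration of
the LRT and trend p-values uses 500 replicates of n = 400 with a
Kolmogorov–Smirnov uniformity check. Chi-square tests use no continuity
correction; the crude-OR continuity option adds 0.5 to all cells only when a
zero cell is present and only on request.

## Known limitations

* Covariates are generated independently; real pigmentary traits are
  correlated, so synthetic adjusted and crude estimates differ less than in
  real data.
* The generator has no recall-bias or interviewer-effect model, and control
  diagnoses are not simulated.
* Printed crude ORs of the original tables are not reproducible from the
  printed counts alone (they appear to be adjusted estimates); the pipeline
  reports crude and adjusted estimates side by side and does not target
  those printed values.
* The RFLP model is pattern-level; it does not simulate digestion chemistry
  or gel migration error beyond the optional ±2 bp tolerance.
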
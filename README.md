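# aidiet

Toolkit for a case-control analysis of anti-inflammatory diet and cutaneous
melanoma, with the COX-2 −765G>C promoter polymorphism as a candidate
genetic effect modifier. It packages four things:

1. **Anti-inflammatory diet score** — an 11-item score built from a
   food-frequency questionnaire (FFQ). Eight foods are recorded on a
   seven-point frequency scale (never, < monthly, < weekly, 1–2/week,
   3–4/week, 5–7/week, daily) and three are yes/no culinary habits. Each
   item contributes 1 when consumption is "high" (green leafy vegetables,
   salad ≥ 3×/week; other vegetables, citrus ≥ 5×/week; fruits, coffee
   daily; nuts, n-3-rich fish weekly or more; exclusive olive oil, fresh
   rosemary, fresh salvia: yes), so the score S ∈ {0..11}. Terciles from
   the controls' distribution (low S ≤ 5, medium 6–7, high S ≥ 8) are the
   exposure categories in all models.
2. **PCR-RFLP genotype calling** for −765G>C: the 228-bp amplicon is cut
   into 161 + 67 bp when the G allele is present, so {161, 67} → GG,
   {228} → CC, {228, 161, 67} → GC; anything else is an explicit no-call.
   GC and CC are pooled as C carriers for analysis.
3. **Association statistics** — crude odds ratios with Woolf confidence
   intervals, Pearson chi-square and Mann–Whitney U tests, multivariable
   logistic regression (ORadj = exp(β) with Wald 95% CIs), a Wald test for
   linear trend over the ordinal-coded terciles, likelihood-ratio tests for
   nested models and for gene–environment interaction, and genotype-
   stratified estimates. Model presets A–H mirror the study's robustness
   models (A: sex, age, education, nevi, photo-type, lentigines, childhood
   sunburn; B–H add BMI, COX-2 inhibitor use, aspirin, genotype, smoking or
   chronic disease).
4. **A synthetic-data generator** that emulates the study design — covariate
   prevalences matching the control marginals, Hardy–Weinberg genotypes,
   diet-driven logistic disease risk, and controls frequency-matched to
   cases on sex (1:1) and 5-year age strata — so the whole pipeline runs
   and is testable at desk scale without any external data.

## Worked example

```python
from aidiet import calibration_default, simulate_study, analyze

dataset = simulate_study(calibration_default(seed=20240523))
report = analyze(dataset.data, presets=("A", "E"))
```

With the packaged calibration and this seed the simulated study has 273
cases and 269 controls; the report prints

```
control mean score 6.25, case mean 5.44
model A (n=542): OR_T2 0.56 (0.36-0.85), OR_T3 0.13 (0.07-0.27), p_trend 2e-08
interaction p = 0.70, n genotyped = 299
  GG: n=197 OR_T3 0.15 (0.05-0.49)
  C_carrier: n=102 OR_T3 0.14 (0.03-0.65)
```

i.e. a high anti-inflammatory score is strongly protective (adjusted
high-vs-low tercile OR well below 1 with a monotone trend), the effect is
present in both genotype strata, and there is no evidence of interaction —
at n = 542 the single-draw estimates scatter widely around the generator's
truth, which is why the recovery checks below use much larger cohorts.

The same pipeline is available from the shell:

```bash
aidiet simulate --seed 42 --out data.csv
aidiet score    --data data.csv --out scored.csv
aidiet genotype --fragments frags.tsv --out calls.tsv
aidiet analyze  --data data.csv --models A,B,C,D,E,F,G,H --out report/
aidiet reproduce --seed 42 --out study/
```

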
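# Methods

## Model overview

`lodsim` simulates a single birth cohort (everyone starts at age 0
simultaneously) whose members carry a fixed polygenic architecture and age
through yearly steps of probabilistic diagnosis and death. Everything
downstream — cohort formation, power curves, association scans, bias
regression — is post-hoc analysis of the recorded life histories
(per-individual age at diagnosis and age at death), so one simulation
serves every study design.

### Genetic architecture

The common low-effect architecture is a cross product of minor (risk)
allele frequencies {0.073, 0.180, 0.286, 0.393, 0.500} and per-allele odds
ratios {1.15, 1.125, 1.10, 1.075, 1.05} — 25 cells in equal proportions.
SNPs are independent (no linkage disequilibrium), additive on the log-odds
scale, with the risk allele always the minor allele and OR ≥ 1. Genotypes
follow Hardy–Weinberg proportions. The SNP count for a target
liability-scale heritability inverts

    h² = var / (var + π²/3),   var_per_SNP = 2p(1−p) ln²(OR),

dividing the required total variance by the proportion-weighted mean cell
variance (3.639×10⁻³ for the default grid) and rounding to the nearest
multiple of the cell count so the grid splits evenly. This reproduces the
reference counts 625 (h²=0.41), 400 (0.31), 600 (0.40) and 100 (0.095)
exactly. For four other reference heritabilities the closed form gives
3500 (0.795), 2000 (0.69), 1100 (0.55) and 1200 (0.57), each 2–6% below
the commonly quoted 3575/2125/1175/1250 — those published counts do not
follow from the closed form under any simple rounding rule, and we report
the closed-form values.

Grids are fully configurable (frequencies, odds ratios, proportions), so
rare medium-effect architectures can be expressed; only the default grid
is validated.

### Aging loop

Each year of age `t`:

1. **Diagnosis count.** The expected number of new diagnoses is
   `I₀(t) · n_unaffected`; the fractional part carries over to the next
   year, making the count deterministic given the hazard curve (a binomial
   draw is available behind a flag for fully stochastic counts). The
   deterministic count matches the design of driving annual diagnoses from
   the incidence curve and suppresses needless variance at desk scale.
2. **Who is diagnosed.** That many individuals are drawn *without*
   replacement from the unaffected pool with selection weight `exp(β)` —
   the Cox hazard multiplier. The draw uses the Gumbel top-k trick
   (add independent Gumbel noise to the log-weights, take the k largest
   keys), which is exactly equivalent to successive
   probability-proportional-to-weight sampling and runs in O(pool) per
   year. A linear-in-β weight mode exists for sensitivity analysis, and a
   uniform mode produces the PRS-blind null simulator used for
   calibration; `exp(β)` is the default because the hazard model is
   multiplicative and scores compare across individuals only through the
   hazard.
3. **Mortality.** Everyone alive dies with the actuarial probability
   `q_t`, independent of PRS and disease status.

The trace records per-age counts, mean scores of the unaffected pool and
of the newly diagnosed, and per-SNP risk-allele frequencies of the
unaffected-alive pool and of everyone diagnosed to date, maintained
incrementally so each genotype row is touched only when its owner changes
state.

### Incidence and mortality inputs

Two parametric hazard families are bundled: logistic in age
(`cap/(1+exp(−k(t−t₀)))`) for diseases whose yearly incidence rises to a
plateau, and a capped exponential for the common cancers. The per-disease
default parameters are deliberately coarse approximations pitched at each
disease's ballpark lifetime risk and maximum yearly incidence; they carry
no claim of registry accuracy, and quantities that depend on a specific
disease's incidence curve (youngest case ages, per-disease multiples)
should be read as illustrative. The stylised
`synthetic_high_incidence` model (logistic, cap 4%/yr, midpoint 55,
steepness 0.2) is the reference condition for design-effect experiments:
high cumulative incidence with high heritability (h² = 0.55) is the regime
where cohort age structure matters most. Mortality defaults to a synthetic
Gompertz–Makeham table (`q_x = 5×10⁻⁴ + 3.5×10⁻⁵ e^{0.09x}`, capped at 1,
ages 0–119; ~57% survivorship to 80), and any actuarial life table in CSV
form (columns `age`, `death_probability`, optionally per sex) can be
supplied instead.

### Cohorts and power

A case cohort becomes formable at the first age where cumulative incidence
reaches 0.25% of the initial population; the frozen cohort is everyone
diagnosed within the 10-year window ending at that age, and its mid-cohort
age is the crossing age. Controls are uniform samples of the
unaffected-alive pool at a chosen mid-age. Allele frequencies for power
curves are tallied over the full case windows and control pools — the
large-sample limit of cohort sampling — with a sampled mode available for
realism.

Power uses the allelic 2×2 log odds ratio
`β̂ = ln[f_case(1−f_ctrl)/(f_ctrl(1−f_case))]`, pooled frequency
`θ f_case + (1−θ) f_ctrl` with θ = 0.5 throughout (equal cases and
controls; configurable), the non-centrality parameter
`λ = 2Nθ(1−θ)f(1−f)β²`, and the noncentral-F tail
`1 − F'(q; 1, N−4, λ)` at the central-F quantile `q` for
P = 0.99999995 (the 5×10⁻⁸ genome-wide level). Required sizes come from
integer bisection on N, bracketed by the normal-approximation inversion
`√λ* = Φ⁻¹(1−2.5×10⁻⁸) + Φ⁻¹(power)`. scipy's noncentral-F
implementation degenerates at zero noncentrality, so λ = 0 is evaluated
with the central F directly (power then equals the significance level, as
it must).

Design curves report, per control mid-age and per grid cell (SNPs within a
cell are pooled), the cases needed for 80% power and the multiple relative
to the youngest age-matched point, which is 1 by construction and shared
by both designs. The age-matched design re-forms both the case window and
the control pool at every mid-age; the young/old design freezes the
youngest cases. A curve ends when the case window or control pool falls
below 0.25% of the initial population; the frozen case cohort is exempt
from the mortality cut (its data are banked at enrollment), otherwise the
design could never be analysed past its first year since the cohort starts
at exactly the threshold size.

### Association and bias correction

Cohorts export to PLINK text PED/MAP (phenotype 2 = case / 1 = control,
alleles A = reference, B = risk) with an age covariate file. The
association scan is the customary single-SNP logistic regression of status
on dosage (optionally + age), fitted by Newton–Raphson to a log-likelihood
tolerance of 10⁻⁸ with monomorphic and separation guards that flag rather
than crash. Wald p-values are calibrated (uniform under the PRS-blind
null; verified by KS test in the suite).

The normalized bias `D(t) = (β̂(t) − β_true)/β_true` is computed per SNP
at 5-year control-age increments, with `β_true` the architecture's ln(OR)
by default (a youngest-age-matched-estimate mode is also provided). The
regression `D(t) = I₀ + S(t−age_Y)^P` is fitted by grid search over P
(0.5–5.0, step 0.1, with 0.01-resolution local refinement) minimizing
residual standard error; P = 2 is always a grid candidate, so the
best-power fit never has larger residual SE than the quadratic rule.
Correction inverts the fit: `β_adj = β_obs/(1 + D̂(t))`.

## Problem sizes and what desk scale can show

Default experiment sizes are 5×10⁴–2×10⁵ individuals with 10²–10³ SNPs; a
full 120-year run at 2×10⁵ × 1100 completes in well under a minute on one
core. At these sizes the 0.25% rule yields case cohorts of a few hundred,
so:

* **Size-robust** (reproduced here): the closed-form SNP counts; the
  direction and rough magnitude of both design effects (age-matched
  multiple ≫ 1 at old ages, young/old multiple < 1); depletion of risk
  alleles from the aging unaffected pool; growth of D(t) with control age;
  recovery of planted bias-regression parameters.
* **Size-sensitive** (not reproduced): precise per-disease multiples and
  regression coefficients, which additionally depend on per-disease
  incidence approximations not bundled here; the near-identity of the
  young/old multiple across all 25 grid cells, which at a few hundred
  cases is swamped by per-cell frequency noise (spread ±25–55% versus the
  ±10% seen with millions of cases — it shrinks as 1/√n_cases).
* **Approximate at desk scale**: proportionality of D(t) to effect-size
  magnitude. The strongly selected small case cohort induces negative
  inter-SNP correlations among cases (a Bulmer-type effect), attenuating
  single-SNP estimates by a roughly constant absolute amount; relative to
  a small β this depresses D noticeably (measured offset ≈ −0.2 between
  the smallest- and largest-effect cells), while the two D(t) curves
  remain strongly correlated. Single-SNP attenuation for highly polygenic
  traits is a known phenomenon and is deliberately not corrected — D(t)
  is a relative quantity.

The synthetic generator emulates: Hardy–Weinberg genotypes, multiplicative
PRS-hazard coupling, actuarial mortality, and prospective single-birth-
cohort aging. It does not emulate: linkage disequilibrium, population
stratification, sex-specific genetics, environmental covariates,
genotyping error, competing-risk mortality, or birth-year cohort effects —
so passing tests demonstrate properties of the idealized model, not of any
real GWAS panel.

## Numerical choices

* Dosages are int8; per-SNP draws stream in 256-SNP blocks to bound peak
  memory (a PRS-only sampling mode skips genotype storage entirely for
  large-n score distributions, at the cost of cohort tallies and PLINK
  export).
* Yearly diagnosis counts floor-with-carry; ties in the Gumbel draw are
  measure-zero.
* Bisection for required N terminates at integer resolution; the returned
  case count is θ·N.
* The bias power-grid is rounded to 10 decimals so P = 2.0 is represented
  exactly; constant-D inputs return slope 0 with the exponent marked
  not-identifiable.
* Logistic Newton iterations clip the linear predictor at ±30 and flag
  |β̂| > 15 or non-convergence as separation.
* All randomness flows from one `numpy.random.Generator` per run;
  identical seeds give byte-identical traces.

## Known limitations

Mortality is independent of disease status, so the model understates
case-pool attrition for lethal diseases. The bundled incidence parameters
are approximations; users studying a specific disease should supply their
own hazard curve. The effect-size "truth" in simulation is the generating
ln(OR); in real data only the youngest-age-matched proxy is available, and
the two differ by the attenuation discussed above.
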
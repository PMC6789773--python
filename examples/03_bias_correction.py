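"""Effect-size inflation with older controls, and its power-law correction.

Runs the youngest-cases/older-controls association scan at 5-year control
age increments on a simulated population, fits the normalized bias
D(t) = I0 + S (t - age_y)^P in both best-power and quadratic modes, and
shows the corrected estimates for the largest-effect SNPs (true OR 1.15).
"""

import numpy as np

from lodsim import (
    PopulationState,
    bias_analysis,
    build_architecture,
    gompertz_makeham_table,
    run_simulation,
    synthetic_high_incidence,
)

spec = build_architecture(0.55)
rng = np.random.default_rng(7)
print(f"simulating 100,000 individuals, {spec.n_snps} SNPs ...")
state = PopulationState.from_architecture(spec, 100_000, rng)
trace = run_simulation(state, synthetic_high_incidence(), gompertz_makeham_table(), seed=rng)

analysis = bias_analysis(state, trace, spec, seed=rng)
print(f"cases frozen at mid-cohort age {analysis.case_mid_age}\n")

print("normalized bias D(t) of the largest-effect cell (true beta = ln 1.15 = 0.1398):")
for t, d in zip(analysis.control_ages, analysis.d_values):
    print(f"  controls at {t:>3}: D = {d:+.3f}")

for fit in (analysis.fit_best_power, analysis.fit_quadratic):
    print(
        f"\n{fit.mode:>10} fit: P = {fit.power:.2f}, I0 = {fit.intercept:+.4f}, "
        f"S = {fit.slope:.3e}, residual SE = {fit.residual_se:.4f}"
    )

oldest = analysis.adjusted[
    analysis.adjusted.control_mid_age == analysis.control_ages[-1]
].dropna(subset=["beta_raw"])
big = oldest[np.isclose(oldest.beta_true, float(spec.effects.max()))]
print(
    f"\nat the oldest controls ({analysis.control_ages[-1]}), largest-effect SNPs:"
    f"\n  median raw beta      {big.beta_raw.median():.4f}"
    f"\n  median adjusted beta {big.beta_adjusted.median():.4f}"
    f"\n  true beta            {big.beta_true.iloc[0]:.4f}"
)
print(
    "\nRaw older-control estimates overshoot the true log odds ratio; dividing\n"
    "by 1 + D(t) from the fitted regression pulls them back toward it."
)
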
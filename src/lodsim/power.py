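"""GWAS discovery power via the non-centrality parameter, and design curves.

For a 1-df allelic association test on ``N`` samples with case fraction
``theta``, pooled risk-allele frequency ``f`` and allelic log odds ratio
``beta``, the non-centrality parameter is

    lambda = 2 N theta (1 - theta) f (1 - f) beta^2

and power at genome-wide significance is the upper tail of a noncentral
F(1, N-4; lambda) beyond the central-F critical value at
``P_sign = 0.99999995`` (the 5e-8 genome-wide level).

``design_curves`` turns a completed simulation into the required-cohort-size
curves for the two study designs: classical age-matched cohorts, and the
youngest possible cases paired with progressively older controls.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .aging import SimulationTrace
from .architecture import ArchitectureSpec
from .cohorts import DEFAULT_MIN_PREVALENCE, DEFAULT_SPAN, effect_from_frequencies, form_cases
from .population import PopulationState

__all__ = [
    "GENOME_WIDE_P_SIGN",
    "PowerResult",
    "DesignCurve",
    "ncp",
    "statistical_power",
    "cases_needed",
    "design_curves",
]

#: 1 - 5e-8: the two-sided genome-wide significance level as a CDF value.
GENOME_WIDE_P_SIGN = 0.99999995


def ncp(N: float, theta: float, f: float, beta: float) -> float:
    """Non-centrality parameter ``2 N theta (1-theta) f (1-f) beta^2``."""
    if N < 1:
        raise ValueError(f"sample size must be >= 1, got {N}")
    if not 0.0 < theta < 1.0:
        raise ValueError(f"case fraction must lie in (0, 1), got {theta}")
    if not 0.0 < f < 1.0:
        raise ValueError(f"pooled frequency must lie in (0, 1), got {f}")
    return 2.0 * N * theta * (1.0 - theta) * f * (1.0 - f) * beta**2


def statistical_power(lam: float, N: float, p_sign: float = GENOME_WIDE_P_SIGN) -> float:
    """Discovery power of the 1-df test at significance quantile ``p_sign``.

    ``1 - CDF_F'(q; 1, N-4, lam)`` with ``q`` the central-F quantile at
    ``p_sign``.  At ``lam = 0`` the noncentral F degenerates to the central
    F and the power equals the significance level ``1 - p_sign``; that
    branch is computed with the central distribution directly.
    """
    if N <= 4:
        raise ValueError(f"sample size must exceed 4 (needs N-4 >= 1 df), got {N}")
    if lam < 0:
        raise ValueError(f"non-centrality must be non-negative, got {lam}")
    df2 = N - 4
    crit = stats.f.ppf(p_sign, 1, df2)
    if lam == 0:
        return float(stats.f.sf(crit, 1, df2))
    return float(stats.ncf.sf(crit, 1, df2, lam))


def _lambda_star(target_power: float, p_sign: float) -> float:
    """Closed-form normal-approximation NCP achieving ``target_power``."""
    alpha2 = (1.0 - p_sign) / 2.0
    return (stats.norm.isf(alpha2) + stats.norm.ppf(target_power)) ** 2


def cases_needed(
    f_case: float,
    f_ctrl: float,
    target_power: float = 0.8,
    theta: float = 0.5,
    p_sign: float = GENOME_WIDE_P_SIGN,
) -> float:
    """Cases required for the target discovery power (``theta * N``).

    Finds the smallest integer total sample size ``N`` whose power reaches
    ``target_power``, bracketing with the normal-approximation inversion of
    the NCP and finishing with integer bisection on the exact noncentral-F
    power, then returns the case share ``theta * N``.
    """
    if f_case == f_ctrl:
        raise ValueError("case and control frequencies are equal; power never exceeds alpha")
    beta, pooled = effect_from_frequencies(f_case, f_ctrl, theta)
    coef = 2.0 * theta * (1.0 - theta) * pooled * (1.0 - pooled) * beta**2
    n0 = _lambda_star(target_power, p_sign) / coef
    lo = max(5, int(n0 * 0.5))
    hi = max(lo + 1, int(math.ceil(n0 * 2.0)))
    while statistical_power(coef * hi, hi, p_sign) < target_power:
        lo, hi = hi, hi * 2
    while statistical_power(coef * lo, lo, p_sign) >= target_power and lo > 5:
        hi, lo = lo, max(5, lo // 2)
    # invariant: power(lo) < target <= power(hi)  (power increases with N)
    while hi - lo > 1:
        mid = (lo + hi) // 2
        if statistical_power(coef * mid, mid, p_sign) >= target_power:
            hi = mid
        else:
            lo = mid
    return theta * hi


@dataclass
class PowerResult:
    """Power summary for one SNP (or grid cell) at one design point."""

    snp_id: str
    lam: float
    power: float
    n_for_target: float
    target_power: float = 0.8


@dataclass
class DesignCurve:
    """Required-size curve for one study design over control mid-ages."""

    design: str
    case_mid_age: int
    table: pd.DataFrame = field(repr=False)

    def multiples(self) -> pd.Series:
        return self.table.set_index("control_mid_age")["multiple_vs_youngest"]


def _cell_frequencies(freqs: np.ndarray, cell_index: np.ndarray, n_cells: int) -> np.ndarray:
    """Mean allele frequency per grid cell (pooling SNPs sharing a cell)."""
    out = np.empty(n_cells)
    for c in range(n_cells):
        out[c] = freqs[cell_index == c].mean()
    return out


def design_curves(
    state: PopulationState,
    trace: SimulationTrace,
    spec: ArchitectureSpec,
    design: str,
    ages: np.ndarray | None = None,
    span: float = DEFAULT_SPAN,
    min_prevalence: float = DEFAULT_MIN_PREVALENCE,
    target_power: float = 0.8,
    theta: float = 0.5,
    cells: str = "reference",
    age_step: int = 1,
) -> DesignCurve:
    """Required cohort size versus mid-cohort age for one study design.

    ``design`` is ``"age_matched"`` (cases and controls share each mid-age)
    or ``"young_cases_old_controls"`` (cases frozen at the youngest
    formable age, controls progressively older).  Frequencies are tallied
    over the full case windows and unaffected pools — the large-sample
    limit of cohort sampling.  ``cells="reference"`` analyses the
    largest-effect, highest-MAF grid cell; ``cells="all"`` emits every cell.

    The curve ends where the case window or the control pool falls below
    ``min_prevalence`` of the initial population.  The reported multiple is
    relative to the youngest age-matched point, which is 1 by construction.
    """
    if design not in ("age_matched", "young_cases_old_controls"):
        raise ValueError(f"unknown design {design!r}")
    if state.genotypes is None:
        raise ValueError("design curves require the full-genotype population mode")

    counts = state.genotypes.counts
    cell_index = _fast_cell_index(spec)
    n_cells = spec.grid.n_cells
    grid_cells = spec.grid.cells()
    # reference cell: largest effect, then highest MAF
    ref_cell = max(range(n_cells), key=lambda c: (grid_cells[c][1], grid_cells[c][0]))
    wanted = range(n_cells) if cells == "all" else [ref_cell]

    case_ids, case_mid_age = form_cases(state, trace, min_prevalence, span)
    threshold = min_prevalence * state.n
    f_case_young = _cell_frequencies(
        state.genotypes.allele_frequencies(case_ids), cell_index, n_cells
    )

    if ages is None:
        ages = np.arange(case_mid_age, int(trace.ages[-1]) + 1, age_step)

    # baseline: youngest age-matched point, shared by both designs
    pool0 = np.flatnonzero(state.unaffected_alive_at(case_mid_age))
    f_ctrl_young = _cell_frequencies(
        state.genotypes.allele_frequencies(pool0), cell_index, n_cells
    )
    n_young = {
        c: cases_needed(f_case_young[c], f_ctrl_young[c], target_power, theta)
        for c in wanted
    }

    rows = []
    for age in ages:
        pool = np.flatnonzero(state.unaffected_alive_at(int(age)))
        if len(pool) < threshold:
            break
        if design == "age_matched":
            if age == case_mid_age:
                window = case_ids  # youngest point: both designs share it
            else:
                window = np.flatnonzero(
                    state.diagnosed_in_window(age - span / 2.0, age + span / 2.0)
                )
            if len(window) < threshold and age != case_mid_age:
                break
            f_case = _cell_frequencies(
                state.genotypes.allele_frequencies(window), cell_index, n_cells
            )
            case_age = int(age)
        else:
            f_case = f_case_young
            case_age = case_mid_age
        f_ctrl = _cell_frequencies(
            state.genotypes.allele_frequencies(pool), cell_index, n_cells
        )
        for c in wanted:
            try:
                n_cases = cases_needed(f_case[c], f_ctrl[c], target_power, theta)
            except ValueError:
                continue  # no frequency difference left at this age
            beta, pooled = effect_from_frequencies(f_case[c], f_ctrl[c], theta)
            total_n = n_cases / theta
            rows.append(
                {
                    "design": design,
                    "case_mid_age": case_age,
                    "control_mid_age": int(age),
                    "snp_id": f"cell{c:02d}",
                    "maf_cell": grid_cells[c][0],
                    "or_cell": grid_cells[c][1],
                    "f_case": f_case[c],
                    "f_ctrl": f_ctrl[c],
                    "beta_hat": beta,
                    "lambda": ncp(total_n, theta, pooled, beta),
                    "n_cases_80pct": n_cases,
                    "multiple_vs_youngest": n_cases / n_young[c],
                }
            )
    if not rows:
        raise ValueError("no analysable design points; pools below threshold everywhere")
    return DesignCurve(design=design, case_mid_age=case_mid_age, table=pd.DataFrame(rows))


def _fast_cell_index(spec: ArchitectureSpec) -> np.ndarray:
    """Grid-cell label per SNP via direct (maf, or) lookup."""
    cells = {
        (round(p, 9), round(r, 9)): i for i, (p, r) in enumerate(spec.grid.cells())
    }
    ors = spec.odds_ratios
    return np.array(
        [cells[(round(p, 9), round(float(r), 9))] for (p, _), r in zip(spec.per_snp, ors)]
    )
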
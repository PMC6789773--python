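"""High-level experiment drivers tying simulation, cohorts and analysis.

These functions reproduce the three study designs end to end on a
completed simulation: the per-design required-size curves live in
:func:`lodsim.power.design_curves`; here, :func:`bias_analysis` runs the
youngest-cases/older-controls association scan at 5-year control-age
increments, fits the normalized-bias regression in both modes and applies
the correction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .aging import SimulationTrace
from .architecture import ArchitectureSpec
from .association import logistic_association
from .bias import BiasFit, adjust_effect, fit_bias
from .cohorts import (
    DEFAULT_MIN_PREVALENCE,
    DEFAULT_SPAN,
    CohortSample,
    form_cases,
    sample_controls,
)
from .population import PopulationState
from .power import _fast_cell_index

__all__ = ["BiasAnalysis", "bias_analysis"]


@dataclass
class BiasAnalysis:
    """Outputs of the control-age bias experiment."""

    case_mid_age: int
    control_ages: np.ndarray
    associations: pd.DataFrame = field(repr=False)  # per SNP x control age
    d_values: np.ndarray  # mean normalized bias of the reference cell per age
    fit_best_power: BiasFit
    fit_quadratic: BiasFit
    adjusted: pd.DataFrame = field(repr=False)

    def report_frame(self) -> pd.DataFrame:
        rows = []
        for f in (self.fit_best_power, self.fit_quadratic):
            rows.append(
                {
                    "mode": f.mode,
                    "P": f.power,
                    "I0": f.intercept,
                    "S": f.slope,
                    "residual_se": f.residual_se,
                    "p_value": f.p_value,
                }
            )
        return pd.DataFrame(rows)


def bias_analysis(
    state: PopulationState,
    trace: SimulationTrace,
    spec: ArchitectureSpec,
    seed: int | np.random.Generator = 0,
    age_step: int = 5,
    span: float = DEFAULT_SPAN,
    min_prevalence: float = DEFAULT_MIN_PREVALENCE,
    snp_subset: np.ndarray | None = None,
    adjust_age: bool = False,
    beta_true_mode: str = "architecture",
) -> BiasAnalysis:
    """Characterize the effect-size bias of older-control designs.

    Cases are frozen at the youngest formable mid-cohort age; at each
    control mid-age (5-year steps by default) an equal number of controls
    is sampled and every SNP in ``snp_subset`` (default: the largest- and
    smallest-effect grid cells) is tested by logistic regression.  The
    reference normalized bias ``D(t)`` is the mean over SNPs of the
    largest-effect, highest-MAF cell.  ``beta_true_mode`` chooses the truth
    against which bias is measured: the architecture's ``ln(OR)``
    (``"architecture"``, default) or the youngest age-matched estimate
    (``"youngest_estimate"``).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    case_ids, age_y = form_cases(state, trace, min_prevalence, span)

    cell_index = _fast_cell_index(spec)
    effects = spec.effects
    grid_cells = spec.grid.cells()
    ref_cell = max(
        range(len(grid_cells)), key=lambda c: (grid_cells[c][1], grid_cells[c][0])
    )
    if snp_subset is None:
        min_cell = min(
            range(len(grid_cells)), key=lambda c: (grid_cells[c][1], -grid_cells[c][0])
        )
        snp_subset = np.flatnonzero(np.isin(cell_index, [ref_cell, min_cell]))
    snp_subset = np.asarray(snp_subset)
    ref_snps = np.flatnonzero(cell_index == ref_cell)
    ref_in_subset = np.isin(snp_subset, ref_snps)
    if not ref_in_subset.any():
        raise ValueError("snp_subset contains no SNP from the reference (largest-effect) cell")

    ages_ind = np.where(state.age_at_diagnosis >= 0, state.age_at_diagnosis, 0).astype(float)

    threshold = min_prevalence * state.n
    control_ages, frames, d_vals = [], [], []
    t = age_y
    max_age = int(trace.ages[-1])
    while t <= max_age:
        pool = int(state.unaffected_alive_at(t).sum())
        if pool < max(len(case_ids), threshold):
            break
        controls = sample_controls(state, t, len(case_ids), rng)
        cohort = CohortSample(
            case_ids=case_ids,
            control_ids=controls,
            case_mid_age=age_y,
            control_mid_age=t,
            span=span,
        )
        ages_ind[controls] = t
        res = logistic_association(
            cohort, state.genotypes, ages=ages_ind, adjust_age=adjust_age, snp_ids=snp_subset
        )
        res["snp_index"] = snp_subset
        res["control_mid_age"] = t
        frames.append(res)
        control_ages.append(t)
        t += age_step
    if len(control_ages) < 4:
        raise ValueError(
            f"only {len(control_ages)} control ages available; bias regression needs >= 4"
        )

    assoc = pd.concat(frames, ignore_index=True)

    if beta_true_mode == "architecture":
        beta_true = {int(k): float(effects[k]) for k in snp_subset}
    elif beta_true_mode == "youngest_estimate":
        first = assoc[assoc["control_mid_age"] == control_ages[0]]
        beta_true = dict(zip(first["snp_index"].astype(int), first["beta"]))
    else:
        raise ValueError(f"unknown beta_true_mode {beta_true_mode!r}")

    assoc["beta_true"] = assoc["snp_index"].map(beta_true)
    assoc["d"] = (assoc["beta"] - assoc["beta_true"]) / assoc["beta_true"]

    ref_mask = assoc["snp_index"].isin(ref_snps)
    d_per_age = (
        assoc[ref_mask].groupby("control_mid_age")["d"].mean().reindex(control_ages)
    )
    # ages where every reference-cell fit failed carry no information
    usable = d_per_age.notna().to_numpy()
    if usable.sum() < 4:
        raise ValueError("fewer than 4 control ages with usable reference-cell estimates")
    d_vals = d_per_age.to_numpy()[usable]
    fit_ages = np.array(control_ages, float)[usable]

    fit_bp = fit_bias(d_vals, fit_ages, age_y, mode="best_power")
    fit_q = fit_bias(d_vals, fit_ages, age_y, mode="quadratic")

    def _safe_adjust(b: float, t_: float) -> float:
        if not np.isfinite(b):
            return np.nan
        try:
            return adjust_effect(b, t_, fit_bp)
        except ValueError:  # degenerate fit predicting 1 + D(t) <= 0
            return np.nan

    assoc["beta_adjusted"] = [
        _safe_adjust(b, t_) for b, t_ in zip(assoc["beta"], assoc["control_mid_age"])
    ]

    adjusted = assoc[
        ["snp_id", "control_mid_age", "beta", "se", "p_value", "beta_true", "d", "beta_adjusted"]
    ].rename(columns={"beta": "beta_raw", "se": "se_raw", "p_value": "p"})

    return BiasAnalysis(
        case_mid_age=age_y,
        control_ages=fit_ages.astype(int),
        associations=assoc,
        d_values=d_vals,
        fit_best_power=fit_bp,
        fit_quadratic=fit_q,
        adjusted=adjusted,
    )
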
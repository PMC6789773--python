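"""Case and control cohort formation from a completed simulation.

The youngest cases cohort freezes the earliest diagnosed individuals once
cumulative incidence crosses a minimum prevalence (0.25% by default) — the
smallest pool judged workable for a GWAS.  Controls are as-yet-unaffected
individuals sampled at a chosen mid-cohort age.  All cohorts span 10 years
of age by default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .aging import SimulationTrace
from .population import PopulationState

__all__ = [
    "DEFAULT_MIN_PREVALENCE",
    "DEFAULT_SPAN",
    "CohortSample",
    "form_cases",
    "sample_controls",
    "effect_from_frequencies",
]

DEFAULT_MIN_PREVALENCE = 0.0025
DEFAULT_SPAN = 10.0


@dataclass
class CohortSample:
    """A case set and a control set with their mid-cohort ages.

    ``f_case`` / ``f_ctrl`` are per-SNP risk-allele frequencies tallied over
    the two sets.
    """

    case_ids: np.ndarray
    control_ids: np.ndarray
    case_mid_age: float
    control_mid_age: float
    span: float = DEFAULT_SPAN
    f_case: np.ndarray | None = None
    f_ctrl: np.ndarray | None = None

    def __post_init__(self) -> None:
        if np.intersect1d(self.case_ids, self.control_ids).size:
            raise ValueError("case and control sets overlap")

    @property
    def n_cases(self) -> int:
        return len(self.case_ids)

    @property
    def n_controls(self) -> int:
        return len(self.control_ids)

    def tally_frequencies(self, state: PopulationState) -> "CohortSample":
        if state.genotypes is None:
            raise ValueError("population has no genotype store; frequencies unavailable")
        self.f_case = state.genotypes.allele_frequencies(self.case_ids)
        self.f_ctrl = state.genotypes.allele_frequencies(self.control_ids)
        return self


def form_cases(
    state: PopulationState,
    trace: SimulationTrace,
    min_prevalence: float = DEFAULT_MIN_PREVALENCE,
    span: float = DEFAULT_SPAN,
) -> tuple[np.ndarray, int]:
    """Freeze the youngest cases cohort.

    Returns ``(case_ids, case_mid_age)`` where ``case_mid_age`` is the first
    age at which cumulative incidence reaches ``min_prevalence`` and the
    cases are everyone diagnosed in the ``span`` years ending there — the
    earliest diagnosed individuals.  The set is kept fixed afterwards.
    """
    cum = trace.cumulative_incidence_curve
    hit = np.flatnonzero(cum >= min_prevalence)
    if len(hit) == 0:
        raise ValueError(
            f"cumulative incidence never reached {min_prevalence:g}; "
            f"maximum achieved was {cum.max():g}"
        )
    mid_age = int(trace.ages[hit[0]])
    # the `span` yearly cohorts ending at the crossing age: (mid - span, mid]
    ids = np.flatnonzero(state.diagnosed_in_window(mid_age - span + 1, mid_age + 1))
    return ids, mid_age


def sample_controls(
    state: PopulationState,
    mid_age: int,
    n: int,
    seed: int | np.random.Generator,
) -> np.ndarray:
    """Uniform sample of ``n`` as-yet-unaffected, alive individuals at ``mid_age``."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    pool = np.flatnonzero(state.unaffected_alive_at(mid_age))
    if n > len(pool):
        raise ValueError(
            f"requested {n} controls at age {mid_age} but only {len(pool)} "
            "unaffected individuals are alive"
        )
    if n == len(pool):
        return pool.copy()
    return np.sort(rng.choice(pool, size=n, replace=False))


def effect_from_frequencies(
    f_case: float | np.ndarray, f_ctrl: float | np.ndarray, theta: float = 0.5
):
    """Allelic log odds ratio and pooled frequency from cohort frequencies.

    ``beta_hat = ln[f_case (1 - f_ctrl) / (f_ctrl (1 - f_case))]`` — the 2x2
    allele-table log-OR — and ``f_pooled = theta f_case + (1-theta) f_ctrl``.
    """
    f_case = np.asarray(f_case, dtype=np.float64)
    f_ctrl = np.asarray(f_ctrl, dtype=np.float64)
    if np.any((f_case <= 0) | (f_case >= 1)) or np.any((f_ctrl <= 0) | (f_ctrl >= 1)):
        raise ValueError("allele frequencies must lie strictly inside (0, 1)")
    if not 0.0 < theta < 1.0:
        raise ValueError("case fraction theta must lie in (0, 1)")
    beta = np.log(f_case * (1.0 - f_ctrl)) - np.log(f_ctrl * (1.0 - f_case))
    pooled = theta * f_case + (1.0 - theta) * f_ctrl
    if beta.ndim == 0:
        return float(beta), float(pooled)
    return beta, pooled
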
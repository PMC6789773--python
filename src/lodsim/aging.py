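"""Forward-time aging of a birth cohort under proportional-hazards incidence.

Each year of age ``t``:

1. the expected number of new diagnoses is set by the baseline incidence,
   ``I0(t) * n_unaffected``, carrying the fractional remainder to the next
   year (a binomial draw is available as an alternative);
2. that many individuals are removed from the unaffected pool *without*
   replacement, with selection weight equal to each individual's Cox hazard
   multiplier ``exp(beta_i)`` — higher-PRS individuals fall ill
   proportionately earlier;
3. actuarial mortality ``q_t`` is applied to everyone alive, independently
   of PRS and disease status.

The trace records, per year, counts and mean scores plus per-SNP risk-allele
frequencies among the unaffected-alive pool and among everyone diagnosed to
date; these are maintained incrementally, so a full 120-year run touches
each genotype row only when its owner changes state.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .incidence import MAX_AGE, IncidenceModel
from .mortality import MortalityTable
from .population import PopulationState

__all__ = ["SimulationTrace", "YearRecord", "simulate_year", "run_simulation", "cumulative_incidence"]

logger = logging.getLogger(__name__)

_WEIGHT_MODES = ("exp", "linear", "uniform")


@dataclass
class YearRecord:
    """What happened during one simulated year of age."""

    age: int
    newly_diagnosed: np.ndarray  # individual indices
    newly_dead: np.ndarray
    n_unaffected_alive: int  # after the year's events
    n_diagnosed_total: int
    n_dead_total: int
    mean_prs_unaffected: float
    mean_prs_newly_diagnosed: float
    carry: float


def _weights_log(prs: np.ndarray, mode: str) -> np.ndarray:
    """Log selection weights for the diagnosis draw."""
    if mode == "exp":
        return prs
    if mode == "uniform":
        return np.zeros_like(prs)
    if mode == "linear":
        with np.errstate(divide="ignore"):
            return np.log(np.maximum(prs, 0.0))
    raise ValueError(f"unknown weight mode {mode!r}; expected one of {_WEIGHT_MODES}")


def _weighted_draw(log_w: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """Draw k items without replacement, probability proportional to weight.

    Gumbel top-k: adding independent Gumbel noise to the log weights and
    taking the k largest keys reproduces successive sampling without
    replacement with probabilities proportional to the weights.
    """
    keys = log_w + rng.gumbel(size=log_w.shape)
    if k >= len(keys):
        return np.arange(len(keys))
    part = np.argpartition(keys, -k)[-k:]
    return part


def simulate_year(
    state: PopulationState,
    incidence: IncidenceModel,
    mortality: MortalityTable,
    rng: np.random.Generator,
    carry: float = 0.0,
    weight_mode: str = "exp",
    binomial_draw: bool = False,
) -> YearRecord:
    """Advance the population by one year in place; return the year's record."""
    t = state.current_age
    if t > MAX_AGE:
        raise ValueError(f"population already at maximum age {MAX_AGE}")
    unaff_idx = np.flatnonzero(state.unaffected_alive)
    hazard = incidence.hazard(t)

    # --- diagnoses -----------------------------------------------------
    if binomial_draw:
        k = int(rng.binomial(len(unaff_idx), hazard))
    else:
        expected = hazard * len(unaff_idx) + carry
        k = int(np.floor(expected))
        carry = expected - k
    if k > len(unaff_idx):
        warnings.warn(
            f"age {t}: requested {k} diagnoses but only {len(unaff_idx)} unaffected remain",
            stacklevel=2,
        )
        k = len(unaff_idx)
    if k > 0:
        chosen = unaff_idx[_weighted_draw(_weights_log(state.prs[unaff_idx], weight_mode), k, rng)]
        state.age_at_diagnosis[chosen] = t
    else:
        chosen = np.array([], dtype=np.int64)

    # --- mortality (independent of PRS and disease status) -------------
    alive_idx = np.flatnonzero(state.alive)
    q = mortality.death_probability(t)
    dying = alive_idx[rng.random(len(alive_idx)) < q] if q > 0 else np.array([], dtype=np.int64)
    state.age_at_death[dying] = t

    state.current_age = t + 1

    unaff = state.unaffected_alive
    new_prs = state.prs[chosen]
    return YearRecord(
        age=t,
        newly_diagnosed=chosen,
        newly_dead=dying,
        n_unaffected_alive=int(unaff.sum()),
        n_diagnosed_total=int(state.diagnosed.sum()),
        n_dead_total=int((~state.alive).sum()),
        mean_prs_unaffected=float(state.prs[unaff].mean()) if unaff.any() else float("nan"),
        mean_prs_newly_diagnosed=float(new_prs.mean()) if len(new_prs) else float("nan"),
        carry=carry,
    )


@dataclass
class SimulationTrace:
    """Per-age summaries of a completed run.

    ``freq_unaffected[t]`` / ``freq_diagnosed[t]`` are per-SNP risk-allele
    frequencies among the unaffected-alive pool at the end of year ``t`` and
    among everyone diagnosed up to and including year ``t`` (NaN while the
    respective pool is empty).
    """

    n_initial: int
    ages: np.ndarray
    n_newly_diagnosed: np.ndarray
    n_unaffected_alive: np.ndarray
    n_diagnosed_total: np.ndarray
    n_dead_total: np.ndarray
    mean_prs_unaffected: np.ndarray
    mean_prs_newly_diagnosed: np.ndarray
    freq_unaffected: np.ndarray | None = None  # (n_ages, n_snps)
    freq_diagnosed: np.ndarray | None = None

    @property
    def cumulative_incidence_curve(self) -> np.ndarray:
        return self.n_diagnosed_total / self.n_initial

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "age": self.ages,
                "n_newly_diagnosed": self.n_newly_diagnosed,
                "n_unaffected_alive": self.n_unaffected_alive,
                "n_diagnosed_total": self.n_diagnosed_total,
                "n_dead_total": self.n_dead_total,
                "cumulative_incidence": self.cumulative_incidence_curve,
                "mean_prs_unaffected": self.mean_prs_unaffected,
                "mean_prs_newly_diagnosed": self.mean_prs_newly_diagnosed,
            }
        )

    def allele_frequency_frame(self, which: str = "unaffected") -> pd.DataFrame:
        arr = self.freq_unaffected if which == "unaffected" else self.freq_diagnosed
        if arr is None:
            raise ValueError("per-SNP frequencies were not recorded for this run")
        cols = [f"snp{i:05d}" for i in range(arr.shape[1])]
        out = pd.DataFrame(arr, columns=cols)
        out.insert(0, "age", self.ages)
        return out


def cumulative_incidence(trace: SimulationTrace, age: int) -> float:
    """Fraction of the initial population diagnosed by the end of year ``age``."""
    idx = np.flatnonzero(trace.ages == age)
    if len(idx) == 0:
        raise ValueError(f"age {age} outside the simulated range {trace.ages[0]}..{trace.ages[-1]}")
    return float(trace.cumulative_incidence_curve[idx[0]])


def run_simulation(
    population: PopulationState,
    incidence: IncidenceModel,
    mortality: MortalityTable,
    max_age: int = MAX_AGE,
    seed: int | np.random.Generator = 0,
    weight_mode: str = "exp",
    binomial_draw: bool = False,
    track_frequencies: bool = True,
) -> SimulationTrace:
    """Run the yearly loop from the population's current age to ``max_age``.

    Mutates ``population`` in place (diagnosis/death ages, current age) and
    returns the trace.  At every age the conservation invariant
    ``unaffected + diagnosed + dead == n`` holds by construction of the
    status encoding.
    """
    if weight_mode not in _WEIGHT_MODES:
        raise ValueError(f"unknown weight mode {weight_mode!r}; expected one of {_WEIGHT_MODES}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = population.n
    track = track_frequencies and population.genotypes is not None
    counts = population.genotypes.counts if track else None

    ages = np.arange(population.current_age, max_age + 1)
    n_ages = len(ages)
    rec_new = np.zeros(n_ages, dtype=np.int64)
    rec_unaff = np.zeros(n_ages, dtype=np.int64)
    rec_diag = np.zeros(n_ages, dtype=np.int64)
    rec_dead = np.zeros(n_ages, dtype=np.int64)
    rec_mean_u = np.full(n_ages, np.nan)
    rec_mean_d = np.full(n_ages, np.nan)
    freq_u = np.full((n_ages, counts.shape[1]), np.nan) if track else None
    freq_d = np.full((n_ages, counts.shape[1]), np.nan) if track else None

    if track:
        # running risk-allele counts (sum of dosages) per SNP
        unaff_mask = population.unaffected_alive
        sum_unaff = counts[unaff_mask].sum(axis=0, dtype=np.float64)
        n_unaff_alive = int(unaff_mask.sum())
        diag_mask = population.diagnosed
        sum_diag = counts[diag_mask].sum(axis=0, dtype=np.float64)
        n_diag = int(diag_mask.sum())

    carry = 0.0
    for i, t in enumerate(ages):
        was_unaffected = population.unaffected_alive  # needed to classify deaths
        rec = simulate_year(
            population,
            incidence,
            mortality,
            rng,
            carry=carry,
            weight_mode=weight_mode,
            binomial_draw=binomial_draw,
        )
        carry = rec.carry
        rec_new[i] = len(rec.newly_diagnosed)
        rec_unaff[i] = rec.n_unaffected_alive
        rec_diag[i] = rec.n_diagnosed_total
        rec_dead[i] = rec.n_dead_total
        rec_mean_u[i] = rec.mean_prs_unaffected
        rec_mean_d[i] = rec.mean_prs_newly_diagnosed

        if track:
            dx = rec.newly_diagnosed
            if len(dx):
                moved = counts[dx].sum(axis=0, dtype=np.float64)
                sum_unaff -= moved
                sum_diag += moved
                n_diag += len(dx)
            n_unaff_alive -= len(dx)
            # deaths from the (pre-year) unaffected pool, excluding this
            # year's diagnoses, leave the unaffected-alive tally
            dead_unaff = rec.newly_dead[
                was_unaffected[rec.newly_dead] & (population.age_at_diagnosis[rec.newly_dead] != t)
            ]
            if len(dead_unaff):
                sum_unaff -= counts[dead_unaff].sum(axis=0, dtype=np.float64)
            n_unaff_alive -= len(dead_unaff)
            if n_unaff_alive > 0:
                freq_u[i] = sum_unaff / (2.0 * n_unaff_alive)
            if n_diag > 0:
                freq_d[i] = sum_diag / (2.0 * n_diag)

        assert rec_unaff[i] + rec_diag[i] - int(
            (population.diagnosed & ~population.alive).sum()
        ) + rec_dead[i] == n  # unaffected + diagnosed-alive + dead
        logger.debug(
            "age %3d: %6d newly diagnosed, %8d unaffected alive, %8d dead",
            t, rec_new[i], rec_unaff[i], rec_dead[i],
        )

    return SimulationTrace(
        n_initial=n,
        ages=ages,
        n_newly_diagnosed=rec_new,
        n_unaffected_alive=rec_unaff,
        n_diagnosed_total=rec_diag,
        n_dead_total=rec_dead,
        mean_prs_unaffected=rec_mean_u,
        mean_prs_newly_diagnosed=rec_mean_d,
        freq_unaffected=freq_u,
        freq_diagnosed=freq_d,
    )
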
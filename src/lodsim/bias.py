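"""Control-age effect-size bias: characterization and correction.

With cases frozen at the youngest formable age and controls taken
progressively older, single-SNP effect-size estimates inflate, because the
aging unaffected pool is depleted of risk alleles.  The normalized bias

    D(t) = (beta(t) - beta_true) / beta_true

grows with control mid-cohort age ``t`` and is summarised by the power-law
regression

    D(t) = I0 + S (t - age_y)^P

with intercept ``I0``, slope ``S``, the youngest case mid-cohort age
``age_y``, and exponent ``P`` found by a grid search with local refinement
(or fixed at 2 for the quadratic rule).  Inverting the fit corrects raw
estimates: ``beta_adj = beta_obs / (1 + D(t))``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["BiasFit", "normalized_bias", "fit_bias", "adjust_effect"]


def normalized_bias(beta_t: float | np.ndarray, beta_true: float) -> float | np.ndarray:
    """Relative inflation ``(beta_t - beta_true) / beta_true``."""
    if beta_true == 0:
        raise ValueError("true effect size must be nonzero")
    out = (np.asarray(beta_t, dtype=np.float64) - beta_true) / beta_true
    return float(out) if out.ndim == 0 else out


@dataclass
class BiasFit:
    """Fitted bias-versus-control-age regression."""

    intercept: float
    slope: float
    power: float
    age_y: float
    residual_se: float
    p_value: float
    mode: str  # "best_power" or "quadratic"
    identifiable: bool = True

    def predict(self, t: float | np.ndarray) -> float | np.ndarray:
        """Predicted normalized bias D(t)."""
        dt = np.asarray(t, dtype=np.float64) - self.age_y
        if np.any(dt < 0):
            raise ValueError("control age below the youngest case age")
        out = self.intercept + self.slope * dt**self.power
        return float(out) if out.ndim == 0 else out


def _linfit(x: np.ndarray, d: np.ndarray) -> tuple[float, float, float, float]:
    """OLS of d on x; returns (intercept, slope, residual SE, slope p-value)."""
    n = len(x)
    A = np.column_stack([np.ones(n), x])
    coef, *_ = np.linalg.lstsq(A, d, rcond=None)
    resid = d - A @ coef
    dof = n - 2
    rse = float(np.sqrt(resid @ resid / dof))
    sxx = float(np.sum((x - x.mean()) ** 2))
    if sxx == 0 or rse == 0:
        p = 0.0 if rse == 0 else 1.0
    else:
        tstat = coef[1] / (rse / np.sqrt(sxx))
        p = float(2.0 * stats.t.sf(abs(tstat), dof))
    return float(coef[0]), float(coef[1]), rse, p


def fit_bias(
    d_values: np.ndarray,
    ages: np.ndarray,
    age_y: float,
    mode: str = "best_power",
    power_grid: np.ndarray | None = None,
) -> BiasFit:
    """Fit ``D(t) = I0 + S (t - age_y)^P`` to observed bias values.

    ``best_power`` mode searches ``P`` over a grid (default 0.5..5.0 in
    steps of 0.1) minimizing the residual standard error of the linear fit
    of ``D`` on ``(t - age_y)^P``, then refines locally at 0.01 resolution;
    ``quadratic`` fixes ``P = 2``.  Needs at least 4 control ages; all ages
    must be at or above ``age_y`` (only the first may equal it).
    """
    d = np.asarray(d_values, dtype=np.float64)
    t = np.asarray(ages, dtype=np.float64)
    if len(d) != len(t):
        raise ValueError("d_values and ages must have equal length")
    if len(d) < 4:
        raise ValueError(f"bias regression needs at least 4 control ages, got {len(d)}")
    if np.any(t < age_y):
        raise ValueError("all control ages must be >= the youngest case age")
    dt = t - age_y

    if np.allclose(d, d[0]):
        return BiasFit(
            intercept=float(d[0]), slope=0.0,
            power=2.0 if mode == "quadratic" else float("nan"),
            age_y=age_y, residual_se=0.0, p_value=1.0, mode=mode,
            identifiable=(mode == "quadratic"),
        )

    def fit_at(p: float) -> tuple[float, float, float, float]:
        return _linfit(dt**p, d)

    if mode == "quadratic":
        i0, s, rse, pv = fit_at(2.0)
        return BiasFit(i0, s, 2.0, age_y, rse, pv, mode)
    if mode != "best_power":
        raise ValueError(f"unknown mode {mode!r}")

    # rounding keeps P = 2 exactly on the grid, so the quadratic rule is
    # always a candidate the best-power search can match or beat
    grid = power_grid if power_grid is not None else np.round(np.arange(0.5, 5.0 + 1e-9, 0.1), 10)
    results = {float(p): fit_at(float(p)) for p in grid}
    best_p = min(results, key=lambda p: results[p][2])
    # local refinement at finer resolution around the grid optimum
    step = float(grid[1] - grid[0]) if len(grid) > 1 else 0.1
    fine = np.arange(max(best_p - step, 1e-6), best_p + step + 1e-9, step / 10.0)
    for p in fine:
        r = fit_at(float(p))
        if r[2] < results[best_p][2]:
            results[float(p)] = r
            best_p = float(p)
    i0, s, rse, pv = results[best_p]
    return BiasFit(i0, s, best_p, age_y, rse, pv, "best_power")


def adjust_effect(beta_obs: float, t: float, fit: BiasFit) -> float:
    """Correct a raw estimate from an older-controls design.

    ``beta_adj = beta_obs / (1 + D(t))`` with ``D(t)`` from the fitted
    regression; at ``t = age_y`` with zero intercept the estimate is
    returned unchanged.
    """
    if t < fit.age_y:
        raise ValueError("control age below the youngest case age")
    d_hat = fit.predict(t)
    denom = 1.0 + d_hat
    if denom <= 0:
        raise ValueError(f"predicted bias {d_hat:.4f} at age {t} makes 1 + D(t) non-positive")
    return beta_obs / denom
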
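"""Yearly baseline incidence models for late-onset diseases.

The baseline hazard ``I0(t)`` gives the probability that an average-risk
unaffected individual is diagnosed during year of age ``t``.  Two parametric
families are provided:

* ``logistic_incidence`` — an S-shaped rise to a plateau, fitting diseases
  whose yearly incidence keeps rising or saturates at old age (dementia,
  diabetes, cardiovascular disease);
* ``capped_exponential_incidence`` — exponential growth from an onset age,
  truncated at a ceiling, fitting the common cancers.

The per-disease default parameters bundled here are approximations chosen
to land in the right ballpark for each disease's lifetime risk and maximum
yearly incidence; they are not fits to registry data and carry no claim of
epidemiological accuracy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np

__all__ = [
    "MAX_AGE",
    "IncidenceModel",
    "logistic_incidence",
    "capped_exponential_incidence",
    "lod_preset",
    "LOD_PRESETS",
    "synthetic_high_incidence",
]

#: Oldest modelled year of age (inclusive).
MAX_AGE = 119


@dataclass(frozen=True)
class IncidenceModel:
    """A deterministic yearly baseline hazard curve ``I0(t)``."""

    name: str
    hazard_fn: Callable[[float], float]
    parameters: dict = field(default_factory=dict)

    def hazard(self, age: float) -> float:
        """Baseline probability of diagnosis during year ``age``."""
        h = float(self.hazard_fn(age))
        if not 0.0 <= h <= 1.0:
            raise ValueError(f"{self.name}: hazard {h} at age {age} outside [0, 1]")
        return h

    def hazards(self, max_age: int = MAX_AGE) -> np.ndarray:
        return np.array([self.hazard(t) for t in range(max_age + 1)])


def logistic_incidence(name: str, cap: float, steepness: float, midpoint: float) -> IncidenceModel:
    """S-shaped hazard ``cap / (1 + exp(-steepness (t - midpoint)))``."""
    if not 0.0 < cap <= 1.0:
        raise ValueError("cap must lie in (0, 1]")

    def fn(t: float) -> float:
        return cap / (1.0 + math.exp(-steepness * (t - midpoint)))

    return IncidenceModel(
        name, fn, {"family": "logistic", "cap": cap, "steepness": steepness, "midpoint": midpoint}
    )


def capped_exponential_incidence(
    name: str, base: float, rate: float, onset: float, cap: float
) -> IncidenceModel:
    """Hazard 0 before ``onset``, then ``base * exp(rate (t - onset))`` up to ``cap``."""
    if not 0.0 < cap <= 1.0:
        raise ValueError("cap must lie in (0, 1]")

    def fn(t: float) -> float:
        if t < onset:
            return 0.0
        return min(base * math.exp(rate * (t - onset)), cap)

    return IncidenceModel(
        name,
        fn,
        {"family": "capped_exponential", "base": base, "rate": rate, "onset": onset, "cap": cap},
    )


# Per-disease approximate parameters.  ``h2`` is the liability heritability
# used when building the matching architecture.
_PRESETS: dict[str, dict] = {
    "alzheimers": dict(h2=0.795, family="logistic", cap=0.30, steepness=0.22, midpoint=95.0),
    "t2d": dict(h2=0.69, family="logistic", cap=0.025, steepness=0.13, midpoint=50.0),
    "stroke": dict(h2=0.41, family="logistic", cap=0.044, steepness=0.11, midpoint=85.0),
    "cad": dict(h2=0.55, family="logistic", cap=0.036, steepness=0.10, midpoint=78.0),
    "breast_cancer": dict(
        h2=0.31, family="capped_exponential", base=1e-4, rate=0.065, onset=25.0, cap=0.0045
    ),
    "prostate_cancer": dict(
        h2=0.57, family="capped_exponential", base=2e-5, rate=0.13, onset=35.0, cap=0.008
    ),
    "colorectal_cancer": dict(
        h2=0.40, family="capped_exponential", base=3e-5, rate=0.09, onset=30.0, cap=0.005
    ),
    "lung_cancer": dict(
        h2=0.095, family="capped_exponential", base=2e-5, rate=0.11, onset=35.0, cap=0.005
    ),
}

LOD_PRESETS = tuple(_PRESETS)


def lod_preset(name: str) -> tuple[IncidenceModel, float]:
    """Bundled approximate incidence model and heritability for a disease.

    Returns ``(model, h2)``.  Recognised names: ``alzheimers``, ``t2d``,
    ``stroke``, ``cad``, ``breast_cancer``, ``prostate_cancer``,
    ``colorectal_cancer``, ``lung_cancer``.
    """
    try:
        p = _PRESETS[name]
    except KeyError:
        raise KeyError(f"unknown disease preset {name!r}; known: {sorted(_PRESETS)}") from None
    if p["family"] == "logistic":
        model = logistic_incidence(name, p["cap"], p["steepness"], p["midpoint"])
    else:
        model = capped_exponential_incidence(name, p["base"], p["rate"], p["onset"], p["cap"])
    return model, p["h2"]


def synthetic_high_incidence() -> IncidenceModel:
    """A stylised high-incidence disease for studies of cohort-design effects.

    Logistic hazard plateauing at 4% per year from late middle age onward —
    the cumulative-incidence regime (stroke/CAD-like) where age structure
    matters most for GWAS cohort design.
    """
    return logistic_incidence("synthetic_high_incidence", cap=0.04, steepness=0.20, midpoint=55.0)
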
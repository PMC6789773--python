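"""Actuarial mortality: yearly death probabilities by age.

A :class:`MortalityTable` holds ``q_x``, the probability of dying during
year of age ``x``, for ages 0..119.  Tables load from actuarial-life-table
CSV files (columns ``age`` and ``death_probability``, optionally one table
per sex); a synthetic Gompertz-Makeham generator is bundled so no external
data file is required.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .incidence import MAX_AGE

__all__ = ["MortalityTable", "gompertz_makeham_table"]


@dataclass(frozen=True)
class MortalityTable:
    """Yearly death probability ``q_x`` for ages 0..119."""

    qx: np.ndarray
    name: str = "mortality"

    def __post_init__(self) -> None:
        qx = np.asarray(self.qx, dtype=np.float64)
        if qx.shape != (MAX_AGE + 1,):
            raise ValueError(f"mortality table must cover ages 0..{MAX_AGE}, got {qx.shape}")
        if np.any((qx < 0) | (qx > 1)):
            raise ValueError("death probabilities must lie in [0, 1]")
        object.__setattr__(self, "qx", qx)

    def death_probability(self, age: int) -> float:
        if not 0 <= age <= MAX_AGE:
            raise ValueError(f"age {age} outside 0..{MAX_AGE}")
        return float(self.qx[age])

    def survivorship(self) -> np.ndarray:
        """Fraction surviving to the start of each year of age (l_x / l_0)."""
        return np.concatenate([[1.0], np.cumprod(1.0 - self.qx)[:-1]])

    @classmethod
    def from_csv(cls, path, sex: str | None = None) -> "MortalityTable":
        """Load from a CSV with columns ``age`` and ``death_probability``.

        Sex-specific layouts use ``death_probability_<sex>`` columns; pass
        ``sex`` to pick one, otherwise the unisex column is required.
        """
        df = pd.read_csv(path, comment="#")
        df.columns = [c.strip().lower() for c in df.columns]
        if "age" not in df.columns:
            raise ValueError(f"{path}: missing required column 'age'")
        col = "death_probability" if sex is None else f"death_probability_{sex.lower()}"
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
        df = df.sort_values("age")
        ages = df["age"].to_numpy()
        if not np.array_equal(ages, np.arange(MAX_AGE + 1)):
            raise ValueError(f"{path}: ages must be exactly 0..{MAX_AGE}")
        return cls(qx=df[col].to_numpy(float), name=str(path))

    def to_csv(self, path) -> None:
        pd.DataFrame({"age": np.arange(MAX_AGE + 1), "death_probability": self.qx}).to_csv(
            path, index=False
        )


def gompertz_makeham_table(
    makeham: float = 5e-4, scale: float = 3.5e-5, shape: float = 0.09
) -> MortalityTable:
    """Synthetic human-like mortality, ``q_x = A + B exp(G x)`` capped at 1.

    Defaults give roughly 57% survivorship to 80 and a few percent to 100,
    in the vicinity of a contemporary US unisex life table.
    """
    ages = np.arange(MAX_AGE + 1)
    qx = np.minimum(makeham + scale * np.exp(shape * ages), 1.0)
    return MortalityTable(qx=qx, name="gompertz_makeham_synthetic")
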
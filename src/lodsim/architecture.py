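"""Common low-effect polygenic architecture: a MAF x odds-ratio grid.

A late-onset disease is modelled as driven by many independent common SNPs
of small effect.  The architecture is a cross-product grid of minor-allele
frequencies and per-allele odds ratios; each SNP is assigned one (MAF, OR)
cell.  All closed-form population-genetic summaries live here:

* per-SNP variance of the allelic log-odds contribution,
  ``var_k = 2 p_k (1 - p_k) ln^2(OR_k)``;
* liability-scale heritability ``h^2 = var / (var + pi^2/3)``, with
  ``pi^2/3`` the variance of the standard logistic distribution;
* the population mean polygenic risk score ``2 sum_k p_k ln(OR_k)``;
* the number of SNPs a grid needs to reach a target heritability.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "LOGISTIC_RESIDUAL_VARIANCE",
    "DEFAULT_MAF_VALUES",
    "DEFAULT_OR_VALUES",
    "AlleleGrid",
    "ArchitectureSpec",
    "snp_variance",
    "heritability_from_variance",
    "variance_for_heritability",
    "snps_for_heritability",
    "mean_prs",
    "build_architecture",
]

#: Variance of the standard logistic distribution, the residual variance of
#: the liability threshold model on the log-odds scale.
LOGISTIC_RESIDUAL_VARIANCE = math.pi**2 / 3.0

#: Default minor (risk) allele frequencies of the common low-effect grid.
DEFAULT_MAF_VALUES = (0.073, 0.180, 0.286, 0.393, 0.500)

#: Default per-allele odds ratios of the common low-effect grid.
DEFAULT_OR_VALUES = (1.15, 1.125, 1.10, 1.075, 1.05)


@dataclass(frozen=True)
class AlleleGrid:
    """A grid of (MAF, OR) cells with sampling proportions.

    By default the grid is the full cross product of ``maf_values`` and
    ``or_values`` in equal proportions (25 cells for the default lists).
    """

    maf_values: tuple[float, ...] = DEFAULT_MAF_VALUES
    or_values: tuple[float, ...] = DEFAULT_OR_VALUES
    proportions: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "maf_values", tuple(float(p) for p in self.maf_values))
        object.__setattr__(self, "or_values", tuple(float(r) for r in self.or_values))
        if any(not (0.0 < p <= 0.5) for p in self.maf_values):
            raise ValueError("all minor allele frequencies must lie in (0, 0.5]")
        if any(r < 1.0 for r in self.or_values):
            raise ValueError("all odds ratios must be >= 1")
        if self.proportions is None:
            object.__setattr__(
                self, "proportions", tuple([1.0 / self.n_cells] * self.n_cells)
            )
        else:
            props = tuple(float(w) for w in self.proportions)
            if len(props) != self.n_cells:
                raise ValueError(
                    f"proportions has length {len(props)}, expected {self.n_cells}"
                )
            if any(w < 0 for w in props) or not math.isclose(
                sum(props), 1.0, abs_tol=1e-9
            ):
                raise ValueError("proportions must be non-negative and sum to 1")
            object.__setattr__(self, "proportions", props)

    @property
    def n_cells(self) -> int:
        return len(self.maf_values) * len(self.or_values)

    def cells(self) -> list[tuple[float, float]]:
        """All (maf, or) pairs, MAF-major order."""
        return [(p, r) for p in self.maf_values for r in self.or_values]

    def mean_snp_variance(self) -> float:
        """Proportion-weighted mean per-SNP variance over the grid cells."""
        cells = self.cells()
        return float(
            sum(w * snp_variance(p, r) for w, (p, r) in zip(self.proportions, cells))
        )

    def to_dict(self) -> dict:
        return {
            "maf_values": list(self.maf_values),
            "or_values": list(self.or_values),
            "proportions": list(self.proportions),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AlleleGrid":
        return cls(
            maf_values=tuple(d["maf_values"]),
            or_values=tuple(d["or_values"]),
            proportions=tuple(d["proportions"]) if d.get("proportions") else None,
        )


def snp_variance(maf: float, or_value: float) -> float:
    """Variance contributed by one biallelic SNP on the log-odds scale.

    ``2 p (1 - p) ln^2(OR)`` — the binomial dosage variance times the
    squared per-allele effect.
    """
    if or_value <= 0:
        raise ValueError(f"odds ratio must be positive, got {or_value}")
    if not 0.0 <= maf <= 1.0:
        raise ValueError(f"allele frequency must lie in [0, 1], got {maf}")
    return 2.0 * maf * (1.0 - maf) * math.log(or_value) ** 2


def heritability_from_variance(total_var: float) -> float:
    """Liability-scale heritability from the total genetic variance.

    ``h^2 = var / (var + pi^2/3)``; strictly increasing in ``total_var``
    and confined to [0, 1).
    """
    if total_var < 0:
        raise ValueError(f"variance must be non-negative, got {total_var}")
    return total_var / (total_var + LOGISTIC_RESIDUAL_VARIANCE)


def variance_for_heritability(h2: float) -> float:
    """Total genetic variance required for liability heritability ``h2``."""
    if not 0.0 <= h2 < 1.0:
        raise ValueError(f"heritability must lie in [0, 1), got {h2}")
    return h2 / (1.0 - h2) * LOGISTIC_RESIDUAL_VARIANCE


def snps_for_heritability(target_h2: float, grid: AlleleGrid | None = None) -> int:
    """SNP count the grid needs to reach a target heritability.

    Inverts the heritability formula for the required total variance,
    divides by the grid's mean per-SNP variance, and rounds to the nearest
    multiple of the number of grid cells so the count splits evenly.
    """
    if not 0.0 < target_h2 < 1.0:
        raise ValueError(f"target heritability must lie in (0, 1), got {target_h2}")
    grid = grid or AlleleGrid()
    raw = variance_for_heritability(target_h2) / grid.mean_snp_variance()
    unit = grid.n_cells
    n = int(round(raw / unit)) * unit
    return max(n, unit)


@dataclass(frozen=True)
class ArchitectureSpec:
    """A concrete architecture: per-SNP (MAF, effect size) assignments."""

    grid: AlleleGrid
    n_snps: int
    #: per-SNP (maf, beta) with beta = ln(OR) of that SNP's cell
    per_snp: tuple[tuple[float, float], ...]
    target_h2: float

    @property
    def mafs(self) -> np.ndarray:
        return np.array([p for p, _ in self.per_snp])

    @property
    def effects(self) -> np.ndarray:
        """Per-SNP effect sizes beta_k = ln(OR_k)."""
        return np.array([b for _, b in self.per_snp])

    @property
    def odds_ratios(self) -> np.ndarray:
        return np.exp(self.effects)

    def total_variance(self) -> float:
        return float(np.sum(2.0 * self.mafs * (1.0 - self.mafs) * self.effects**2))

    def realized_h2(self) -> float:
        return heritability_from_variance(self.total_variance())

    def cell_index(self) -> np.ndarray:
        """Grid-cell label (0..n_cells-1) of each SNP, MAF-major order."""
        cells = {c: i for i, c in enumerate(self.grid.cells())}
        ors = self.odds_ratios
        return np.array(
            [
                cells[min(cells, key=lambda c, p=p, r=r: abs(c[0] - p) + abs(c[1] - r))]
                for (p, _), r in zip(self.per_snp, ors)
            ]
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "snp_id": [f"snp{i:05d}" for i in range(self.n_snps)],
                "maf": self.mafs,
                "odds_ratio": self.odds_ratios,
                "effect_size": self.effects,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def to_dict(self) -> dict:
        return {
            "grid": self.grid.to_dict(),
            "n_snps": self.n_snps,
            "target_h2": self.target_h2,
            "per_snp": [[p, b] for p, b in self.per_snp],
        }

    def save(self, path) -> None:
        path = str(path)
        with open(path, "w") as fh:
            if path.endswith(".json"):
                json.dump(self.to_dict(), fh, indent=1)
            else:
                yaml.safe_dump(self.to_dict(), fh)

    @classmethod
    def from_dict(cls, d: dict) -> "ArchitectureSpec":
        return cls(
            grid=AlleleGrid.from_dict(d["grid"]),
            n_snps=int(d["n_snps"]),
            per_snp=tuple((float(p), float(b)) for p, b in d["per_snp"]),
            target_h2=float(d["target_h2"]),
        )

    @classmethod
    def load(cls, path) -> "ArchitectureSpec":
        path = str(path)
        with open(path) as fh:
            d = json.load(fh) if path.endswith(".json") else yaml.safe_load(fh)
        return cls.from_dict(d)


def mean_prs(spec: ArchitectureSpec) -> float:
    """Population mean of the polygenic risk score, ``2 sum_k p_k ln(OR_k)``."""
    return float(2.0 * np.sum(spec.mafs * spec.effects))


def build_architecture(
    target_h2: float,
    grid: AlleleGrid | None = None,
    n_snps: int | None = None,
) -> ArchitectureSpec:
    """Construct an architecture reaching ``target_h2`` on the given grid.

    SNPs are spread over grid cells as evenly as possible (cell counts
    differ by at most one; remainders go to the earliest cells in MAF-major
    order).  ``n_snps`` overrides the closed-form count when given.
    """
    grid = grid or AlleleGrid()
    if n_snps is None:
        n_snps = snps_for_heritability(target_h2, grid)
    if n_snps < 1:
        raise ValueError("need at least one SNP")
    cells = grid.cells()
    base, extra = divmod(n_snps, len(cells))
    per_snp: list[tuple[float, float]] = []
    for i, (p, r) in enumerate(cells):
        count = base + (1 if i < extra else 0)
        per_snp.extend([(p, math.log(r))] * count)
    return ArchitectureSpec(
        grid=grid, n_snps=n_snps, per_snp=tuple(per_snp), target_h2=target_h2
    )
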
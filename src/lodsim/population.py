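"""Genotype assignment under Hardy-Weinberg proportions and PRS computation.

Each individual carries a risk-allele dosage in {0, 1, 2} at every SNP,
drawn independently with genotype frequencies ``p^2, 2p(1-p), (1-p)^2``
(risk allele at frequency ``p``).  The polygenic risk score is the dosage-
weighted sum of per-allele log odds ratios, a lifelong characteristic fixed
at birth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .architecture import ArchitectureSpec

__all__ = ["GenotypeStore", "PopulationState", "assign_genotypes", "compute_prs", "sample_prs"]

_CHUNK = 256  # SNPs per block when streaming genotype draws


@dataclass
class GenotypeStore:
    """Compact dosage matrix: ``counts[i, k]`` in {0, 1, 2}, dtype int8."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int8)
        if self.counts.ndim != 2:
            raise ValueError("dosage matrix must be 2-D (individuals x SNPs)")

    @property
    def n_individuals(self) -> int:
        return self.counts.shape[0]

    @property
    def n_snps(self) -> int:
        return self.counts.shape[1]

    def allele_frequencies(self, ids: np.ndarray | None = None) -> np.ndarray:
        """Risk-allele frequency per SNP over the given individuals (all by default)."""
        sub = self.counts if ids is None else self.counts[ids]
        if sub.shape[0] == 0:
            raise ValueError("cannot tally allele frequencies over an empty set")
        return sub.mean(axis=0, dtype=np.float64) / 2.0


def _draw_dosages(mafs: np.ndarray, n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw an (n x len(mafs)) HWE dosage block."""
    u = rng.random((n, len(mafs)))
    # P(dosage>=1) = 1-(1-p)^2, P(dosage==2) = p^2
    q = 1.0 - mafs
    out = (u < 1.0 - q**2).astype(np.int8)
    out += (u < mafs**2).astype(np.int8)
    return out


def assign_genotypes(spec: ArchitectureSpec, n: int, seed: int | np.random.Generator) -> GenotypeStore:
    """Sample HWE genotypes for ``n`` individuals under the architecture."""
    if n < 1:
        raise ValueError(f"population size must be >= 1, got {n}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    mafs = spec.mafs
    counts = np.empty((n, spec.n_snps), dtype=np.int8)
    for lo in range(0, spec.n_snps, _CHUNK):
        hi = min(lo + _CHUNK, spec.n_snps)
        counts[:, lo:hi] = _draw_dosages(mafs[lo:hi], n, rng)
    return GenotypeStore(counts)


def compute_prs(store: GenotypeStore, spec: ArchitectureSpec) -> np.ndarray:
    """Per-individual PRS ``beta_i = sum_k a_ik ln(OR_k)``."""
    if store.n_snps != spec.n_snps:
        raise ValueError(
            f"genotype store has {store.n_snps} SNPs but architecture has {spec.n_snps}"
        )
    return store.counts @ spec.effects


def sample_prs(spec: ArchitectureSpec, n: int, seed: int | np.random.Generator) -> np.ndarray:
    """Draw PRS values directly, discarding genotypes.

    Memory-light alternative to :func:`assign_genotypes` + :func:`compute_prs`
    for large populations where only the score distribution matters.  Cohort
    allele-frequency tallies and PLINK export need the full genotype mode.
    """
    if n < 1:
        raise ValueError(f"population size must be >= 1, got {n}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    mafs, effects = spec.mafs, spec.effects
    prs = np.zeros(n)
    for lo in range(0, spec.n_snps, _CHUNK):
        hi = min(lo + _CHUNK, spec.n_snps)
        prs += _draw_dosages(mafs[lo:hi], n, rng) @ effects[lo:hi]
    return prs


@dataclass
class PopulationState:
    """A single birth cohort advancing through life in yearly steps.

    Life history is encoded by two per-individual ages, both -1 while the
    event has not happened: ``age_at_diagnosis`` and ``age_at_death``.
    Status transitions are unaffected -> diagnosed, unaffected -> dead and
    diagnosed -> dead only.
    """

    genotypes: GenotypeStore | None
    prs: np.ndarray
    current_age: int = 0
    age_at_diagnosis: np.ndarray = field(default=None)  # type: ignore[assignment]
    age_at_death: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        n = len(self.prs)
        if self.genotypes is not None and self.genotypes.n_individuals != n:
            raise ValueError("genotype store and PRS vector sizes disagree")
        if self.age_at_diagnosis is None:
            self.age_at_diagnosis = np.full(n, -1, dtype=np.int16)
        if self.age_at_death is None:
            self.age_at_death = np.full(n, -1, dtype=np.int16)

    @property
    def n(self) -> int:
        return len(self.prs)

    # --- masks at the current age -------------------------------------
    @property
    def alive(self) -> np.ndarray:
        return self.age_at_death < 0

    @property
    def diagnosed(self) -> np.ndarray:
        return self.age_at_diagnosis >= 0

    @property
    def unaffected_alive(self) -> np.ndarray:
        return self.alive & ~self.diagnosed

    # --- retrospective masks (valid after a completed run) -------------
    def diagnosed_by(self, age: int) -> np.ndarray:
        return (self.age_at_diagnosis >= 0) & (self.age_at_diagnosis <= age)

    def dead_by(self, age: int) -> np.ndarray:
        return (self.age_at_death >= 0) & (self.age_at_death <= age)

    def unaffected_alive_at(self, age: int) -> np.ndarray:
        """Individuals neither diagnosed nor dead by the end of year ``age``."""
        return ~self.diagnosed_by(age) & ~self.dead_by(age)

    def diagnosed_in_window(self, lo: float, hi: float) -> np.ndarray:
        """Diagnosis age in the half-open window [lo, hi)."""
        dx = self.age_at_diagnosis
        return (dx >= 0) & (dx >= lo) & (dx < hi)

    @classmethod
    def from_architecture(
        cls, spec: ArchitectureSpec, n: int, seed: int | np.random.Generator
    ) -> "PopulationState":
        store = assign_genotypes(spec, n, seed)
        return cls(genotypes=store, prs=compute_prs(store, spec))
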
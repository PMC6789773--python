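"""PLINK text export and per-SNP logistic association.

Cohorts are written as PLINK PED/MAP text files (phenotype 1 = control,
2 = case; alleles coded ``A`` = reference, ``B`` = risk) together with an
age covariate file.  Association is the customary single-SNP logistic
regression of case status on risk-allele dosage, optionally with an age
covariate, fitted by Newton-Raphson with a log-likelihood convergence
tolerance of 1e-8 and guards for monomorphic SNPs and complete separation
(flagged, never a crash).
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohorts import CohortSample
from .population import GenotypeStore

__all__ = [
    "AssociationResult",
    "export_plink",
    "read_plink_dosages",
    "logistic_association",
]

_GENO_CODES = {0: "A A", 1: "A B", 2: "B B"}


@dataclass
class AssociationResult:
    """Per-SNP logistic association estimate."""

    snp_id: str
    beta: float
    se: float
    p_value: float
    control_mid_age: float
    converged: bool = True
    flag: str = ""  # "", "monomorphic", "separation"


def export_plink(
    cohort: CohortSample,
    genotypes: GenotypeStore,
    ages: np.ndarray,
    path_prefix,
) -> tuple[str, str, str]:
    """Write ``<prefix>.ped``, ``<prefix>.map`` and ``<prefix>.cov``.

    ``ages`` gives each individual's age (indexed like the genotype store):
    diagnosis age for cases, sampling age for controls.  Returns the three
    paths written.
    """
    prefix = str(path_prefix)
    ids = np.concatenate([cohort.case_ids, cohort.control_ids])
    if ids.max() >= genotypes.n_individuals:
        raise ValueError("cohort references individuals outside the genotype store")
    pheno = np.concatenate(
        [np.full(cohort.n_cases, 2, dtype=int), np.full(cohort.n_controls, 1, dtype=int)]
    )
    ped_path, map_path, cov_path = prefix + ".ped", prefix + ".map", prefix + ".cov"
    try:
        with open(ped_path, "w") as ped:
            for ind, ph in zip(ids, pheno):
                geno = " ".join(_GENO_CODES[d] for d in genotypes.counts[ind])
                ped.write(f"F{ind} I{ind} 0 0 0 {ph} {geno}\n")
        with open(map_path, "w") as mp:
            for k in range(genotypes.n_snps):
                mp.write(f"1 snp{k:05d} 0 {k + 1}\n")
        with open(cov_path, "w") as cov:
            cov.write("FID IID age\n")
            for ind in ids:
                cov.write(f"F{ind} I{ind} {ages[ind]}\n")
    except OSError as exc:
        raise OSError(f"cannot write PLINK files at prefix {prefix!r}: {exc}") from exc
    return ped_path, map_path, cov_path


def read_plink_dosages(ped_path) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Parse a PED file back into (dosages, phenotypes, individual ids).

    Risk-allele dosage is the count of ``B`` alleles per SNP.
    """
    dosages, phenos, iids = [], [], []
    with open(ped_path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            iids.append(parts[1])
            phenos.append(int(parts[5]))
            alleles = parts[6:]
            if len(alleles) % 2:
                raise ValueError(f"{ped_path}: odd number of allele columns")
            dosages.append(
                [
                    (alleles[2 * k] == "B") + (alleles[2 * k + 1] == "B")
                    for k in range(len(alleles) // 2)
                ]
            )
    return np.array(dosages, dtype=np.int8), np.array(phenos), iids


def _newton_logistic(
    X: np.ndarray, y: np.ndarray, tol: float = 1e-8, max_iter: int = 50
) -> tuple[np.ndarray, np.ndarray, bool]:
    """ML logistic fit; returns (beta, standard errors, converged)."""
    n, p = X.shape
    beta = np.zeros(p)
    ll_old = -np.inf
    converged = False
    for _ in range(max_iter):
        eta = np.clip(X @ beta, -30, 30)
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1.0 - mu)
        grad = X.T @ (y - mu)
        hess = (X * w[:, None]).T @ X
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError:
            return beta, np.full(p, np.nan), False
        beta = beta + step
        ll = float(np.sum(y * eta - np.log1p(np.exp(eta))))
        if abs(ll - ll_old) < tol:
            converged = True
            break
        ll_old = ll
    eta = np.clip(X @ beta, -30, 30)
    mu = 1.0 / (1.0 + np.exp(-eta))
    w = mu * (1.0 - mu)
    hess = (X * w[:, None]).T @ X
    try:
        cov = np.linalg.inv(hess)
        se = np.sqrt(np.diag(cov))
    except np.linalg.LinAlgError:
        se = np.full(p, np.nan)
    return beta, se, converged


def logistic_association(
    cohort: CohortSample,
    genotypes: GenotypeStore,
    ages: np.ndarray | None = None,
    adjust_age: bool = False,
    snp_ids: np.ndarray | None = None,
) -> pd.DataFrame:
    """Single-SNP logistic regression of case status on dosage.

    Returns one row per SNP with columns ``snp_id, beta, se, p_value,
    control_mid_age, converged, flag``.  ``snp_ids`` restricts the scan to
    a subset of SNP indices.  Requires at least two cases and two controls.
    """
    from scipy import stats

    if cohort.n_cases < 2 or cohort.n_controls < 2:
        raise ValueError("association needs at least 2 cases and 2 controls")
    if adjust_age and ages is None:
        raise ValueError("age adjustment requested but no ages supplied")
    ids = np.concatenate([cohort.case_ids, cohort.control_ids])
    y = np.concatenate(
        [np.ones(cohort.n_cases), np.zeros(cohort.n_controls)]
    )
    dos = genotypes.counts[ids].astype(np.float64)
    snp_idx = np.arange(genotypes.n_snps) if snp_ids is None else np.asarray(snp_ids)

    n = len(ids)
    base_cols = 3 if adjust_age else 2
    X = np.empty((n, base_cols))
    X[:, 0] = 1.0
    if adjust_age:
        X[:, 2] = ages[ids]

    rows = []
    for k in snp_idx:
        d = dos[:, k]
        flag, beta_k, se_k, p_k, conv = "", np.nan, np.nan, np.nan, False
        if d.min() == d.max():
            flag = "monomorphic"
        else:
            X[:, 1] = d
            beta, se, conv = _newton_logistic(X, y)
            if not conv or abs(beta[1]) > 15 or not np.isfinite(se[1]):
                flag = "separation"
                conv = False
            else:
                beta_k, se_k = float(beta[1]), float(se[1])
                p_k = float(2.0 * stats.norm.sf(abs(beta_k / se_k)))
        rows.append(
            {
                "snp_id": f"snp{k:05d}",
                "beta": beta_k,
                "se": se_k,
                "p_value": p_k,
                "control_mid_age": cohort.control_mid_age,
                "converged": conv,
                "flag": flag,
            }
        )
    return pd.DataFrame(rows)
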
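"""Benchmark multi-trait tests: SUM_SCORE, TATES and MANOVA.

These are the standard comparators for a single-variant multi-trait
association scan, all with asymptotic p-values:

* SUM_SCORE — the signed sum of the K univariate score statistics,
  standardised by its null variance 1ᵀR1 (R the trait correlation
  matrix); powerful when effects share a direction, weak when they cancel.
* TATES — sorts the univariate p-values and Simes-corrects each prefix by
  the effective number of independent tests among its traits, estimated
  from the eigenvalues of their correlation matrix.
* MANOVA — multivariate regression of the traits on the genotype, Wilks'
  Λ with the exact F transform for a single predictor.

For one predictor Wilks' Λ = 1/(1 + t) with t = var(X)·βᵀV_R⁻¹β, and
T_MHT = t/(1 + t): MANOVA and MHT are strictly monotone transforms of one
another, which is why their permutation p-values coincide.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.stats

from mhto.core_estimation import (
    GenotypeVector,
    PhenotypeMatrix,
    _check_aligned,
    genotype_variance,
)
from mhto.permutation import TestResult

__all__ = [
    "UnivariateResults",
    "univariate_score_tests",
    "sum_score_test",
    "tates_test",
    "manova_test",
]

_P_FLOOR = np.finfo(float).tiny


@dataclass
class UnivariateResults:
    """Per-trait score statistics, two-sided p-values and the trait correlation matrix."""

    z_stats: np.ndarray
    p_values: np.ndarray
    trait_corr: np.ndarray
    trait_names: list[str]


def univariate_score_tests(
    phenotypes: PhenotypeMatrix, genotypes: GenotypeVector
) -> UnivariateResults:
    """Standardised score statistic Z_k = √n · corr(x, y_k) for every trait.

    Z_k = Σ_i (x_i − x̄)(y_ik − ȳ_k) / sqrt(n · var̂(X) · var̂(Y_k)), which is
    asymptotically N(0,1) under no association; p-values are two-sided.
    """
    _check_aligned(phenotypes, genotypes)
    x = genotypes.values
    y = phenotypes.values
    n = x.size
    var_x = genotype_variance(genotypes)
    if var_x <= 0.0:
        raise ValueError("genotype vector is constant")
    var_y = np.var(y, axis=0)
    if np.any(var_y <= 0.0):
        k = int(np.argmin(var_y))
        raise ValueError(f"trait {phenotypes.trait_names[k]!r} has zero variance")
    xc = x - x.mean()
    cross = (y - y.mean(axis=0)).T @ xc / n
    z = np.sqrt(n) * cross / np.sqrt(var_x * var_y)
    pvals = 2.0 * scipy.stats.norm.sf(np.abs(z))
    return UnivariateResults(
        z_stats=z,
        p_values=np.clip(pvals, _P_FLOOR, 1.0),
        trait_corr=np.corrcoef(y, rowvar=False).reshape(y.shape[1], y.shape[1]),
        trait_names=list(phenotypes.trait_names),
    )


def sum_score_test(univariate: UnivariateResults, squared: bool = False) -> TestResult:
    """SUM_SCORE: signed sum of the univariate score statistics.

    S = Σ_k Z_k has null variance 1ᵀR1 under joint asymptotic normality of
    the Z_k with correlation matrix R (the trait correlations), giving a
    two-sided normal p-value for S/√(1ᵀR1).

    ``squared=True`` switches to the quadratic alternative Σ_k Z_k²,
    referred to the distribution of Σ λ_i χ²_1 with λ_i the eigenvalues of
    R — kept for sensitivity analysis, not the default.
    """
    z = univariate.z_stats
    r = univariate.trait_corr
    if squared:
        stat = float(np.sum(z**2))
        lam = np.linalg.eigvalsh(r)
        lam = lam[lam > 1e-12]
        # Satterthwaite scaled chi-square for a weighted sum of chi2_1
        scale = np.sum(lam**2) / np.sum(lam)
        df = np.sum(lam) ** 2 / np.sum(lam**2)
        p = float(scipy.stats.chi2.sf(stat / scale, df))
        return TestResult(stat, max(p, _P_FLOOR), "SUM_SCORE_SQ")
    null_var = float(np.ones(z.size) @ r @ np.ones(z.size))
    if null_var <= 0.0:
        raise ValueError("degenerate trait correlation: null variance of S is <= 0")
    stat = float(np.sum(z))
    p = float(2.0 * scipy.stats.norm.sf(abs(stat) / np.sqrt(null_var)))
    return TestResult(stat, max(p, _P_FLOOR), "SUM_SCORE")


def _effective_tests(corr: np.ndarray) -> float:
    """Effective number of independent tests from correlation eigenvalues.

    m_e = Σ_i [ 1(λ_i ≥ 1) + (λ_i − floor(λ_i)) ]; equals the matrix size
    for independent traits and 1 for perfectly correlated ones.
    """
    lam = np.linalg.eigvalsh(corr)
    lam = np.clip(lam, 0.0, None)
    return float(np.sum((lam >= 1.0).astype(float) + (lam - np.floor(lam))))


def tates_test(univariate: UnivariateResults) -> TestResult:
    """TATES: Simes-style combination of sorted p-values with an
    effective-number-of-tests correction for trait correlation.

    With p_(1) ≤ … ≤ p_(K) and m_e(j) the effective test count among the j
    most significant traits (m_e = m_e(K) for all of them),

        p_TATES = min_j  m_e · p_(j) / m_e(j).

    The p-value correlations are approximated by the trait correlations.
    """
    order = np.argsort(univariate.p_values, kind="stable")
    p_sorted = univariate.p_values[order]
    k = p_sorted.size
    me_j = np.empty(k)
    for j in range(1, k + 1):
        sub = univariate.trait_corr[np.ix_(order[:j], order[:j])]
        me_j[j - 1] = _effective_tests(sub)
    me_total = me_j[-1]
    p = float(np.min(me_total * p_sorted / me_j))
    p = min(max(p, _P_FLOOR), 1.0)
    return TestResult(
        statistic=p,
        p_value=p,
        method="TATES",
        details={"m_eff": me_total, "top_trait": univariate.trait_names[order[0]]},
    )


def manova_test(
    phenotypes: PhenotypeMatrix, genotypes: GenotypeVector
) -> TestResult:
    """One-predictor MANOVA via Wilks' Λ with its exact F transform.

    Regresses all K traits on intercept + genotype; Λ = det(E)/det(E + H)
    with E the residual and H the hypothesis SSCP.  For a single predictor
    F = (1 − Λ)/Λ · (n − K − 1)/K is exactly F(K, n − K − 1), and all four
    classical MANOVA statistics give the same p-value.
    """
    _check_aligned(phenotypes, genotypes)
    n, k = phenotypes.values.shape
    if n <= k + 1:
        raise ValueError(f"MANOVA needs n > K + 1 (got n={n}, K={k})")
    x = genotypes.values
    var_x = genotype_variance(genotypes)
    if var_x <= 0.0:
        raise ValueError("genotype vector is constant")
    y = phenotypes.values
    xc = x - x.mean()
    yc = y - y.mean(axis=0)
    sxx = float(xc @ xc)
    b = yc.T @ xc / sxx
    h = np.outer(b, b) * sxx
    e = yc.T @ yc - h
    sign, logdet_e = np.linalg.slogdet(e)
    sign_t, logdet_t = np.linalg.slogdet(e + h)
    if sign <= 0 or sign_t <= 0:
        raise ValueError("residual SSCP is singular; traits are linearly dependent")
    wilks = float(np.exp(logdet_e - logdet_t))
    f_stat = (1.0 - wilks) / wilks * (n - k - 1) / k
    p = float(scipy.stats.f.sf(f_stat, k, n - k - 1))
    return TestResult(
        statistic=wilks,
        p_value=max(p, _P_FLOOR),
        method="MANOVA",
        details={"F": f_stat, "df1": k, "df2": n - k - 1},
    )
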
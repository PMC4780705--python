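"""Factor-model phenotype simulator and type-I error / power experiments.

Traits are generated from the pleiotropy factor model

    y = λ x + c γ f + sqrt(1 − c²) ε,

where x is the HWE genotype score at the variant, λ the K-vector of
genetic effect sizes, f ~ MVN(0, Σ) a vector of R latent factors with
exchangeable correlation Σ = (1 − ρ)I + ρ·11ᵀ, γ the K×R loading matrix
assigning each trait to exactly one factor with unit loading, and ε
independent standard normal residuals.  Under the null (β = 0) every
trait has marginal variance c²·1 + (1 − c²) = 1 regardless of the model.

Five loading layouts are supported (affected traits occupy the trailing
positions):

1. one factor, all K traits affected equally;
2. five equal factor blocks, the last block's K/5 traits affected;
3. two equal factor blocks, the last block's K/2 traits affected;
4. five equal factor blocks, only the last trait affected;
5. one factor, only the last trait affected.

The experiment runners draw a fresh genotype vector and trait matrix per
replicate, score all requested tests, and report rejection proportions
with the normal-approximation binomial confidence interval
α ± 1.96·sqrt(α(1 − α)/R) attached.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from mhto.core_estimation import GenotypeVector, PhenotypeMatrix
from mhto.permutation import mht_pvalue, mhto_pvalue, permute_and_score
from mhto.comparators import (
    manova_test,
    sum_score_test,
    tates_test,
    univariate_score_tests,
)

__all__ = [
    "ScenarioConfig",
    "ExperimentReport",
    "ALL_TESTS",
    "simulate_genotypes",
    "build_loadings",
    "simulate_traits",
    "run_all_tests",
    "type1_experiment",
    "power_experiment",
    "ci_bounds",
]

ALL_TESTS = ("MHT", "MHT-O", "SUM_SCORE", "TATES", "MANOVA")

#: default effect-size grids per loading model, chosen so that power at
#: n=1000, K=20, c=0.5 spans roughly 0.1-0.9 across the five tests
DEFAULT_BETA_GRIDS = {
    1: (0.03, 0.05, 0.08, 0.12),
    2: (0.05, 0.08, 0.12, 0.16),
    3: (0.04, 0.06, 0.09, 0.13),
    4: (0.10, 0.14, 0.18, 0.22),
    5: (0.10, 0.14, 0.18, 0.22),
}


@dataclass
class ScenarioConfig:
    """One simulation scenario: loading model plus sampling parameters.

    ``c`` controls how much trait correlation the latent factors induce
    (within-factor correlation c², between-factor c²ρ); the default 0.5
    gives moderately correlated traits.  Null calibration is insensitive
    to ``c``; power levels are not.
    """

    model: int
    K: int = 20
    n: int = 1000
    beta: float = 0.0
    maf: float = 0.3
    rho: float = 0.2
    c: float = 0.5
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.model not in (1, 2, 3, 4, 5):
            raise ValueError(f"model must be 1-5, got {self.model}")
        if self.K < 1 or self.n < 3:
            raise ValueError("invalid K or n")
        if self.model in (2, 4) and self.K % 5 != 0:
            raise ValueError(f"model {self.model} requires K divisible by 5")
        if self.model == 3 and self.K % 2 != 0:
            raise ValueError("model 3 requires K even")
        if not 0.0 < self.maf <= 0.5:
            raise ValueError("maf must lie in (0, 0.5]")
        if self.beta < 0.0:
            raise ValueError("beta must be nonnegative")
        if not 0.0 <= self.c < 1.0:
            raise ValueError("c must lie in [0, 1)")
        r = {1: 1, 2: 5, 3: 2, 4: 5, 5: 1}[self.model]
        if r > 1 and self.rho <= -1.0 / (r - 1):
            raise ValueError(f"rho={self.rho} makes the factor covariance indefinite")

    @property
    def n_factors(self) -> int:
        return {1: 1, 2: 5, 3: 2, 4: 5, 5: 1}[self.model]


@dataclass
class ExperimentReport:
    """Rejection proportions per test (and per α or per β) with CI metadata."""

    kind: str
    scenario: dict
    replicates: int
    B: int
    seed: int | None
    alphas: list[float]
    betas: list[float]
    rejections: dict  # test -> {str(alpha or beta) -> proportion}
    ci: dict  # str(alpha) -> [lo, hi]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        keys = self.alphas if self.kind == "type1" else self.betas
        key_name = "alpha" if self.kind == "type1" else "beta"
        for test, vals in self.rejections.items():
            for key in keys:
                row = {
                    "test": test,
                    key_name: key,
                    "rejection": vals[str(key)],
                    "replicates": self.replicates,
                }
                if self.kind == "type1":
                    row["ci_lo"], row["ci_hi"] = self.ci[str(key)]
                rows.append(row)
        return pd.DataFrame(rows)

    def to_json(self, **kwargs) -> str:
        return json.dumps(asdict(self), indent=2, **kwargs)


def simulate_genotypes(
    n: int, maf: float, seed: int | None | np.random.Generator = None
) -> GenotypeVector:
    """i.i.d. Hardy–Weinberg genotype counts: P(2)=maf², P(1)=2·maf(1−maf), P(0)=(1−maf)²."""
    if not 0.0 < maf <= 0.5:
        raise ValueError("maf must lie in (0, 0.5]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    x = rng.binomial(2, maf, size=n).astype(float)
    return GenotypeVector(values=x, sample_ids=[f"S{i:06d}" for i in range(n)])


def build_loadings(model: int, K: int, beta: float) -> tuple[np.ndarray, np.ndarray, int]:
    """Effect-size vector λ, loading matrix γ and factor count R for one model.

    Each trait loads on exactly one factor with weight 1; affected traits
    (those with λ = β) occupy the trailing positions.
    """
    cfg = ScenarioConfig(model=model, K=K, n=3, beta=max(beta, 0.0))
    r = cfg.n_factors
    block = K // r
    gamma = np.zeros((K, r))
    for i in range(r):
        gamma[i * block : (i + 1) * block, i] = 1.0
    lam = np.zeros(K)
    n_affected = {1: K, 2: K // 5, 3: K // 2, 4: 1, 5: 1}[model]
    if n_affected:
        lam[K - n_affected :] = beta
    return lam, gamma, r


def simulate_traits(
    cfg: ScenarioConfig,
    genotypes: GenotypeVector,
    seed: int | None | np.random.Generator = None,
) -> PhenotypeMatrix:
    """Draw the K traits from the factor model given a genotype vector."""
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(cfg.seed if seed is None else seed)
    )
    lam, gamma, r = build_loadings(cfg.model, cfg.K, cfg.beta)
    sigma = (1.0 - cfg.rho) * np.eye(r) + cfg.rho * np.ones((r, r))
    try:
        chol = np.linalg.cholesky(sigma)
    except np.linalg.LinAlgError as exc:
        raise ValueError("factor covariance is not positive definite") from exc
    n = genotypes.n_samples
    f = rng.standard_normal((n, r)) @ chol.T
    eps = rng.standard_normal((n, cfg.K))
    y = (
        np.outer(genotypes.values, lam)
        + cfg.c * (f @ gamma.T)
        + np.sqrt(1.0 - cfg.c**2) * eps
    )
    names = [f"T{k + 1}" for k in range(cfg.K)]
    return PhenotypeMatrix(values=y, sample_ids=list(genotypes.sample_ids), trait_names=names)


def run_all_tests(
    phenotypes: PhenotypeMatrix,
    genotypes: GenotypeVector,
    B: int,
    seed: int | None,
    tests: Sequence[str] = ALL_TESTS,
) -> dict[str, float]:
    """p-values of the requested tests on one dataset (one permutation ensemble
    shared by MHT and MHT-O)."""
    out: dict[str, float] = {}
    if "MHT" in tests or "MHT-O" in tests:
        ens = permute_and_score(phenotypes, genotypes, B=B, seed=seed)
        if "MHT" in tests:
            out["MHT"] = mht_pvalue(ens).p_value
        if "MHT-O" in tests:
            out["MHT-O"] = mhto_pvalue(ens).p_value
    if {"SUM_SCORE", "TATES"} & set(tests):
        uni = univariate_score_tests(phenotypes, genotypes)
        if "SUM_SCORE" in tests:
            out["SUM_SCORE"] = sum_score_test(uni).p_value
        if "TATES" in tests:
            out["TATES"] = tates_test(uni).p_value
    if "MANOVA" in tests:
        out["MANOVA"] = manova_test(phenotypes, genotypes).p_value
    return out


def _replicate_pvalues(
    cfg: ScenarioConfig,
    replicates: int,
    B: int,
    seed: int,
    tests: Sequence[str],
) -> dict[str, np.ndarray]:
    """p-value arrays per test over fresh genotype+trait replicates.

    Replicate r draws from the substream (seed, r), so runs are resumable
    and independent of execution order.
    """
    pvals: dict[str, list[float]] = {t: [] for t in tests}
    for rep in range(replicates):
        rng = np.random.default_rng([seed, rep])
        g = simulate_genotypes(cfg.n, cfg.maf, rng)
        y = simulate_traits(cfg, g, rng)
        perm_seed = int(rng.integers(2**31 - 1))
        res = run_all_tests(y, g, B=B, seed=perm_seed, tests=tests)
        for t in tests:
            pvals[t].append(res[t])
    return {t: np.asarray(v) for t, v in pvals.items()}


def type1_experiment(
    cfg: ScenarioConfig,
    replicates: int = 10_000,
    B: int = 1000,
    alphas: Iterable[float] = (0.05, 0.01),
    seed: int = 0,
    tests: Sequence[str] = ALL_TESTS,
) -> ExperimentReport:
    """Empirical type-I error of each test under a null (β = 0) scenario.

    Rejection proportions at every α come with the binomial CI for the
    replicate count actually used.
    """
    if cfg.beta != 0.0:
        raise ValueError("type-I error experiments require beta = 0")
    alphas = [float(a) for a in alphas]
    pvals = _replicate_pvalues(cfg, replicates, B, seed, tests)
    rejections = {
        t: {str(a): float(np.mean(p <= a)) for a in alphas} for t, p in pvals.items()
    }
    # boundary levels (0, 1) have degenerate, replicate-free intervals
    ci = {
        str(a): (list(ci_bounds(a, replicates)) if 0.0 < a < 1.0 else [a, a])
        for a in alphas
    }
    return ExperimentReport(
        kind="type1",
        scenario=asdict(cfg),
        replicates=replicates,
        B=B,
        seed=seed,
        alphas=alphas,
        betas=[0.0],
        rejections=rejections,
        ci=ci,
    )


def power_experiment(
    cfg: ScenarioConfig,
    beta_grid: Sequence[float],
    replicates: int = 500,
    B: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
    tests: Sequence[str] = ALL_TESTS,
) -> ExperimentReport:
    """Empirical power of each test over a grid of effect sizes at level α."""
    if any(b < 0 for b in beta_grid):
        raise ValueError("beta grid must be nonnegative")
    betas = [float(b) for b in beta_grid]
    rejections: dict[str, dict[str, float]] = {t: {} for t in tests}
    for i, b in enumerate(betas):
        cfg_b = ScenarioConfig(
            model=cfg.model, K=cfg.K, n=cfg.n, beta=b, maf=cfg.maf,
            rho=cfg.rho, c=cfg.c, seed=cfg.seed,
        )
        pvals = _replicate_pvalues(cfg_b, replicates, B, seed + i, tests)
        for t in tests:
            rejections[t][str(b)] = float(np.mean(pvals[t] <= alpha))
    return ExperimentReport(
        kind="power",
        scenario=asdict(cfg),
        replicates=replicates,
        B=B,
        seed=seed,
        alphas=[float(alpha)],
        betas=betas,
        rejections=rejections,
        ci={str(alpha): list(ci_bounds(alpha, replicates))},
    )


def ci_bounds(alpha: float, R: int) -> tuple[float, float]:
    """Normal-approximation 95% CI for an estimated rejection rate:
    α ± 1.96·sqrt(α(1 − α)/R)."""
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie strictly between 0 and 1")
    if R < 1:
        raise ValueError("replicate count must be >= 1")
    half = 1.96 * np.sqrt(alpha * (1.0 - alpha) / R)
    return (alpha - half, alpha + half)
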
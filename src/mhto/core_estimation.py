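"""Per-trait marginal linear models and variance-component matrices.

Every test in the package consumes the same decomposition of the total
phenotypic covariance,

    V_P = V_G + V_R,

where ``V_G = var(X) * beta beta^T`` is the (rank-one) genetic covariance
explained by the genotype score X through the marginal models
``Y_k = alpha_k + beta_k X + eps_k``, and V_R is the covariance of the OLS
residuals.  All variances use the 1/n (population-style) denominator, with
no Bessel correction, applied consistently so that every ratio formed
downstream is convention-free.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "PhenotypeMatrix",
    "GenotypeVector",
    "MarginalFit",
    "VarianceComponents",
    "AlignmentError",
    "DegenerateGenotypeError",
    "SingularCovarianceError",
    "align_samples",
    "genotype_variance",
    "fit_marginal_models",
    "residual_covariance",
    "variance_components",
    "residualize_covariates",
]

#: reciprocal condition number below which V_P is treated as singular
RCOND_SINGULAR = 1e-12


class AlignmentError(ValueError):
    """Sample identifiers of phenotype and genotype inputs cannot be reconciled."""


class DegenerateGenotypeError(ValueError):
    """The genotype vector is constant, so no association model is identifiable."""


class SingularCovarianceError(np.linalg.LinAlgError):
    """V_P (or a trait-subset submatrix of it) is numerically singular.

    A singular V_P almost always signals duplicated or linearly dependent
    traits; deduplicate the trait panel rather than relying on a
    pseudo-inverse.
    """


@dataclass
class PhenotypeMatrix:
    """n samples by K quantitative traits, with identifiers on both axes."""

    values: np.ndarray
    sample_ids: list[str]
    trait_names: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("phenotype values must be a 2-D matrix")
        n, k = self.values.shape
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.trait_names = [str(t) for t in self.trait_names]
        if len(self.sample_ids) != n:
            raise ValueError(f"{len(self.sample_ids)} sample ids for {n} rows")
        if len(self.trait_names) != k:
            raise ValueError(f"{len(self.trait_names)} trait names for {k} columns")
        if len(set(self.trait_names)) != k:
            raise ValueError("trait names must be unique")
        if n < 3:
            raise ValueError("at least 3 samples are required")
        if k < 1:
            raise ValueError("at least one trait is required")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("phenotype matrix contains missing/non-finite values")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_traits(self) -> int:
        return self.values.shape[1]


@dataclass
class GenotypeVector:
    """Genotype scores (minor-allele counts 0/1/2 or dosages in [0, 2]) for one variant."""

    values: np.ndarray
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        self.sample_ids = [str(s) for s in self.sample_ids]
        if len(self.sample_ids) != self.values.size:
            raise ValueError("sample ids and genotype values differ in length")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("genotype vector contains missing/non-finite values")

    @property
    def n_samples(self) -> int:
        return self.values.size


@dataclass
class MarginalFit:
    """OLS fits of each trait on the genotype: intercepts, slopes, residual matrix."""

    intercepts: np.ndarray
    slopes: np.ndarray
    residuals: np.ndarray


@dataclass
class VarianceComponents:
    """var(X), beta, and the V_R / V_G / V_P covariance partition for one variant."""

    var_x: float
    beta: np.ndarray
    V_R: np.ndarray
    V_G: np.ndarray
    V_P: np.ndarray
    trait_names: list[str] = field(default_factory=list)

    @property
    def n_traits(self) -> int:
        return self.beta.size


def align_samples(
    phenotypes: PhenotypeMatrix, genotypes: GenotypeVector
) -> tuple[PhenotypeMatrix, GenotypeVector]:
    """Intersect the two inputs on sample ID, in phenotype-file order.

    Samples missing from either input are dropped (complete-case analysis).
    Raises :class:`AlignmentError` if the intersection is empty or too small
    to fit a model.
    """
    geno_index = {s: i for i, s in enumerate(genotypes.sample_ids)}
    keep_rows: list[int] = []
    keep_geno: list[int] = []
    for i, s in enumerate(phenotypes.sample_ids):
        j = geno_index.get(s)
        if j is not None:
            keep_rows.append(i)
            keep_geno.append(j)
    if len(keep_rows) < 3:
        raise AlignmentError(
            f"only {len(keep_rows)} samples shared between phenotype and genotype inputs"
        )
    ids = [phenotypes.sample_ids[i] for i in keep_rows]
    p = PhenotypeMatrix(phenotypes.values[keep_rows], ids, list(phenotypes.trait_names))
    g = GenotypeVector(genotypes.values[keep_geno], ids)
    return p, g


def _check_aligned(phenotypes: PhenotypeMatrix, genotypes: GenotypeVector) -> None:
    if phenotypes.sample_ids != genotypes.sample_ids:
        raise AlignmentError(
            "phenotype and genotype sample ids differ; call align_samples() first"
        )


def genotype_variance(genotypes: GenotypeVector | np.ndarray) -> float:
    """1/n variance of the genotype scores; 0 iff the vector is constant."""
    x = genotypes.values if isinstance(genotypes, GenotypeVector) else np.asarray(genotypes, float)
    if x.size < 2:
        raise ValueError("genotype variance needs at least 2 samples")
    return float(np.var(x))


def fit_marginal_models(
    phenotypes: PhenotypeMatrix, genotypes: GenotypeVector
) -> MarginalFit:
    """OLS fit of each trait on the genotype: ``y_ik = alpha_k + beta_k x_i + eps_ik``.

    The slope is cov(x, y_k)/var(x); the 1/n convention cancels in the
    ratio, so slopes agree with any textbook OLS fit.
    """
    _check_aligned(phenotypes, genotypes)
    x = genotypes.values
    var_x = genotype_variance(genotypes)
    # scale-relative guard: catches exactly-constant vectors and the
    # numerically-zero residual genotypes left by self-regression
    if var_x <= 1e-12 * max(1.0, float(np.max(np.abs(x))) ** 2):
        raise DegenerateGenotypeError("genotype vector is (numerically) constant")
    y = phenotypes.values
    xc = x - x.mean()
    ybar = y.mean(axis=0)
    slopes = (y - ybar).T @ xc / (x.size * var_x)
    intercepts = ybar - slopes * x.mean()
    residuals = y - intercepts - np.outer(x, slopes)
    return MarginalFit(intercepts=intercepts, slopes=slopes, residuals=residuals)


def residual_covariance(fit: MarginalFit) -> np.ndarray:
    """K x K residual covariance V_R with (j,k) entry ``(1/n) sum_i r_ij r_ik``."""
    r = fit.residuals
    n = r.shape[0]
    vr = r.T @ r / n
    return (vr + vr.T) / 2.0  # enforce exact symmetry


def variance_components(
    phenotypes: PhenotypeMatrix, genotypes: GenotypeVector
) -> VarianceComponents:
    """Assemble var(X), beta, V_R, V_G = var(X)·beta betaᵀ and V_P = V_G + V_R.

    Because the residuals are orthogonal to the centred genotype, V_P is
    exactly the 1/n sample covariance matrix of the traits — in particular
    its diagonal recovers the total 1/n variance of each trait.

    Raises :class:`SingularCovarianceError` when V_P has reciprocal
    condition number below 1e-12 (redundant traits).
    """
    fit = fit_marginal_models(phenotypes, genotypes)
    var_x = genotype_variance(genotypes)
    beta = fit.slopes
    v_r = residual_covariance(fit)
    v_g = var_x * np.outer(beta, beta)
    v_p = v_g + v_r
    eigvals = np.linalg.eigvalsh(v_p)
    if eigvals[-1] <= 0.0 or eigvals[0] / eigvals[-1] < RCOND_SINGULAR:
        raise SingularCovarianceError(
            "V_P is numerically singular (rcond < 1e-12); the trait panel "
            "contains redundant traits — deduplicate before testing"
        )
    return VarianceComponents(
        var_x=var_x,
        beta=beta,
        V_R=v_r,
        V_G=v_g,
        V_P=v_p,
        trait_names=list(phenotypes.trait_names),
    )


def residualize_covariates(
    phenotypes: PhenotypeMatrix,
    genotypes: GenotypeVector,
    covariates: np.ndarray | Sequence[Sequence[float]] | None = None,
) -> tuple[PhenotypeMatrix, GenotypeVector]:
    """Regress traits and genotype on intercept + covariates; return the residuals.

    The canonical use is stratification control: pass the first L genotype
    principal components and run any of the tests on the residualized
    pair.  With ``covariates=None`` (or zero columns) the inputs are
    returned centred only.  A rank-deficient covariate matrix raises.
    """
    _check_aligned(phenotypes, genotypes)
    n = phenotypes.n_samples
    y = phenotypes.values
    x = genotypes.values
    if covariates is None:
        c = np.empty((n, 0))
    else:
        c = np.atleast_2d(np.asarray(covariates, dtype=float))
        if c.shape[0] != n:
            c = c.T
        if c.shape[0] != n:
            raise ValueError("covariate matrix does not match the sample count")
    if c.shape[1] >= n:
        raise ValueError("more covariates than samples")
    design = np.column_stack([np.ones(n), c])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("covariate matrix is rank deficient")
    proj, *_ = np.linalg.lstsq(design, np.column_stack([y, x]), rcond=None)
    resid = np.column_stack([y, x]) - design @ proj
    p_out = PhenotypeMatrix(
        resid[:, :-1], list(phenotypes.sample_ids), list(phenotypes.trait_names)
    )
    g_out = GenotypeVector(resid[:, -1], list(genotypes.sample_ids))
    return p_out, g_out
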
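"""Single-layer permutation machinery for MHT and MHT-O p-values.

One set of B genotype shuffles serves two purposes at once: it converts
the path statistics T_MHT,r into per-size p-values p_r, and it calibrates
the min-p statistic min_r p_r — the single-layer scheme of Ge et al. that
avoids nested (two-layer) permutation.

With b = 0 the observed data and b = 1…B the shuffles,

    p_r^(b) = #{d in 0..B : T_MHT,r^(d) > T_MHT,r^(b)} / B,
    p^(b)   = min_r p_r^(b),
    p-value(MHT-O) = #{b in 1..B : p^(b) < p^(0)} / B.

The plain MHT p-value uses only the full-panel column:
#{b in 1..B : T_MHT,K^(b) >= T_MHT,K^(0)} / B.

Inequalities are kept strict exactly as written above; ties between
continuous statistics have probability ~0, and the degenerate all-equal
column (every p_r^(b) = 0) is documented rather than special-cased.

Permutation is cheap here because the trait covariance V_P and var(X) are
invariant under shuffling genotype labels — only the slope vector β moves.
All B+1 slope vectors come from one matrix product, and the greedy
deletion paths are run for all permutations simultaneously with batched
rank-one inverse downdates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

from mhto.core_estimation import (
    DegenerateGenotypeError,
    GenotypeVector,
    PhenotypeMatrix,
    SingularCovarianceError,
    _check_aligned,
)

__all__ = [
    "PermutationEnsemble",
    "TestResult",
    "permute_and_score",
    "ge_pvalues",
    "mht_pvalue",
    "mhto_pvalue",
]


@dataclass
class PermutationEnsemble:
    """(B+1) x K table of greedy-path statistics across genotype shuffles.

    ``stats[b, r-1]`` is T_MHT,r for permutation b; row 0 is the observed
    data and coincides with the :class:`~mhto.mht.DeletionPath` statistics
    of the unpermuted inputs.  ``deleted_order`` records the observed
    (b = 0) greedy deletion order for reporting.
    """

    B: int
    seed: int | None
    stats: np.ndarray
    deleted_order: list[int] = field(default_factory=list)

    @property
    def n_traits(self) -> int:
        return self.stats.shape[1]


@dataclass
class TestResult:
    """One association test outcome: statistic, p-value and provenance."""

    statistic: float
    p_value: float
    method: str
    B: int = 0
    details: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")


def _batched_greedy_paths(
    v_p: np.ndarray, betas: np.ndarray, var_x: float
) -> tuple[np.ndarray, np.ndarray]:
    """Run the greedy deletion path for many slope vectors against one V_P.

    Parameters
    ----------
    v_p : (K, K) trait covariance (permutation-invariant).
    betas : (M, K) slope vectors, one row per permutation (row 0 observed).
    var_x : genotype variance (permutation-invariant).

    Returns
    -------
    stats : (M, K) with column r-1 holding T_MHT,r per permutation.
    first_deleted : (M, K-1) original trait index deleted at each step
        (size K -> K-1 first), used to report the observed deletion order.
    """
    m_perm, k = betas.shape
    try:
        inv0 = np.linalg.inv(v_p)
    except np.linalg.LinAlgError as exc:
        raise SingularCovarianceError("V_P is singular") from exc
    minv = np.broadcast_to(inv0, (m_perm, k, k)).copy()
    alive = np.broadcast_to(np.arange(k), (m_perm, k)).copy()
    bsub = betas.copy()
    stats = np.empty((m_perm, k))
    deleted = np.empty((m_perm, max(k - 1, 0)), dtype=int)
    rows = np.arange(m_perm)
    for r in range(k, 0, -1):
        u = np.einsum("mij,mj->mi", minv, bsub)
        h = np.einsum("mi,mi->m", bsub, u)
        stats[:, r - 1] = var_x * h
        if r == 1:
            break
        mdiag = np.diagonal(minv, axis1=1, axis2=2)
        if np.any(mdiag <= 0.0) or not np.all(np.isfinite(mdiag)):
            bad = int(np.where(np.any((mdiag <= 0.0) | ~np.isfinite(mdiag), axis=1))[0][0])
            raise SingularCovarianceError(
                f"singular V_P submatrix encountered in permutation {bad} at panel size {r}"
            )
        q = u - mdiag * bsub
        h_del = h[:, None] - 2.0 * bsub * u + bsub**2 * mdiag - q**2 / mdiag
        # alive rows stay sorted, so argmax's first hit is the smallest trait index
        pos = np.argmax(h_del, axis=1)
        deleted[:, k - r] = alive[rows, pos]
        col = np.take_along_axis(minv, pos[:, None, None], axis=2)[:, :, 0]
        minv = minv - col[:, :, None] * col[:, None, :] / mdiag[rows, pos][:, None, None]
        keep = np.ones((m_perm, r), dtype=bool)
        keep[rows, pos] = False
        minv = minv[keep].reshape(m_perm, r - 1, r)
        minv = (
            minv.transpose(0, 2, 1)[keep].reshape(m_perm, r - 1, r - 1).transpose(0, 2, 1)
        )
        bsub = bsub[keep].reshape(m_perm, r - 1)
        alive = alive[keep].reshape(m_perm, r - 1)
    return stats, deleted


def permute_and_score(
    phenotypes: PhenotypeMatrix,
    genotypes: GenotypeVector,
    B: int = 1000,
    seed: int | None = None,
) -> PermutationEnsemble:
    """Score the observed data and B genotype shuffles along the greedy path.

    Each permutation independently shuffles the genotype vector with the
    traits fixed, re-estimates the variance components and recomputes the
    full deletion path.  (In practice only β needs re-estimation — V_P and
    var(X) are label-invariant — and all paths run batched; the result is
    identical to naive recomputation.)  Reproducible given ``seed``.
    """
    _check_aligned(phenotypes, genotypes)
    if B < 1:
        raise ValueError("at least one permutation is required")
    x = genotypes.values
    n = x.size
    var_x = float(np.var(x))
    if var_x <= 0.0:
        raise DegenerateGenotypeError("genotype vector is constant")
    y = phenotypes.values
    yc = y - y.mean(axis=0)
    v_p = yc.T @ yc / n  # equals V_G + V_R for any genotype labelling
    v_p = (v_p + v_p.T) / 2.0
    rng = np.random.default_rng(seed)
    xmat = np.empty((n, B + 1))
    xmat[:, 0] = x
    xmat[:, 1:] = rng.permuted(np.broadcast_to(x, (B, n)).copy(), axis=1).T
    xmat -= x.mean()  # shuffling preserves the mean
    betas = (yc.T @ xmat).T / (n * var_x)  # (B+1, K)
    stats, deleted = _batched_greedy_paths(v_p, betas, var_x)
    return PermutationEnsemble(
        B=B, seed=seed, stats=stats, deleted_order=[int(i) for i in deleted[0]]
    )


def ge_pvalues(ensemble: PermutationEnsemble) -> np.ndarray:
    """Per-size permutation p-values p_r^(b) for every row of the ensemble.

    ``p[b, r-1]`` counts, over all B+1 rows d (including d = b), how often
    T_MHT,r^(d) strictly exceeds T_MHT,r^(b), divided by B.  Values range
    over {0, 1/B, …, 1}; an all-tied column yields all zeros.
    """
    stats = ensemble.stats
    out = np.empty_like(stats)
    n_rows = stats.shape[0]
    for col in range(stats.shape[1]):
        v = stats[:, col]
        order = np.sort(v)
        out[:, col] = n_rows - np.searchsorted(order, v, side="right")
    return out / ensemble.B


def mht_pvalue(ensemble: PermutationEnsemble) -> TestResult:
    """Permutation p-value of plain MHT on the full trait panel.

    p = #{b in 1..B : T_MHT,K^(b) >= T_MHT,K^(0)} / B.  The resolution
    floor 1/B is recorded in the result details.
    """
    full = ensemble.stats[:, -1]
    p = float(np.sum(full[1:] >= full[0]) / ensemble.B)
    return TestResult(
        statistic=float(full[0]),
        p_value=p,
        method="MHT",
        B=ensemble.B,
        details={"resolution": 1.0 / ensemble.B, "seed": ensemble.seed},
    )


def mhto_pvalue(ensemble: PermutationEnsemble) -> TestResult:
    """Overall MHT-O p-value from the single permutation layer.

    The statistic is the observed min-p, p^(0) = min_r p_r^(0); the
    p-value is the fraction of permutations whose own min-p falls strictly
    below it.
    """
    pmat = ge_pvalues(ensemble)
    pmin = pmat.min(axis=1)
    p0 = float(pmin[0])
    p = float(np.sum(pmin[1:] < p0) / ensemble.B)
    r_star = int(np.argmin(pmat[0]) + 1)
    return TestResult(
        statistic=p0,
        p_value=p,
        method="MHT-O",
        B=ensemble.B,
        details={
            "selected_size": r_star,
            "deleted_order": list(ensemble.deleted_order),
            "resolution": 1.0 / ensemble.B,
            "seed": ensemble.seed,
        },
    )
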
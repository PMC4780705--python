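"""Maximum heritability statistic and the greedy trait-deletion path.

For a weight vector w, the heritability of the combined trait wᵀY is

    h_w² = wᵀ V_G w / wᵀ V_P w.

Maximising over w gives the MHT statistic.  Because V_G = var(X)·β βᵀ has
rank one, the maximum eigenvalue of V_G V_P⁻¹ has the closed form

    T_MHT = λ_max(V_G V_P⁻¹) = var(X) · βᵀ V_P⁻¹ β,

a number in [0, 1).  The trait-deleting variant repeatedly removes the
trait whose deletion leaves the largest T_MHT on the survivors, recording
the statistic at every panel size; the permutation module turns that path
into the MHT-O min-p test.

Subset statistics are computed by indexing into the full-panel β and V_P
rather than refitting: the marginal fit of one trait does not depend on
which other traits are present, so the submatrix route is algebraically
identical to recomputation on a physically reduced trait matrix (and is
what makes the permutation test affordable).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import scipy.linalg

from mhto.core_estimation import SingularCovarianceError, VarianceComponents

__all__ = [
    "DeletionPath",
    "combination_heritability",
    "mht_statistic",
    "greedy_deletion_path",
]


@dataclass
class DeletionPath:
    """Greedy deletion order and the statistics T_MHT,r for r = K … 1.

    ``stats_by_size[r-1]`` holds T_MHT evaluated on the surviving panel of
    size r; ``deleted_order[j]`` is the original trait index removed at the
    step taking the panel from size K-j to K-j-1; ``subsets[r-1]`` is the
    surviving index tuple at size r.
    """

    deleted_order: list[int]
    stats_by_size: np.ndarray
    subsets: list[tuple[int, ...]]

    @property
    def n_traits(self) -> int:
        return self.stats_by_size.size


def combination_heritability(vc: VarianceComponents, w: Sequence[float]) -> float:
    """Heritability h_w² = wᵀV_G w / wᵀV_P w of the combination wᵀY.

    Invariant to rescaling of w; raises if w lies in the null space of V_P.
    """
    w = np.asarray(w, dtype=float).ravel()
    if w.size != vc.n_traits:
        raise ValueError("weight vector length does not match the trait count")
    denom = float(w @ vc.V_P @ w)
    if denom <= 0.0 or not np.isfinite(denom):
        raise ValueError("w has zero variance under V_P; heritability undefined")
    return float(w @ vc.V_G @ w) / denom


def mht_statistic(
    vc: VarianceComponents, subset: Sequence[int] | None = None
) -> float:
    """T_MHT = var(X)·β_sᵀ (V_P[s,s])⁻¹ β_s on a trait subset s (default: all).

    Solved through a Cholesky factorisation of the V_P submatrix; a
    factorisation failure raises :class:`SingularCovarianceError` naming
    the subset.
    """
    if subset is None:
        idx = np.arange(vc.n_traits)
    else:
        idx = np.asarray(sorted(set(int(i) for i in subset)), dtype=int)
        if idx.size == 0:
            raise ValueError("trait subset is empty")
        if idx.min() < 0 or idx.max() >= vc.n_traits:
            raise ValueError("trait subset indices out of range")
    beta = vc.beta[idx]
    vp = vc.V_P[np.ix_(idx, idx)]
    try:
        cho = scipy.linalg.cho_factor(vp, lower=True)
    except scipy.linalg.LinAlgError as exc:
        raise SingularCovarianceError(
            f"V_P submatrix on traits {tuple(idx)} is not positive definite"
        ) from exc
    return float(vc.var_x * beta @ scipy.linalg.cho_solve(cho, beta))


def greedy_deletion_path(vc: VarianceComponents) -> DeletionPath:
    """Delete one trait at a time, always the one whose removal maximises T_MHT.

    At panel size r every one of the r single-deletion subsets is scored and
    the maximiser is removed (ties broken toward the smallest original trait
    index); T_MHT is recorded at every size from K down to 1.

    Deletion scores come from a rank-one downdate of the running V_P
    inverse: with M = (V_P[s,s])⁻¹ and u = Mβ_s, removing trait i gives

        T(s minus i) / var(X) = βᵀMβ − 2β_i u_i + β_i² M_ii − (u_i − M_ii β_i)² / M_ii,

    evaluated for all i at once.
    """
    k = vc.n_traits
    try:
        m = np.linalg.inv(vc.V_P)
    except np.linalg.LinAlgError as exc:
        raise SingularCovarianceError("V_P is singular") from exc
    alive = np.arange(k)
    beta = vc.beta.copy()
    stats = np.empty(k)
    deleted: list[int] = []
    subsets: list[tuple[int, ...]] = [tuple()] * k
    for r in range(k, 0, -1):
        bsub = beta[alive]
        u = m @ bsub
        h = float(bsub @ u)
        stats[r - 1] = vc.var_x * h
        subsets[r - 1] = tuple(int(i) for i in alive)
        if r == 1:
            break
        mdiag = np.diag(m).copy()
        if np.any(mdiag <= 0.0) or not np.all(np.isfinite(mdiag)):
            raise SingularCovarianceError(
                f"V_P submatrix on traits {tuple(alive)} is numerically singular"
            )
        q = u - mdiag * bsub
        h_del = h - 2.0 * bsub * u + bsub**2 * mdiag - q**2 / mdiag
        # alive is kept sorted, so argmax's first-hit rule == smallest trait index
        pos = int(np.argmax(vc.var_x * h_del))
        deleted.append(int(alive[pos]))
        col = m[:, pos]
        m = m - np.outer(col, col) / mdiag[pos]
        keep = np.ones(r, dtype=bool)
        keep[pos] = False
        m = m[np.ix_(keep, keep)]
        alive = alive[keep]
    return DeletionPath(deleted_order=deleted, stats_by_size=stats, subsets=subsets)
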
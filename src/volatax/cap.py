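"""Canonical analysis of principal coordinates (CAP).

PCoA of an arbitrary dissimilarity matrix, selection of the number of
principal-coordinate axes m, canonical discriminant analysis of those axes
against a-priori groups, leave-one-out (LOO) allocation with Gower
projection of the held-out sample, permutation tests, and compound-vector
overlays (per-compound correlations with the first two canonical axes).

Conventions
-----------
* Negative PCoA eigenvalues are reported but their axes are dropped
  (no Lingoes/Cailliez correction by default).
* Eigenvector signs are fixed deterministically: each PCoA axis has its
  largest-magnitude loading positive; each canonical axis is oriented so
  the first group's centroid is nonnegative on it.
* LOO places the held-out sample by projecting its squared distances onto
  the retained eigenbasis (Gower's supplementary-point formula), then
  allocates to the nearest group centroid in canonical space.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.linalg import eigh

from .errors import DegenerateInputError, GroupingError
from .io_formats import PeakTable
from .preprocess import DistanceMatrix

logger = logging.getLogger(__name__)

EIG_REL_TOLERANCE = 1e-10  # axes with eigenvalue <= tol * |lambda_1| dropped


# ---------------------------------------------------------------------------
# Result types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PCoAResult:
    """Principal coordinates of a dissimilarity matrix."""

    sample_ids: tuple[str, ...]
    eigenvalues: np.ndarray            # all N eigenvalues, descending
    axis_scores: np.ndarray            # samples x retained axes (eigvec * sqrt(lambda))
    eigenvectors: np.ndarray = field(repr=False)  # unit-norm, retained axes only
    proportion_explained: np.ndarray = field(default=None)

    @property
    def retained_axes(self) -> int:
        return self.axis_scores.shape[1]


@dataclass(frozen=True)
class CAPResult:
    """One canonical discriminant analysis on m principal-coordinate axes."""

    sample_ids: tuple[str, ...]
    groups: tuple[str, ...]            # per-sample labels, aligned to sample_ids
    group_order: tuple[str, ...]       # order of first appearance
    m: int
    delta_sq: np.ndarray               # squared canonical correlations, descending
    canonical_scores: np.ndarray       # samples x a
    group_centroids: np.ndarray        # g x a, rows follow group_order
    trace_statistic: float
    loo_error_pct: float | None = None
    confusion: pd.DataFrame | None = None
    p_trace: float | None = None
    p_first: float | None = None

    @property
    def n_axes(self) -> int:
        return self.canonical_scores.shape[1]

    def centroid_of(self, group: str) -> np.ndarray:
        return self.group_centroids[self.group_order.index(group)]


@dataclass(frozen=True)
class CompoundVector:
    """Correlation of one compound with the first two canonical axes."""

    compound_id: str
    x: float
    y: float
    significant: bool = False

    @property
    def squared_length(self) -> float:
        return self.x * self.x + self.y * self.y


# ---------------------------------------------------------------------------
# Gower centering and PCoA
# ---------------------------------------------------------------------------

def gower_center(dm: DistanceMatrix | np.ndarray) -> np.ndarray:
    """Double-center -0.5 * D^2: G = J (-1/2 D∘D) J with J = I - 11'/n."""
    if isinstance(dm, DistanceMatrix):
        d = dm.values
    else:
        d = np.asarray(dm, dtype=float)
        if d.ndim != 2 or d.shape[0] != d.shape[1]:
            raise DegenerateInputError("distance matrix must be square")
        if not np.allclose(d, d.T, atol=1e-10, rtol=0):
            raise DegenerateInputError("distance matrix must be symmetric")
    if d.shape[0] < 2:
        raise DegenerateInputError("need at least 2 samples")
    a = -0.5 * d * d
    row = a.mean(axis=1, keepdims=True)
    col = a.mean(axis=0, keepdims=True)
    return a - row - col + a.mean()


def pcoa(dm: DistanceMatrix, eig_tolerance: float | None = None) -> PCoAResult:
    """Eigendecompose the Gower-centered matrix; keep positive axes.

    Axes with eigenvalue <= tolerance (default ``1e-10 * |lambda_1|``) are
    dropped; negative eigenvalues remain visible in ``eigenvalues``.
    """
    g = gower_center(dm)
    vals, vecs = eigh(g)
    order = np.argsort(vals)[::-1]
    vals = vals[order]
    vecs = vecs[:, order]
    scale = abs(vals[0]) if vals.size else 0.0
    tol = eig_tolerance if eig_tolerance is not None else EIG_REL_TOLERANCE * scale
    keep = vals > max(tol, 0.0)
    if not keep.any():
        raise DegenerateInputError(
            "no positive PCoA eigenvalues above tolerance (degenerate input)"
        )
    lam = vals[keep]
    v = vecs[:, keep]
    # deterministic sign: largest-|loading| entry of each axis is positive
    for k in range(v.shape[1]):
        j = int(np.argmax(np.abs(v[:, k])))
        if v[j, k] < 0:
            v[:, k] = -v[:, k]
    scores = v * np.sqrt(lam)
    pos_sum = lam.sum()
    return PCoAResult(
        sample_ids=dm.sample_ids,
        eigenvalues=vals,
        axis_scores=scores,
        eigenvectors=v,
        proportion_explained=lam / pos_sum,
    )


# ---------------------------------------------------------------------------
# Canonical discriminant analysis on the first m axes
# ---------------------------------------------------------------------------

def _group_order(groups: Sequence[str]) -> tuple[str, ...]:
    order: list[str] = []
    for g in groups:
        if g not in order:
            order.append(g)
    return tuple(order)


def _check_groups(groups: Sequence[str], n: int) -> tuple[str, ...]:
    groups = tuple(str(g) for g in groups)
    if len(groups) != n:
        raise GroupingError(
            f"got {len(groups)} group labels for {n} samples"
        )
    order = _group_order(groups)
    if len(order) < 2:
        raise GroupingError("need at least 2 a-priori groups")
    return groups


def canonical_analysis(
    pc: PCoAResult, groups: Sequence[str], m: int
) -> CAPResult:
    """Canonical discriminant analysis of the first m orthonormal PCoA axes.

    With Q the orthonormal basis of the first m axes and H the group
    "hat" projector, the eigenvalues of Q'HQ are the squared canonical
    correlations; canonical scores are the samples projected on the
    corresponding directions of Q.
    """
    n = len(pc.sample_ids)
    groups = _check_groups(groups, n)
    order = _group_order(groups)
    g = len(order)
    if not 1 <= m <= pc.retained_axes:
        raise DegenerateInputError(
            f"m={m} not in [1, {pc.retained_axes}] retained axes"
        )
    q = pc.eigenvectors[:, :m]
    labels = np.array([order.index(x) for x in groups])
    sizes = np.bincount(labels, minlength=g)
    if (sizes == 0).any():
        raise GroupingError("empty a-priori group")
    # Q'HQ = sum_g n_g qbar_g qbar_g'
    qbar = np.vstack([q[labels == k].mean(axis=0) for k in range(g)])
    w = (qbar * sizes[:, None]).T @ qbar
    vals, vecs = eigh(w)
    idx = np.argsort(vals)[::-1]
    a = min(m, g - 1)
    delta_sq = np.clip(vals[idx][:a], 0.0, 1.0)
    u = vecs[:, idx][:, :a]
    scores = q @ u
    centroids = np.vstack([scores[labels == k].mean(axis=0) for k in range(g)])
    # orient: first group's centroid nonnegative on each axis
    for k in range(a):
        col = centroids[:, k]
        pivot = 0
        while pivot < g - 1 and abs(col[pivot]) < 1e-12:
            pivot += 1
        if col[pivot] < 0:
            scores[:, k] = -scores[:, k]
            centroids[:, k] = -centroids[:, k]
    return CAPResult(
        sample_ids=pc.sample_ids,
        groups=groups,
        group_order=order,
        m=m,
        delta_sq=delta_sq,
        canonical_scores=scores,
        group_centroids=centroids,
        trace_statistic=float(delta_sq.sum()),
    )


# ---------------------------------------------------------------------------
# Leave-one-out allocation
# ---------------------------------------------------------------------------

def _project_supplementary(
    d_tr_sq: np.ndarray, d_new_sq: np.ndarray, eigvecs: np.ndarray,
    eigvals: np.ndarray,
) -> np.ndarray:
    """Gower's formula: coordinates of a new point in an existing PCoA basis.

    Returns the new point's row in the *orthonormal* (unit-eigenvector)
    basis, i.e. comparable with rows of Q.
    """
    n = d_tr_sq.shape[0]
    row_means = d_tr_sq.mean(axis=1)
    grand = d_tr_sq.mean()
    g_new = -0.5 * (d_new_sq - d_new_sq.mean() - row_means + grand)
    return (g_new @ eigvecs) / eigvals


def loo_misclassification(
    dm: DistanceMatrix, groups: Sequence[str], m: int
) -> tuple[float, pd.DataFrame]:
    """Leave-one-out allocation error (percent) and confusion table.

    Each sample is held out; PCoA and the canonical axes are recomputed on
    the remaining N-1 samples; the held-out sample is projected into the
    canonical space via its distances to the retained samples and allocated
    to the nearest group centroid (Euclidean in canonical space).
    """
    n = dm.n_samples
    groups = _check_groups(groups, n)
    order = _group_order(groups)
    g = len(order)
    d = dm.values
    confusion = pd.DataFrame(
        np.zeros((g, g), dtype=int), index=list(order), columns=list(order)
    )
    errors = 0
    for i in range(n):
        idx = np.array([j for j in range(n) if j != i])
        d_tr = d[np.ix_(idx, idx)]
        tr_groups = [groups[j] for j in idx]
        tr_order = _group_order(tr_groups)
        sub = DistanceMatrix(
            sample_ids=tuple(dm.sample_ids[j] for j in idx),
            values=d_tr,
            metric_name=dm.metric_name,
        )
        pc = pcoa(sub)
        m_fold = min(m, pc.retained_axes)
        if m_fold < m:
            logger.info(
                "LOO fold %d: m reduced from %d to %d (retained axes)",
                i, m, m_fold,
            )
        cap = canonical_analysis(pc, tr_groups, m_fold)
        z = _project_supplementary(
            d_tr ** 2, d[i, idx] ** 2,
            pc.eigenvectors[:, :m_fold],
            pc.eigenvalues[: pc.retained_axes][:m_fold],
        )
        z_can = z @ np.linalg.lstsq(
            pc.eigenvectors[:, :m_fold], cap.canonical_scores, rcond=None
        )[0]
        dist = np.linalg.norm(cap.group_centroids - z_can, axis=1)
        predicted = cap.group_order[int(np.argmin(dist))]
        confusion.loc[groups[i], predicted] += 1
        if predicted != groups[i]:
            errors += 1
    return 100.0 * errors / n, confusion


def select_m(
    dm: DistanceMatrix,
    groups: Sequence[str],
    m_max: int | None = None,
    m_cap: int = 20,
    pc: PCoAResult | None = None,
) -> int:
    """Scan m from g-1 upward, minimizing LOO error; ties -> smallest m."""
    n = dm.n_samples
    groups = _check_groups(groups, n)
    g = len(_group_order(groups))
    if pc is None:
        pc = pcoa(dm)
    hi = min(pc.retained_axes, n - g, m_cap)
    if m_max is not None:
        hi = min(hi, m_max)
    lo = g - 1
    if hi < 1:
        raise DegenerateInputError("no feasible number of PCoA axes")
    if hi < lo:
        logger.warning(
            "fewer usable axes (%d) than groups-1 (%d); scanning up to %d",
            hi, lo, hi,
        )
        lo = hi
    best_m, best_err = lo, np.inf
    for m in range(lo, hi + 1):
        err, _ = loo_misclassification(dm, groups, m)
        if err < best_err - 1e-12:
            best_m, best_err = m, err
    return best_m


# ---------------------------------------------------------------------------
# Permutation test
# ---------------------------------------------------------------------------

def permutation_test(
    dm: DistanceMatrix,
    groups: Sequence[str],
    m: int,
    n_perm: int = 999,
    seed: int | None = None,
    pc: PCoAResult | None = None,
) -> tuple[float, float]:
    """Permutation p-values for the trace statistic and the first delta^2.

    p = (1 + #{permuted statistic >= observed}) / (1 + n_perm).
    """
    if n_perm < 99:
        raise DegenerateInputError("n_perm must be at least 99")
    n = dm.n_samples
    groups = _check_groups(groups, n)
    order = _group_order(groups)
    g = len(order)
    if pc is None:
        pc = pcoa(dm)
    q = pc.eigenvectors[:, :m]
    labels = np.array([order.index(x) for x in groups])

    def stats(lab: np.ndarray) -> tuple[float, float]:
        qbar = np.vstack([q[lab == k].mean(axis=0) for k in range(g)])
        sizes = np.bincount(lab, minlength=g)
        w = (qbar * sizes[:, None]).T @ qbar
        vals = np.linalg.eigvalsh(w)
        vals = np.clip(np.sort(vals)[::-1][: min(m, g - 1)], 0.0, 1.0)
        return float(vals.sum()), float(vals[0])

    obs_trace, obs_first = stats(labels)
    rng = np.random.default_rng(seed)
    ge_trace = ge_first = 0
    for _ in range(n_perm):
        perm = rng.permutation(labels)
        t, f = stats(perm)
        if t >= obs_trace - 1e-12:
            ge_trace += 1
        if f >= obs_first - 1e-12:
            ge_first += 1
    p_trace = (1 + ge_trace) / (1 + n_perm)
    p_first = (1 + ge_first) / (1 + n_perm)
    return p_trace, p_first


# ---------------------------------------------------------------------------
# Compound vectors
# ---------------------------------------------------------------------------

def compound_vectors(
    pt: PeakTable,
    cap: CAPResult,
    sig_cutoff: float,
    sig_mode: str = "len2",
) -> list[CompoundVector]:
    """Pearson correlations of each compound with canonical axes 1 and 2.

    ``sig_mode='len2'`` flags vectors with X^2+Y^2 > cutoff; ``'abs_r'``
    flags vectors with |X| > cutoff or |Y| > cutoff. Zero-variance
    compounds yield (0, 0) with a warning. If only one canonical axis is
    available, Y = 0.
    """
    if sig_mode not in ("len2", "abs_r"):
        raise DegenerateInputError(f"unknown significance mode {sig_mode!r}")
    if tuple(pt.sample_ids) != tuple(cap.sample_ids):
        raise GroupingError(
            "peak table sample order does not match canonical scores"
        )
    axis1 = cap.canonical_scores[:, 0]
    if cap.n_axes >= 2:
        axis2 = cap.canonical_scores[:, 1]
    else:
        logger.warning("only one canonical axis; vector Y set to 0")
        axis2 = None
    vectors = []
    n_flat = 0
    for row, compound in zip(pt.abundances, pt.compound_ids):
        if np.std(row) == 0:
            n_flat += 1
            x = y = 0.0
        else:
            x = _pearson(row, axis1)
            y = _pearson(row, axis2) if axis2 is not None else 0.0
        if sig_mode == "len2":
            significant = x * x + y * y > sig_cutoff
        else:
            significant = abs(x) > sig_cutoff or abs(y) > sig_cutoff
        vectors.append(
            CompoundVector(compound_id=compound, x=x, y=y, significant=significant)
        )
    if n_flat:
        logger.warning("%d zero-variance compound(s) got vector (0, 0)", n_flat)
    return vectors


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc @ xc) * (yc @ yc))
    if denom == 0:
        return 0.0
    return float(np.clip((xc @ yc) / denom, -1.0, 1.0))


# ---------------------------------------------------------------------------
# Convenience: full CAP round on a distance matrix
# ---------------------------------------------------------------------------

def cap_analysis(
    dm: DistanceMatrix,
    groups: Sequence[str],
    m: int | None = None,
    m_max: int | None = None,
    n_perm: int = 0,
    seed: int | None = None,
) -> CAPResult:
    """PCoA + (optional) m selection + canonical analysis + LOO (+ test)."""
    pc = pcoa(dm)
    if m is None:
        m = select_m(dm, groups, m_max=m_max, pc=pc)
    m = min(m, pc.retained_axes)
    cap = canonical_analysis(pc, groups, m)
    err, confusion = loo_misclassification(dm, groups, m)
    p_trace = p_first = None
    if n_perm:
        p_trace, p_first = permutation_test(
            dm, groups, m, n_perm=n_perm, seed=seed, pc=pc
        )
    return CAPResult(
        sample_ids=cap.sample_ids,
        groups=cap.groups,
        group_order=cap.group_order,
        m=m,
        delta_sq=cap.delta_sq,
        canonical_scores=cap.canonical_scores,
        group_centroids=cap.group_centroids,
        trace_statistic=cap.trace_statistic,
        loo_error_pct=err,
        confusion=confusion,
        p_trace=p_trace,
        p_first=p_first,
    )
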
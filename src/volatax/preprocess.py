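"""Replicate averaging, abundance transforms and dissimilarity matrices.

The default pipeline (replicate means → relative abundances → Bray-Curtis)
feeds the constrained ordination; every step is selectable per round from
the cascade plan.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .errors import ConfigurationError, ConsistencyError, DegenerateInputError
from .io_formats import PeakTable, SampleTable

logger = logging.getLogger(__name__)

TRANSFORMS = ("relative", "log1p", "presence", "none")
METRICS = ("bray-curtis", "euclidean", "jaccard-binary")


@dataclass(frozen=True)
class DistanceMatrix:
    """Square symmetric sample dissimilarity matrix with zero diagonal."""

    sample_ids: tuple[str, ...]
    values: np.ndarray
    metric_name: str

    def __post_init__(self):
        ids = tuple(str(s) for s in self.sample_ids)
        object.__setattr__(self, "sample_ids", ids)
        v = np.asarray(self.values, dtype=float)
        n = len(ids)
        if v.shape != (n, n):
            raise ConfigurationError(
                f"distance matrix shape {v.shape} does not match {n} samples"
            )
        if not np.allclose(v, v.T, atol=1e-12, rtol=0):
            raise ConfigurationError("distance matrix is not symmetric")
        v = (v + v.T) / 2.0
        np.fill_diagonal(v, 0.0)
        if (v < 0).any():
            raise ConfigurationError("distance matrix has negative entries")
        v.setflags(write=False)
        object.__setattr__(self, "values", v)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)


def average_technical_replicates(pt: PeakTable, st: SampleTable) -> PeakTable:
    """Collapse technical replicates to their arithmetic mean.

    Output columns are replicate groups, ordered by first appearance among
    the peak table's samples. Groups with fewer than 3 replicates trigger a
    warning (the protocol expects n >= 3).
    """
    rep_of = st.replicate_group_of_sample()
    missing = [s for s in pt.sample_ids if s not in rep_of]
    if missing:
        raise ConsistencyError(
            f"samples absent from metadata: {missing}"
        )
    order: list[str] = []
    members: dict[str, list[int]] = {}
    for j, s in enumerate(pt.sample_ids):
        g = rep_of[s]
        if g not in members:
            members[g] = []
            order.append(g)
        members[g].append(j)
    cols = []
    for g in order:
        idx = members[g]
        if len(idx) < 3:
            logger.warning(
                "replicate group %r has only %d replicate(s); protocol "
                "expects n >= 3", g, len(idx),
            )
        cols.append(pt.abundances[:, idx].mean(axis=1))
    return replace(
        pt,
        sample_ids=tuple(order),
        abundances=np.column_stack(cols),
    )


def transform_abundances(
    pt: PeakTable, mode: str, detection_threshold: float = 0.0
) -> PeakTable:
    """Apply a column-wise abundance transform.

    relative : divide each sample column by its sum (all-zero column stays
               zero, with a warning)
    log1p    : natural log of (1 + value)
    presence : 1 where value > detection_threshold else 0
    none     : identity
    """
    if mode not in TRANSFORMS:
        raise ConfigurationError(
            f"unknown transform {mode!r}; valid transforms: {TRANSFORMS}"
        )
    values = pt.abundances
    if mode == "none":
        out = values.copy()
    elif mode == "log1p":
        out = np.log1p(values)
    elif mode == "presence":
        out = (values > detection_threshold).astype(float)
    else:  # relative
        sums = values.sum(axis=0)
        zero = sums == 0
        if zero.any():
            logger.warning(
                "%d all-zero sample column(s) left unchanged by the "
                "relative transform", int(zero.sum()),
            )
        safe = np.where(zero, 1.0, sums)
        out = values / safe
    return replace(pt, abundances=out)


def compute_distance_matrix(pt: PeakTable, metric: str) -> DistanceMatrix:
    """Pairwise sample dissimilarities.

    bray-curtis    : sum|u-v| / sum(u+v), 0 when both profiles are empty
    euclidean      : standard
    jaccard-binary : 1 - |intersection| / |union| on presence vectors
    """
    if metric not in METRICS:
        raise ConfigurationError(
            f"unknown metric {metric!r}; valid metrics: {METRICS}"
        )
    if pt.n_samples < 2:
        raise DegenerateInputError("need at least 2 samples for distances")
    profiles = pt.abundances.T  # samples x compounds
    if metric == "euclidean":
        condensed = pdist(profiles, metric="euclidean")
    elif metric == "bray-curtis":
        condensed = pdist(profiles, metric="braycurtis")
        condensed = np.nan_to_num(condensed, nan=0.0)  # both-empty pairs
    else:
        condensed = pdist(profiles > 0, metric="jaccard")
        condensed = np.nan_to_num(condensed, nan=0.0)
    return DistanceMatrix(
        sample_ids=pt.sample_ids,
        values=squareform(condensed),
        metric_name=metric,
    )


def prune_compounds(pt: PeakTable) -> PeakTable:
    """Drop compounds whose row is all zero across the retained samples."""
    nonzero = (pt.abundances > 0).any(axis=1)
    if not nonzero.any():
        raise DegenerateInputError("pruning would remove every compound")
    removed = [c for c, keep in zip(pt.compound_ids, nonzero) if not keep]
    if removed:
        logger.info("pruned %d all-zero compound(s): %s", len(removed), removed)
        keep_ids = [c for c, k in zip(pt.compound_ids, nonzero) if k]
        return pt.subset_compounds(keep_ids)
    return pt
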
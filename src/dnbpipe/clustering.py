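"""Temporal profile clustering by fuzzy c-means.

Gene expression profiles (replicate means per time point, standardized per
gene) are softly partitioned into ``c`` clusters by minimizing

    J = sum_i sum_k u_ik^m * ||x_i - v_k||^2

subject to each membership row summing to one, with fuzzifier ``m > 1``.
The alternating updates are the classical ones: centroids are the
membership-weighted means, memberships follow the inverse-distance rule

    u_ik = 1 / sum_j (d_ik / d_ij)^(2/(m-1)).

Genes are assigned to their argmax-membership cluster when that membership
clears a threshold, mirroring the "core gene" convention of soft temporal
clustering tools.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .errors import EmptyResultError, ParameterError
from .io import ExpressionTimeCourse

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TemporalProfileMatrix:
    """Standardized per-gene temporal profiles (gene x time)."""

    gene_ids: tuple[str, ...]
    times: tuple[float, ...]
    profiles: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "profiles",
                           np.asarray(self.profiles, dtype=float))
        if self.profiles.shape != (len(self.gene_ids), len(self.times)):
            raise ParameterError("profiles shape must be genes x times")


@dataclass(frozen=True)
class FuzzyClustering:
    """Soft clustering result: membership matrix, centroids, objective."""

    membership: np.ndarray  # genes x c
    centroids: np.ndarray   # c x times
    fuzzifier: float
    objective: float
    n_iter: int
    converged: bool
    seed: int
    gene_ids: tuple[str, ...] = ()

    @property
    def n_clusters(self) -> int:
        return self.centroids.shape[0]


def build_profiles(tc: ExpressionTimeCourse) -> TemporalProfileMatrix:
    """Average replicates per time point and standardize each gene.

    Rows are centred and scaled to unit sample SD (ddof=1, the convention of
    R's ``scale``); genes with zero temporal variance are dropped with a
    logged warning.
    """
    times = tc.times
    if times.size < 2:
        raise ParameterError("need >= 2 time points")
    means = np.column_stack([
        tc.values[:, tc.sample_indices_at([t])].mean(axis=1) for t in times
    ])
    sd = means.std(axis=1, ddof=1)
    keep = sd > 0
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.warning("dropping %d gene(s) with flat temporal profile",
                       n_dropped)
    if not keep.any():
        raise EmptyResultError("every gene has a flat temporal profile")
    profiles = (means[keep] - means[keep].mean(axis=1, keepdims=True)) \
        / sd[keep, None]
    return TemporalProfileMatrix(
        gene_ids=tuple(g for g, k in zip(tc.gene_ids, keep) if k),
        times=tuple(float(t) for t in times),
        profiles=profiles,
    )


def _evaluate_objective(x: np.ndarray, u: np.ndarray, v: np.ndarray,
                        m: float) -> float:
    d2 = cdist(x, v, metric="sqeuclidean")
    return float(((u ** m) * d2).sum())


def fuzzy_cmeans(profiles: TemporalProfileMatrix | np.ndarray, c: int,
                 m: float = 2.0, tol: float = 1e-6, max_iter: int = 300,
                 seed: int = 0) -> FuzzyClustering:
    """Fuzzy c-means on temporal profiles.

    Initialization draws each membership row from a flat Dirichlet with the
    given seed, so runs are reproducible.  Iteration stops when the
    objective decreases by less than ``tol`` (it is non-increasing by
    construction) or after ``max_iter`` sweeps.  A profile coinciding
    exactly with a centroid receives indicator membership of the nearest
    (lowest-index) coincident centroid.
    """
    if isinstance(profiles, TemporalProfileMatrix):
        x = profiles.profiles
        gene_ids = profiles.gene_ids
    else:
        x = np.asarray(profiles, dtype=float)
        gene_ids = ()
    n = x.shape[0]
    if not 1 <= c < n:
        raise ParameterError("need 1 <= c < n_genes")
    if m <= 1:
        raise ParameterError("fuzzifier m must be > 1")
    if tol <= 0:
        raise ParameterError("tol must be > 0")

    rng = np.random.default_rng(seed)
    u = rng.dirichlet(np.ones(c), size=n)

    prev_j = np.inf
    j = np.inf
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        um = u ** m
        v = (um.T @ x) / um.sum(axis=0)[:, None]
        d2 = cdist(x, v, metric="sqeuclidean")
        zero_rows = np.nonzero((d2 == 0).any(axis=1))[0]
        with np.errstate(divide="ignore", invalid="ignore"):
            inv = d2 ** (-1.0 / (m - 1.0))
            u = inv / inv.sum(axis=1, keepdims=True)
        for i in zero_rows:
            u[i] = 0.0
            u[i, int(np.argmin(d2[i]))] = 1.0
        j = _evaluate_objective(x, u, v, m)
        if abs(prev_j - j) < tol:
            converged = True
            break
        prev_j = j

    return FuzzyClustering(
        membership=u,
        centroids=v,
        fuzzifier=m,
        objective=j,
        n_iter=n_iter,
        converged=converged,
        seed=seed,
        gene_ids=tuple(gene_ids),
    )


def assign_clusters(fc: FuzzyClustering,
                    membership_threshold: float = 0.5) -> dict[str, int | None]:
    """Assign each gene to its argmax-membership cluster above a threshold.

    Genes whose maximal membership is below the threshold map to ``None``
    (unassigned); ties break toward the lowest cluster index.  Requires the
    clustering to carry gene ids.
    """
    if not 0 < membership_threshold <= 1:
        raise ParameterError("membership_threshold must be in (0, 1]")
    if not fc.gene_ids:
        raise ParameterError("clustering carries no gene ids")
    best = np.argmax(fc.membership, axis=1)  # ties -> lowest index
    best_val = fc.membership[np.arange(len(best)), best]
    return {
        g: (int(k) if val >= membership_threshold else None)
        for g, k, val in zip(fc.gene_ids, best, best_val)
    }
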
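"""Dynamic-network-biomarker statistics and tipping-point detection.

A candidate gene module in a time window ("state") is scored by the
composite index

    CI = SD_in * PCC_in / PCC_out

where PCC_in is the mean absolute pairwise Pearson correlation among module
genes (self-pairs excluded), PCC_out the mean absolute correlation between
module genes and all non-module genes, and SD_in the mean per-gene standard
deviation of the module genes within the window.  A system approaching a
critical transition shows a sharp CI peak: within-module correlation and
dispersion rise while coupling to the rest of the network falls.  The window
with the (earliest) maximal CI over the candidate modules is reported as the
tipping point, and the winning module as the DNB gene set.

Absolute correlations are used throughout: signed averaging would let an
anti-correlated module cancel to zero despite strong coupling.  PCC_out is
floored at a small epsilon in the CI denominator so decorrelated backgrounds
cannot produce infinities.

Module discovery is global, window scoring local.  With few pooled samples
per window (bulk designs typically have 2-3 replicates), window-local
clustering is dominated by selection noise: among thousands of genes some
small set is always spuriously near-perfectly correlated in a handful of
samples, and picking the tightest window-local cluster inflates PCC_in by
construction.  Candidate modules are therefore formed once from the whole
course (full-course correlations pool every sample and are independent of
the sample-to-time assignment), and only the CI evaluation slides across
windows.  The permutation test exploits the same property: because the
candidate pool is (almost entirely) invariant under permutation of the
sample-to-time assignment, re-running the full max-over-candidates-and-
windows selection inside each permutation yields an exchangeable, correctly
calibrated null for the CI peak.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .errors import EmptyCandidatesError, ParameterError
from .io import ExpressionTimeCourse

DEFAULT_EPSILON = 1e-3
DEFAULT_MIN_SIZE = 20
DEFAULT_MAX_SIZE = 100
#: per-window pooled sample count that the auto window-width rule targets;
#: with fewer samples the null mean of |r| is so high (0.64 at n=3) that
#: window statistics are mostly noise.
TARGET_WINDOW_SAMPLES = 9


@dataclass(frozen=True)
class DNBWindowStats:
    """Module statistics for one sliding window."""

    window_index: int
    window_times: tuple[float, ...]
    module_gene_ids: frozenset[str]
    pcc_in: float
    pcc_out: float
    sd_in: float
    ci: float
    n_samples: int = 0


@dataclass(frozen=True)
class DNBResult:
    """Per-window best modules, the tipping point, and its significance."""

    per_window: tuple[DNBWindowStats, ...]
    tp_window_index: int
    dnb_gene_ids: frozenset[str]
    permutation_p: float | None = None
    n_permutations: int = 0
    seed: int | None = None
    window_width: int = 1

    @property
    def ci_series(self) -> np.ndarray:
        return np.array([w.ci for w in self.per_window])

    @property
    def tp_times(self) -> tuple[float, ...]:
        return self.per_window[self.tp_window_index].window_times


# ---------------------------------------------------------------------------
# low-level statistics
# ---------------------------------------------------------------------------

def _standardize_columns(window: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Column-standardized matrix (scaled so Z.T @ Z is the correlation
    matrix) and per-column sample SD (ddof=1)."""
    n = window.shape[0]
    mean = window.mean(axis=0)
    sd = window.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (window - mean) / sd
    return z / np.sqrt(n - 1), sd


def _abs_corr(window: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """|Pearson correlation| between all columns, plus per-column SD."""
    z, sd = _standardize_columns(window)
    corr = np.abs(z.T @ z)
    np.clip(corr, 0.0, 1.0, out=corr)
    return corr, sd


def _stats_from_corr(corr_abs: np.ndarray, sd: np.ndarray, idx: np.ndarray,
                     epsilon: float) -> tuple[float, float, float, float]:
    """(pcc_in, pcc_out, sd_in, ci) for module columns ``idx``."""
    s = idx.size
    n = corr_abs.shape[0]
    sub = corr_abs[np.ix_(idx, idx)]
    sub_sum = float(sub.sum())
    pcc_in = (sub_sum - s) / (s * (s - 1))
    row_sum = float(corr_abs[idx].sum())
    pcc_out = (row_sum - sub_sum) / (s * (n - s))
    sd_in = float(sd[idx].mean())
    ci = sd_in * pcc_in / max(pcc_out, epsilon)
    return pcc_in, pcc_out, sd_in, ci


def module_stats(window: np.ndarray, gene_ids: Sequence[str],
                 module_gene_ids: Iterable[str],
                 epsilon: float = DEFAULT_EPSILON,
                 window_index: int = 0,
                 window_times: Sequence[float] = ()) -> DNBWindowStats:
    """Compute PCC_in, PCC_out, SD_in and CI for one module in one window.

    ``window`` is samples x genes.  Requires >= 3 samples, a module of
    2 <= size < n_genes, and no zero-variance gene within the window.
    """
    window = np.asarray(window, dtype=float)
    if window.ndim != 2 or window.shape[0] < 3:
        raise ParameterError("window must be samples x genes with >= 3 samples")
    if window.shape[1] != len(gene_ids):
        raise ParameterError("gene_ids length must match window columns")
    module = frozenset(module_gene_ids)
    if len(module) < 2:
        raise ParameterError("module must contain >= 2 genes")
    unknown = module - set(gene_ids)
    if unknown:
        raise ParameterError(f"module gene(s) not in window: {sorted(unknown)[:5]}")
    if len(module) >= len(gene_ids):
        raise ParameterError("module must be a proper subset of genes "
                             "(PCC_out undefined otherwise)")
    sd_all = window.std(axis=0, ddof=1)
    if (sd_all == 0).any():
        bad = [g for g, s in zip(gene_ids, sd_all) if s == 0]
        raise ParameterError(
            f"zero-variance gene(s) in window: {bad[:5]}; drop them upstream"
        )
    corr_abs, sd = _abs_corr(window)
    idx = np.array([i for i, g in enumerate(gene_ids) if g in module])
    pcc_in, pcc_out, sd_in, ci = _stats_from_corr(corr_abs, sd, idx, epsilon)
    return DNBWindowStats(
        window_index=window_index,
        window_times=tuple(float(t) for t in window_times),
        module_gene_ids=module,
        pcc_in=pcc_in,
        pcc_out=pcc_out,
        sd_in=sd_in,
        ci=ci,
        n_samples=window.shape[0],
    )


# ---------------------------------------------------------------------------
# candidate module formation
# ---------------------------------------------------------------------------

def _cut_levels(n_genes: int, min_size: int, max_size: int,
                n_cut_levels: int) -> list[int]:
    lo = max(2, int(np.ceil(n_genes / max_size)))
    hi = max(lo, int(np.floor(n_genes / min_size)))
    ks = np.unique(np.geomspace(lo, hi, num=n_cut_levels).round().astype(int))
    return [int(k) for k in ks if 2 <= k < n_genes]


#: distance cuts (on 1 - |PCC|) complementing the cluster-count cuts;
#: tight blocks surface at low heights regardless of how many singleton
#: genes remain above them.
DISTANCE_CUTS = (0.2, 0.3, 0.4, 0.5, 0.6, 0.7)


def candidate_modules(matrix: np.ndarray, gene_ids: Sequence[str],
                      min_size: int = DEFAULT_MIN_SIZE,
                      max_size: int = DEFAULT_MAX_SIZE,
                      n_cut_levels: int = 8,
                      corr_abs: np.ndarray | None = None) -> list[frozenset[str]]:
    """Candidate gene modules from hierarchical clustering.

    Genes are clustered by average linkage on the distance ``1 - |PCC|``;
    the tree is cut at ``n_cut_levels`` cluster counts spanning
    ``[n_genes/max_size, n_genes/min_size]`` plus a fixed ladder of
    distance thresholds, and every cluster whose size falls within
    ``[min_size, max_size]`` becomes a candidate (deduplicated,
    deterministic given input ordering).  ``matrix`` is samples x genes —
    typically the whole course rather than a single window (see module
    docstring).
    """
    n_genes = len(gene_ids)
    if not 2 <= min_size <= max_size < n_genes:
        raise ParameterError("need 2 <= min_size <= max_size < n_genes")
    if corr_abs is None:
        corr_abs, _ = _abs_corr(np.asarray(matrix, dtype=float))
    dist = 1.0 - corr_abs
    np.fill_diagonal(dist, 0.0)
    condensed = squareform(dist, checks=False)
    tree = linkage(condensed, method="average")

    gene_arr = np.asarray(gene_ids)
    seen: set[frozenset[str]] = set()
    out: list[frozenset[str]] = []
    cuts = [("maxclust", k) for k in
            _cut_levels(n_genes, min_size, max_size, n_cut_levels)]
    cuts += [("distance", h) for h in DISTANCE_CUTS]
    for criterion, t in cuts:
        labels = fcluster(tree, t=t, criterion=criterion)
        for lab in np.unique(labels):
            members = gene_arr[labels == lab]
            if min_size <= members.size <= max_size:
                mod = frozenset(members.tolist())
                if mod not in seen:
                    seen.add(mod)
                    out.append(mod)
    if not out:
        raise EmptyCandidatesError(
            "no cluster within size bounds at any cut; widen "
            "[min_size, max_size] or adjust n_cut_levels"
        )
    return out


class _CandidatePool:
    """Deterministic candidate-module index sets for one time course.

    Sources: average-linkage clusters of the full-course ``1 - |PCC|``
    distance (the strategy behind :func:`candidate_modules`), correlation-
    refined variants of those clusters at a grid of sizes, and top
    principal-component loading sets — all computed from full-course,
    assignment-invariant quantities.  Optionally, per-window dispersion-ratio
    seeds (genes whose window SD most exceeds their course SD) refined by
    full-course correlation are added; these depend weakly on the
    sample-to-time assignment and are excluded from the pool used inside the
    permutation test.
    """

    def __init__(self, tc: ExpressionTimeCourse, min_size: int, max_size: int,
                 n_cut_levels: int, refine_sizes: Sequence[int] = (35, 50, 70, 100),
                 n_pcs: int = 4, refine_iters: int = 2):
        X = tc.values.T  # samples x genes
        self.corr_full, self.sd_full = _abs_corr(X)
        self.min_size, self.max_size = min_size, max_size
        self._refine_sizes = [s for s in refine_sizes if min_size <= s <= max_size]
        self._refine_iters = refine_iters
        self._seen: set[frozenset[int]] = set()
        self.invariant: list[np.ndarray] = []   # assignment-invariant members
        self.extra: list[np.ndarray] = []       # window-seeded members

        base = candidate_modules(X, tc.gene_ids, min_size=min_size,
                                 max_size=max_size, n_cut_levels=n_cut_levels,
                                 corr_abs=self.corr_full)
        pos = {g: i for i, g in enumerate(tc.gene_ids)}
        for mod in base:
            idx = np.fromiter(sorted(pos[g] for g in mod), dtype=int)
            self._add(idx, self.invariant)
            for size in self._refine_sizes:
                self._add(self._refine(idx, size), self.invariant)

        z, _ = _standardize_columns(X)
        _, _, vt = np.linalg.svd(z, full_matrices=False)
        for j in range(min(n_pcs, vt.shape[0])):
            order = np.argsort(-np.abs(vt[j]), kind="stable")
            for size in self._refine_sizes:
                seed = np.sort(order[:size])
                self._add(seed, self.invariant)
                self._add(self._refine(seed, size), self.invariant)

    def _add(self, idx: np.ndarray, dest: list[np.ndarray]) -> None:
        key = frozenset(idx.tolist())
        if key not in self._seen:
            self._seen.add(key)
            dest.append(idx)

    def _refine(self, idx: np.ndarray, size: int) -> np.ndarray:
        cur = idx
        for _ in range(self._refine_iters):
            score = self.corr_full[cur].mean(axis=0)
            cur = np.sort(np.argsort(-score, kind="stable")[:size])
        return cur

    def add_window_seeds(self, window: np.ndarray) -> None:
        """Dispersion-ratio seeds from one window, refined globally."""
        ratio = window.std(axis=0, ddof=1) / self.sd_full
        order = np.argsort(-ratio, kind="stable")
        for size in self._refine_sizes:
            seed = np.sort(order[:size])
            self._add(seed, self.extra)
            self._add(self._refine(seed, size), self.extra)

    @property
    def all_candidates(self) -> list[np.ndarray]:
        return self.invariant + self.extra


# ---------------------------------------------------------------------------
# tipping-point detection
# ---------------------------------------------------------------------------

def _resolve_window_width(tc: ExpressionTimeCourse,
                          window_width: int | None) -> int:
    if window_width is not None:
        if window_width < 1:
            raise ParameterError("window_width must be >= 1")
        return window_width
    times = tc.times
    min_reps = min(tc.sample_indices_at([t]).size for t in times)
    width = int(np.ceil(TARGET_WINDOW_SAMPLES / min_reps))
    return min(max(width, 1), len(times) - 1)


def _windows(tc: ExpressionTimeCourse, width: int) -> list[tuple[float, ...]]:
    times = [float(t) for t in tc.times]
    if width > len(times):
        raise ParameterError("window_width exceeds number of time points")
    return [tuple(times[i:i + width]) for i in range(len(times) - width + 1)]


def _window_matrix(tc: ExpressionTimeCourse,
                   window_times: Sequence[float]) -> np.ndarray:
    cols = tc.sample_indices_at(window_times)
    return tc.values[:, cols].T  # samples x genes


def detect_tipping_point(tc: ExpressionTimeCourse,
                         window_width: int | None = None,
                         min_size: int = DEFAULT_MIN_SIZE,
                         max_size: int = DEFAULT_MAX_SIZE,
                         epsilon: float = DEFAULT_EPSILON,
                         n_cut_levels: int = 8) -> DNBResult:
    """Slide windows over the time course and locate the CI peak.

    Each window pools the replicates of ``window_width`` consecutive time
    points; the default width is the smallest one giving at least 9 pooled
    samples per window (capped at one less than the number of time points).
    Candidate modules are formed once from the whole course; within each
    window every candidate is scored and the maximum-CI module recorded.
    The tipping point is the earliest window attaining the global maximum
    CI, and its winning module is the DNB gene set.
    """
    width = _resolve_window_width(tc, window_width)
    windows = _windows(tc, width)
    gene_arr = np.asarray(tc.gene_ids)
    sd_course = tc.values.std(axis=1, ddof=1)
    if (sd_course == 0).any():
        n_bad = int((sd_course == 0).sum())
        warnings.warn(f"dropping {n_bad} constant gene(s)", stacklevel=2)
        tc = tc.subset_genes(gene_arr[sd_course > 0].tolist())
        gene_arr = np.asarray(tc.gene_ids)

    pool = _CandidatePool(tc, min_size, max_size, n_cut_levels)
    window_mats = []
    for w_times in windows:
        window = _window_matrix(tc, w_times)
        if window.shape[0] < 3:
            raise ParameterError(
                f"window at times {w_times} has only {window.shape[0]} pooled "
                "samples; use a larger window_width"
            )
        window_mats.append(window)
        pool.add_window_seeds(window)

    per_window: list[DNBWindowStats] = []
    for w_idx, (w_times, window) in enumerate(zip(windows, window_mats)):
        corr_abs, sd = _abs_corr(window)
        best: DNBWindowStats | None = None
        for idx in pool.all_candidates:
            pcc_in, pcc_out, sd_in, ci = _stats_from_corr(
                corr_abs, sd, idx, epsilon)
            if best is None or ci > best.ci:
                best = DNBWindowStats(
                    window_index=w_idx,
                    window_times=w_times,
                    module_gene_ids=frozenset(gene_arr[idx].tolist()),
                    pcc_in=pcc_in,
                    pcc_out=pcc_out,
                    sd_in=sd_in,
                    ci=ci,
                    n_samples=window.shape[0],
                )
        assert best is not None
        per_window.append(best)

    ci = np.array([w.ci for w in per_window])
    tp = int(np.argmax(ci))  # argmax returns the earliest maximum
    return DNBResult(
        per_window=tuple(per_window),
        tp_window_index=tp,
        dnb_gene_ids=per_window[tp].module_gene_ids,
        window_width=width,
    )


# ---------------------------------------------------------------------------
# permutation significance of the CI peak
# ---------------------------------------------------------------------------

def _group_by_size(local_idx: list[np.ndarray]) -> dict[int, np.ndarray]:
    """Stack candidate index vectors of equal size into (count x size) blocks."""
    groups: dict[int, list[np.ndarray]] = {}
    for li in local_idx:
        groups.setdefault(li.size, []).append(li)
    return {s: np.vstack(v) for s, v in groups.items()}


def _selection_statistic(values: np.ndarray, windows_cols: list[np.ndarray],
                         size_groups: dict[int, np.ndarray],
                         union: np.ndarray, bg: np.ndarray,
                         epsilon: float) -> float:
    """Max over windows and candidates of the (subsampled-PCC_out) CI.

    ``values`` is genes x samples; ``size_groups`` holds the candidates'
    positions within ``union``, stacked by module size.  PCC_out is
    estimated against the fixed background gene subsample ``bg``.
    """
    best = -np.inf
    n_bg = bg.size
    for cols in windows_cols:
        win_u = values[np.ix_(union, cols)].T
        win_b = values[np.ix_(bg, cols)].T
        zu, sd_u = _standardize_columns(win_u)
        zb, _ = _standardize_columns(win_b)
        cb_rows = np.abs(zu.T @ zb).sum(axis=1)
        for s, idx_mat in size_groups.items():
            sub = np.abs(np.einsum("tgi,tgj->gij", zu[:, idx_mat],
                                   zu[:, idx_mat], optimize=True))
            pcc_in = (sub.sum(axis=(1, 2)) - s) / (s * (s - 1))
            pcc_out = cb_rows[idx_mat].sum(axis=1) / (s * n_bg)
            sd_in = sd_u[idx_mat].mean(axis=1)
            ci = sd_in * pcc_in / np.maximum(pcc_out, epsilon)
            best = max(best, float(ci.max()))
    return best


def permutation_significance(tc: ExpressionTimeCourse, result: DNBResult,
                             n_perm: int = 99, seed: int = 0,
                             epsilon: float = DEFAULT_EPSILON,
                             min_size: int = DEFAULT_MIN_SIZE,
                             max_size: int = DEFAULT_MAX_SIZE,
                             n_cut_levels: int = 8,
                             n_background: int = 300,
                             test_window_width: int | None = None) -> float:
    """Permutation p-value for the observed CI peak.

    Null model: sample-to-time assignments are permuted uniformly and the
    entire module selection — max CI over the assignment-invariant candidate
    pool and over all test windows — is recomputed, so the observed and
    null statistics are exchangeable under the null and the test is exactly
    calibrated.

    The statistic is evaluated on narrow test windows (default: the
    smallest width giving >= 3 pooled samples, i.e. single time points in
    a triplicate design).  Permuting sample-to-time assignments relocates
    but cannot destroy sample-level covariance, so what the test actually
    probes is whether the high-dispersion, tightly correlated samples are
    *aligned* with a time label; narrow windows are the most sensitive to
    that alignment.  PCC_out is estimated against a fixed, seeded subsample
    of ``n_background`` genes to keep the loop affordable; the same
    estimator is used for the observed statistic.  The p-value uses the
    add-one estimator ``(1 + #{null >= observed}) / (n_perm + 1)``.
    """
    if n_perm < 19:
        raise ParameterError("n_perm must be >= 19 (p resolution too coarse)")
    rng = np.random.default_rng(seed)
    if test_window_width is None:
        min_reps = min(tc.sample_indices_at([t]).size for t in tc.times)
        test_window_width = max(1, int(np.ceil(3 / min_reps)))
    windows = _windows(tc, test_window_width)
    windows_cols = [tc.sample_indices_at(w) for w in windows]

    pool = _CandidatePool(tc, min_size, max_size, n_cut_levels)
    candidates = pool.invariant
    union = np.unique(np.concatenate(candidates))
    local = {int(g): i for i, g in enumerate(union)}
    local_idx = [np.fromiter((local[int(i)] for i in idx), dtype=int)
                 for idx in candidates]
    size_groups = _group_by_size(local_idx)
    n_genes = tc.values.shape[0]
    bg = rng.choice(n_genes, size=min(n_background, n_genes), replace=False)
    bg = np.sort(bg)

    observed = _selection_statistic(tc.values, windows_cols, size_groups,
                                    union, bg, epsilon)
    n_samples = tc.values.shape[1]
    exceed = 0
    for _ in range(n_perm):
        perm = rng.permutation(n_samples)
        null_stat = _selection_statistic(tc.values[:, perm], windows_cols,
                                         size_groups, union, bg, epsilon)
        if null_stat >= observed:
            exceed += 1
    return (1 + exceed) / (n_perm + 1)


def with_significance(tc: ExpressionTimeCourse, result: DNBResult,
                      n_perm: int = 99, seed: int = 0,
                      epsilon: float = DEFAULT_EPSILON) -> DNBResult:
    """Return a copy of ``result`` annotated with its permutation p-value."""
    p = permutation_significance(tc, result, n_perm=n_perm, seed=seed,
                                 epsilon=epsilon)
    return replace(result, permutation_p=p, n_permutations=n_perm, seed=seed)
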
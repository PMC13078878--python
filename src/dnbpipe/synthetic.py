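"""Seeded simulator of time-course expression with a planted critical transition.

The generator plants one gene module whose behaviour near a chosen tipping
time reproduces the three hallmarks of a dynamic network biomarker: the
module's within-group correlation and per-gene dispersion rise sharply while
its correlation with the rest of the transcriptome falls.  A shared latent
factor model makes all three properties hold simultaneously and keeps the
expected statistics available in closed form for testing.

Per sample at time ``t`` (replicate ``r``) the model draws a module factor
``z ~ N(0,1)`` and a global factor ``w ~ N(0,1)`` and emits, on the log
scale,

    module gene g:      x = mu_g + a(t) * z + b(t) * w + sigma * eps_g
    background gene h:  x = mu_h + c * w            + sigma * eps_h

with a Gaussian bump ``K(t) = exp(-(t - t_tau)^2 / (2 lambda^2))`` centred on
the tipping time ``t_tau`` driving the loading schedules

    a(t) = a0 + (a1 - a0) * K(t)        (module coupling rises at t_tau)
    b(t) = b0 * (1 - delta * K(t))      (coupling to the background falls).

At the bump peak the expected within-module Pearson correlation is
``(a^2 + b^2) / (a^2 + b^2 + sigma^2)`` and the module-to-background
correlation is proportional to ``b(t) * c``, so the planted transition is
analytically checkable.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import ParameterError
from .io import ExpressionTimeCourse, GeneSetCollection

DEFAULT_TIME_POINTS: tuple[float, ...] = (0, 1, 2, 3, 4, 5, 6, 7)


@dataclass(frozen=True)
class SyntheticParams:
    """Parameters of the planted-transition factor model.

    Defaults emulate a bulk RNA-seq drug-treatment time course: 2000 genes,
    a 50-gene module, 8 daily time points with 3 replicates each, and a
    tipping point planted at day 2 with bump width half the sampling
    interval.
    """

    n_genes: int = 2000
    module_size: int = 50
    time_points: tuple[float, ...] = DEFAULT_TIME_POINTS
    replicates_per_time: int = 3
    tp_index: int = 2
    module_loading_base: float = 0.2      # a0
    module_loading_peak: float = 2.0      # a1
    global_loading_module_base: float = 0.5  # b0
    global_loading_background: float = 0.5   # c
    loading_drop_fraction: float = 0.8    # delta
    bump_width: float | None = None       # lambda; default 0.5 * median dt
    noise_sd: float = 1.0                 # sigma
    baseline_mean: float = 5.0            # mu ~ N(baseline_mean, baseline_sd)
    baseline_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.module_size >= self.n_genes:
            raise ParameterError("module_size must be < n_genes")
        if self.module_size < 2:
            raise ParameterError("module_size must be >= 2")
        if len(self.time_points) < 2:
            raise ParameterError("need >= 2 time points")
        diffs = np.diff(np.asarray(self.time_points, dtype=float))
        if not (diffs > 0).all():
            raise ParameterError("time_points must be strictly increasing")
        if not 0 <= self.tp_index < len(self.time_points):
            raise ParameterError("tp_index out of range")
        if self.replicates_per_time < 2:
            raise ParameterError("replicates_per_time must be >= 2")
        loadings = (self.module_loading_base, self.module_loading_peak,
                    self.global_loading_module_base,
                    self.global_loading_background)
        if not np.isfinite(loadings).all():
            raise ParameterError("loadings must be finite")
        if self.module_loading_base < 0:
            raise ParameterError("module_loading_base must be >= 0")
        if self.module_loading_peak < self.module_loading_base:
            raise ParameterError("module_loading_peak must be >= base")
        if not 0 <= self.loading_drop_fraction <= 1:
            raise ParameterError("loading_drop_fraction must be in [0, 1]")
        if self.bump_width is not None and self.bump_width <= 0:
            raise ParameterError("bump_width must be > 0")
        if self.noise_sd < 0:
            raise ParameterError("noise_sd must be >= 0")

    @property
    def resolved_bump_width(self) -> float:
        if self.bump_width is not None:
            return self.bump_width
        dt = float(np.median(np.diff(np.asarray(self.time_points, float))))
        return 0.5 * dt

    def loading_schedule(self, t: float) -> tuple[float, float]:
        """Return (a(t), b(t)) for a time point."""
        t_tau = float(self.time_points[self.tp_index])
        lam = self.resolved_bump_width
        k = float(np.exp(-((t - t_tau) ** 2) / (2.0 * lam ** 2)))
        a = self.module_loading_base + (
            self.module_loading_peak - self.module_loading_base) * k
        b = self.global_loading_module_base * (
            1.0 - self.loading_drop_fraction * k)
        return a, b

    def expected_module_correlation(self, t: float) -> float:
        """Theoretical within-module Pearson correlation at time ``t``."""
        a, b = self.loading_schedule(t)
        shared = a * a + b * b
        return shared / (shared + self.noise_sd ** 2)


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth of a simulated course: planted tipping point and module."""

    tp_index: int
    module_gene_ids: frozenset[str]
    params: SyntheticParams
    baseline_means: tuple[float, ...] = field(default=(), repr=False)

    @property
    def tp_time(self) -> float:
        return float(self.params.time_points[self.tp_index])

    def to_json(self, path: str | Path) -> None:
        payload = {
            "tp_index": self.tp_index,
            "tp_time": self.tp_time,
            "module_gene_ids": sorted(self.module_gene_ids),
            "params": asdict(replace(self.params)),
            "baseline_means": list(self.baseline_means),
        }
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticTruth":
        payload = json.loads(Path(path).read_text())
        params = dict(payload["params"])
        params["time_points"] = tuple(params["time_points"])
        return cls(
            tp_index=payload["tp_index"],
            module_gene_ids=frozenset(payload["module_gene_ids"]),
            params=SyntheticParams(**params),
            baseline_means=tuple(payload.get("baseline_means", ())),
        )


def _gene_ids(n_genes: int) -> list[str]:
    width = max(4, len(str(n_genes)))
    return [f"G{i:0{width}d}" for i in range(1, n_genes + 1)]


def simulate_timecourse(
    params: SyntheticParams,
    exponentiate: bool = False,
) -> tuple[ExpressionTimeCourse, SyntheticTruth]:
    """Simulate a seeded expression time course with a planted transition.

    Returns the expression object (genes x samples, samples ordered
    time-major then replicate) and the ground truth for recovery tests.
    Identical parameters (including seed) give bit-identical output.
    With ``exponentiate`` the log-scale values are mapped through
    ``2**x - 1`` to a pseudo-count scale (``is_log=False``), handy for
    exercising normalization and I/O round trips.
    """
    rng = np.random.default_rng(params.seed)
    n, m = params.n_genes, params.module_size
    gene_ids = _gene_ids(n)

    mu = rng.normal(params.baseline_mean, params.baseline_sd, size=n)
    module_idx = np.sort(rng.choice(n, size=m, replace=False))
    is_module = np.zeros(n, dtype=bool)
    is_module[module_idx] = True

    times = [float(t) for t in params.time_points]
    n_samples = len(times) * params.replicates_per_time
    z = rng.standard_normal(n_samples)
    w = rng.standard_normal(n_samples)
    eps = rng.standard_normal((n, n_samples))

    values = np.empty((n, n_samples))
    sample_ids: list[str] = []
    sample_time: dict[str, float] = {}
    sample_rep: dict[str, str] = {}
    col = 0
    for t in times:
        a, b = params.loading_schedule(t)
        for rep in range(1, params.replicates_per_time + 1):
            x = mu + params.noise_sd * eps[:, col]
            x[is_module] += a * z[col] + b * w[col]
            x[~is_module] += params.global_loading_background * w[col]
            values[:, col] = x
            sid = f"t{t:g}_r{rep}"
            sample_ids.append(sid)
            sample_time[sid] = t
            sample_rep[sid] = str(rep)
            col += 1

    if exponentiate:
        values = np.exp2(values) - 1.0
    tc = ExpressionTimeCourse(
        gene_ids=gene_ids,
        sample_ids=sample_ids,
        values=values,
        sample_time=sample_time,
        sample_replicate=sample_rep,
        is_log=not exponentiate,
    )
    truth = SyntheticTruth(
        tp_index=params.tp_index,
        module_gene_ids=frozenset(gene_ids[i] for i in module_idx),
        params=params,
        baseline_means=tuple(mu.tolist()),
    )
    return tc, truth


def simulate_gene_sets(truth: SyntheticTruth, n_sets: int = 20,
                       set_size: int = 50, seed: int = 0) -> GeneSetCollection:
    """Gene-set collection with one set matching the planted module.

    ``planted_module_set`` is a copy of the planted module truncated or
    padded (with random non-module genes) to ``set_size``; the remaining
    sets are uniform random draws from all genes.
    """
    if n_sets < 1:
        raise ParameterError("n_sets must be >= 1")
    params = truth.params
    if set_size > params.n_genes:
        raise ParameterError("set_size must be <= n_genes")
    rng = np.random.default_rng(seed)
    all_genes = np.array(_gene_ids(params.n_genes))
    module = sorted(truth.module_gene_ids)

    if set_size <= len(module):
        planted = module[:set_size]
    else:
        pool = np.array(sorted(set(all_genes) - set(module)))
        pad = rng.choice(pool, size=set_size - len(module), replace=False)
        planted = module + sorted(pad.tolist())

    sets: dict[str, list[str]] = {"planted_module_set": list(planted)}
    desc = {"planted_module_set": "copy of the planted DNB module"}
    width = max(2, len(str(n_sets)))
    for i in range(1, n_sets):
        name = f"random_set_{i:0{width}d}"
        members = rng.choice(all_genes, size=set_size, replace=False)
        sets[name] = sorted(members.tolist())
        desc[name] = "uniform random gene draw"
    return GeneSetCollection(sets=sets, description=desc)
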
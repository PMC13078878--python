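"""Containers and readers/writers for time-course expression data and gene sets.

The canonical on-disk representation is a dense TSV expression matrix (first
column gene id, remaining columns samples) with a sample-metadata sidecar TSV
(``sample_id``, ``time``, ``replicate``).  Sample headers of the form
``t{time}_r{rep}`` can be parsed as a fallback when no metadata file is given.
Gene sets use the GMT dialect: one set per line, tab-separated name,
description, then members.  All readers tolerate gzip (by file extension).
"""

from __future__ import annotations

import gzip
import logging
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import IO, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import EmptyResultError, FormatError, ParameterError

logger = logging.getLogger(__name__)

_HEADER_RE = re.compile(r"^t(?P<time>[0-9.+-eE]+)_r(?P<rep>.+)$")


def _open_text(path: str | Path, mode: str = "rt") -> IO[str]:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)  # type: ignore[return-value]
    return open(path, mode)


@dataclass
class ExpressionTimeCourse:
    """A gene x sample expression matrix with ordered time/replicate labels.

    Values are understood to be on a log-like normalized scale (``is_log``)
    unless stated otherwise; the dynamic-network statistics downstream only
    assume a roughly continuous expression measure.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray  # genes x samples, float64
    sample_time: dict[str, float]
    sample_replicate: dict[str, str]
    is_log: bool = True

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.validate()

    # -- validation ------------------------------------------------------
    def validate(self) -> None:
        if len(set(self.gene_ids)) != len(self.gene_ids):
            dup = pd.Index(self.gene_ids)
            dup = dup[dup.duplicated()].tolist()
            raise FormatError(f"duplicate gene id(s): {dup[:5]}")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise FormatError("duplicate sample ids")
        missing = [s for s in self.sample_ids if s not in self.sample_time]
        if missing:
            raise FormatError(
                f"sample(s) missing from metadata: {', '.join(missing[:5])}"
            )
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise FormatError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if not np.isfinite(self.values).all():
            g, s = np.argwhere(~np.isfinite(self.values))[0]
            raise FormatError(
                f"non-finite value at gene '{self.gene_ids[g]}', "
                f"sample '{self.sample_ids[s]}'"
            )
        if len(self.times) < 2:
            raise FormatError("need at least 2 distinct time points")

    # -- views -----------------------------------------------------------
    @property
    def times(self) -> np.ndarray:
        """Distinct time points, ascending."""
        return np.unique([self.sample_time[s] for s in self.sample_ids])

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def sample_indices_at(self, times: Sequence[float]) -> np.ndarray:
        """Column indices of samples whose time is in ``times``."""
        wanted = set(float(t) for t in times)
        return np.array(
            [i for i, s in enumerate(self.sample_ids)
             if float(self.sample_time[s]) in wanted],
            dtype=int,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids,
                            columns=self.sample_ids)

    def subset_genes(self, keep: Sequence[str]) -> "ExpressionTimeCourse":
        keep_set = set(keep)
        idx = [i for i, g in enumerate(self.gene_ids) if g in keep_set]
        return replace(
            self,
            gene_ids=[self.gene_ids[i] for i in idx],
            values=self.values[idx],
        )

    def sorted_by_time(self) -> "ExpressionTimeCourse":
        """Samples reordered by (time, replicate label); gene order kept."""
        order = sorted(
            range(len(self.sample_ids)),
            key=lambda i: (float(self.sample_time[self.sample_ids[i]]),
                           str(self.sample_replicate.get(self.sample_ids[i], ""))),
        )
        return replace(
            self,
            sample_ids=[self.sample_ids[i] for i in order],
            values=self.values[:, order],
        )


@dataclass
class GeneSetCollection:
    """Named gene sets with free-text descriptions (GMT-serializable)."""

    sets: dict[str, list[str]] = field(default_factory=dict)
    description: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise FormatError(f"gene set '{name}' is empty")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self) -> Iterator[str]:
        return iter(self.sets)

    def __getitem__(self, name: str) -> list[str]:
        return self.sets[name]


# ---------------------------------------------------------------------------
# expression matrix I/O
# ---------------------------------------------------------------------------

def _fmt_num(x: float) -> str:
    return f"{x:g}"


def write_timecourse(tc: ExpressionTimeCourse, matrix_path: str | Path,
                     metadata_path: str | Path) -> None:
    df = tc.to_frame()
    df.index.name = "gene_id"
    df.to_csv(matrix_path, sep="\t", float_format="%.10g")
    meta = pd.DataFrame({
        "sample_id": tc.sample_ids,
        "time": [_fmt_num(tc.sample_time[s]) for s in tc.sample_ids],
        "replicate": [tc.sample_replicate.get(s, "") for s in tc.sample_ids],
    })
    meta.to_csv(metadata_path, sep="\t", index=False)


def _metadata_from_headers(sample_ids: Sequence[str]) -> tuple[dict, dict]:
    sample_time: dict[str, float] = {}
    sample_rep: dict[str, str] = {}
    for s in sample_ids:
        m = _HEADER_RE.match(s)
        if m is None:
            raise FormatError(
                f"no metadata file given and sample id '{s}' does not follow "
                "the 't{time}_r{rep}' convention"
            )
        sample_time[s] = float(m.group("time"))
        sample_rep[s] = m.group("rep")
    return sample_time, sample_rep


def load_timecourse(matrix_path: str | Path,
                    metadata_path: str | Path | None = None,
                    is_log: bool = True) -> ExpressionTimeCourse:
    """Read a TSV expression matrix plus its sample-metadata sidecar.

    With ``metadata_path=None``, times and replicates are parsed from
    ``t{time}_r{rep}`` sample headers.  Samples are reordered by ascending
    time for downstream iteration.
    """
    raw = pd.read_csv(matrix_path, sep="\t", index_col=0, dtype=str)
    gene_ids = raw.index.astype(str).tolist()
    if raw.index.duplicated().any():
        dup = raw.index[raw.index.duplicated()].tolist()
        raise FormatError(f"duplicate gene id(s) in matrix: {dup[:5]}")
    sample_ids = [str(c) for c in raw.columns]

    values = raw.apply(pd.to_numeric, errors="coerce").to_numpy(dtype=float)
    bad = np.argwhere(~np.isfinite(values))
    if bad.size:
        g, s = bad[0]
        raise FormatError(
            f"non-numeric or missing value at row '{gene_ids[g]}', "
            f"column '{sample_ids[s]}' in {matrix_path}"
        )

    if metadata_path is not None:
        meta = pd.read_csv(metadata_path, sep="\t", dtype=str)
        required = {"sample_id", "time", "replicate"}
        if not required.issubset(meta.columns):
            raise FormatError(
                f"metadata must have columns {sorted(required)}; "
                f"found {list(meta.columns)}"
            )
        sample_time = {}
        sample_rep = {}
        for _, row in meta.iterrows():
            try:
                sample_time[row["sample_id"]] = float(row["time"])
            except (TypeError, ValueError) as exc:
                raise FormatError(
                    f"non-numeric time '{row['time']}' for sample "
                    f"'{row['sample_id']}'"
                ) from exc
            sample_rep[row["sample_id"]] = str(row["replicate"])
        uncovered = [s for s in sample_ids if s not in sample_time]
        if uncovered:
            raise FormatError(
                "metadata is missing sample(s): " + ", ".join(uncovered[:5])
            )
    else:
        sample_time, sample_rep = _metadata_from_headers(sample_ids)

    tc = ExpressionTimeCourse(
        gene_ids=gene_ids,
        sample_ids=sample_ids,
        values=values,
        sample_time={s: sample_time[s] for s in sample_ids},
        sample_replicate={s: sample_rep.get(s, "") for s in sample_ids},
        is_log=is_log,
    )
    return tc.sorted_by_time()


# ---------------------------------------------------------------------------
# normalization / filtering
# ---------------------------------------------------------------------------

def filter_and_normalize(tc: ExpressionTimeCourse, min_mean: float = 0.0,
                         log_transform: bool = False,
                         pseudo_count: float = 1.0) -> ExpressionTimeCourse:
    """Drop low-mean and constant genes; optionally log2-transform.

    Genes whose overall mean is below ``min_mean`` are removed, then genes
    with zero variance across all samples are removed (Pearson correlation
    is undefined for them) with a logged warning.  When ``log_transform`` is
    set, values become ``log2(value + pseudo_count)``.
    """
    if min_mean < 0:
        raise ParameterError("min_mean must be >= 0")
    if log_transform and pseudo_count <= 0:
        raise ParameterError("pseudo_count must be > 0 when log-transforming")

    means = tc.values.mean(axis=1)
    keep = means >= min_mean
    variances = tc.values.var(axis=1)
    constant = variances == 0.0
    n_const = int((keep & constant).sum())
    if n_const:
        logger.warning("dropping %d constant gene(s)", n_const)
    keep &= ~constant
    if not keep.any():
        raise EmptyResultError(
            "all genes removed by filtering; lower min_mean or check input"
        )
    values = tc.values[keep]
    if log_transform:
        values = np.log2(values + pseudo_count)
    return replace(
        tc,
        gene_ids=[g for g, k in zip(tc.gene_ids, keep) if k],
        values=values,
        is_log=tc.is_log or log_transform,
    )


# ---------------------------------------------------------------------------
# GMT I/O
# ---------------------------------------------------------------------------

def load_gmt(path: str | Path) -> GeneSetCollection:
    """Parse a GMT gene-set file (name, description, members per line)."""
    sets: dict[str, list[str]] = {}
    desc: dict[str, str] = {}
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}:{lineno}: expected >= 3 tab-separated fields, "
                    f"got {len(fields)}"
                )
            name, description, *members = fields
            members = [m for m in members if m]
            if not members:
                raise FormatError(f"{path}:{lineno}: set '{name}' has no members")
            if name in sets:
                raise FormatError(f"{path}:{lineno}: duplicate set name '{name}'")
            # de-duplicate while preserving order
            sets[name] = list(dict.fromkeys(members))
            desc[name] = description
    return GeneSetCollection(sets=sets, description=desc)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with _open_text(path, "wt") as fh:
        for name, members in collection.sets.items():
            desc = collection.description.get(name, "")
            fh.write("\t".join([name, desc, *members]) + "\n")
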
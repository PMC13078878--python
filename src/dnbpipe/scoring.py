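"""Gene-set over-representation and rank-AUC signature scoring.

Over-representation uses the exact upper-tail hypergeometric test: for a
query of ``n`` genes drawn from a universe of ``N`` genes of which ``K``
belong to a set, the p-value of observing ``k`` or more overlaps is
``P[X >= k]`` with ``X ~ Hypergeometric(N, K, n)``, adjusted across sets by
Benjamini-Hochberg.

Signature activity per sample follows the recovery-curve AUC idea: rank all
genes by expression (descending), walk the top ``x`` fraction of ranks
accumulating gene-set hits, and report the area under that step curve
normalized by the maximal achievable area.  Being rank-based, the score is
invariant under any strictly increasing transformation of the sample's
expression values.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .errors import ParameterError
from .io import ExpressionTimeCourse, GeneSetCollection

logger = logging.getLogger(__name__)

DEFAULT_TOP_FRACTION = 0.05

ENRICHMENT_COLUMNS = ["set_name", "universe_size", "set_size_in_universe",
                      "query_size", "overlap", "p_value", "fdr"]


@dataclass(frozen=True)
class SignatureScore:
    """Rank-AUC activity of one gene set in one sample."""

    sample_id: str
    set_name: str
    score: float
    top_fraction: float
    n_genes_ranked: int


def hypergeometric_enrichment(query: Iterable[str],
                              collection: GeneSetCollection,
                              universe: Iterable[str]) -> pd.DataFrame:
    """Exact upper-tail hypergeometric over-representation with BH FDR.

    Sets are intersected with the universe before testing; sets with no
    member in the universe are skipped with a warning.  Returns one row per
    tested set, sorted by p-value ascending.
    """
    universe = set(universe)
    query = set(query)
    if not query:
        raise ParameterError("query gene set is empty")
    if not universe:
        raise ParameterError("universe is empty")
    outside = query - universe
    if outside:
        logger.warning("dropping %d query gene(s) outside the universe",
                       len(outside))
        query &= universe
        if not query:
            raise ParameterError("no query gene is in the universe")

    N, n = len(universe), len(query)
    rows = []
    for name, members in collection.sets.items():
        in_universe = universe.intersection(members)
        K = len(in_universe)
        if K == 0:
            logger.warning("set '%s' has no member in the universe; skipped",
                           name)
            continue
        k = len(query & in_universe)
        p = float(hypergeom.sf(k - 1, N, K, n))
        rows.append((name, N, K, n, k, min(p, 1.0)))
    if not rows:
        return pd.DataFrame(columns=ENRICHMENT_COLUMNS)
    df = pd.DataFrame(rows, columns=ENRICHMENT_COLUMNS[:-1])
    df["fdr"] = multipletests(df["p_value"], method="fdr_bh")[1]
    return df.sort_values("p_value", kind="stable").reset_index(drop=True)


def _ranked_gene_order(values: np.ndarray, gene_ids: np.ndarray) -> np.ndarray:
    """Indices ordering genes by expression descending, ties by gene id."""
    return np.lexsort((gene_ids, -values))


def _auc_from_hits(hits: np.ndarray, n_set_ranked: int, L: int) -> float:
    """Normalized area under the cumulative hit curve over the top L ranks."""
    raw = float(np.cumsum(hits[:L]).sum())
    s_eff = min(n_set_ranked, L)
    if s_eff == 0:
        return 0.0
    ideal = s_eff * (s_eff + 1) / 2 + (L - s_eff) * s_eff
    return raw / ideal


def auc_signature_score(expression: pd.Series | Sequence[float],
                        gene_set: Iterable[str],
                        top_fraction: float = DEFAULT_TOP_FRACTION,
                        gene_ids: Sequence[str] | None = None,
                        sample_id: str = "",
                        set_name: str = "") -> SignatureScore:
    """Recovery-curve AUC of one gene set in one sample.

    Genes are ranked by expression descending with ties broken by ascending
    gene id (a stable, platform-independent rule).  Over the top
    ``L = ceil(top_fraction * G)`` ranks the cumulative count of gene-set
    members forms a step curve whose area, divided by the maximal achievable
    area (all rankable members packed at the top), is the score in [0, 1].
    """
    if isinstance(expression, pd.Series):
        values = expression.to_numpy(dtype=float)
        ids = np.asarray(expression.index.astype(str))
    else:
        values = np.asarray(expression, dtype=float)
        if gene_ids is None:
            raise ParameterError("gene_ids required when expression is an array")
        ids = np.asarray([str(g) for g in gene_ids])
    if values.size == 0:
        raise ParameterError("expression vector is empty")
    if not 0 < top_fraction <= 1:
        raise ParameterError("top_fraction must be in (0, 1]")

    member = np.isin(ids, np.asarray(sorted(set(gene_set))))
    n_ranked = int(member.sum())
    G = values.size
    L = math.ceil(top_fraction * G)
    if n_ranked == 0:
        logger.warning("gene set '%s' shares no gene with the ranking; "
                       "score set to 0", set_name or "<unnamed>")
        score = 0.0
    else:
        order = _ranked_gene_order(values, ids)
        score = _auc_from_hits(member[order], n_ranked, L)
    return SignatureScore(
        sample_id=sample_id,
        set_name=set_name,
        score=score,
        top_fraction=top_fraction,
        n_genes_ranked=G,
    )


def score_matrix(tc: ExpressionTimeCourse, collection: GeneSetCollection,
                 top_fraction: float = DEFAULT_TOP_FRACTION) -> pd.DataFrame:
    """Rank-AUC scores for every (sample, set) pair, long format."""
    if not 0 < top_fraction <= 1:
        raise ParameterError("top_fraction must be in (0, 1]")
    ids = np.asarray(tc.gene_ids)
    G = ids.size
    L = math.ceil(top_fraction * G)
    membership = {
        name: np.isin(ids, np.asarray(sorted(set(members))))
        for name, members in collection.sets.items()
    }
    rows = []
    for s_idx, sample in enumerate(tc.sample_ids):
        order = _ranked_gene_order(tc.values[:, s_idx], ids)
        for name, member in membership.items():
            n_ranked = int(member.sum())
            score = _auc_from_hits(member[order], n_ranked, L) if n_ranked \
                else 0.0
            rows.append((sample, name, score))
    return pd.DataFrame(rows, columns=["sample_id", "set_name", "score"])
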
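"""Enrichment statistics and cell-profile module scoring.

Three families of tests live here: Fisher's-exact / hypergeometric
enrichment of one gene set in another over an explicit background
(e.g. DE transcripts within co-expression modules), over-representation
analysis (ORA) of a query against a GMT collection with BH correction,
and AUCell-style module activity scoring of per-cell rankings (area under
the gene-recovery curve within a top-rank window) with rank-sum group
comparisons per cell type.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import GeneSetCollection
from .demod import adjust_bh
from .rrho import hypergeom_tail

logger = logging.getLogger(__name__)


@dataclass
class EnrichmentRow:
    """One enrichment test: overlap k of an n-gene query with a K-gene set
    over an N-gene background."""

    name: str
    k: int
    K: int
    n: int
    N: int
    odds_ratio: float
    p: float
    continuity: bool = False
    q: float | None = None


def fisher_enrichment(query, target, background, name: str = "") -> EnrichmentRow:
    """Hypergeometric / Fisher enrichment of query in target over background.

    The 2x2 table is (in/out query) x (in/out target) over the background;
    p is the exact hypergeometric upper tail; the odds ratio is ad/bc with
    0.5 added to every cell only when some cell is zero (flagged).
    """
    background = set(background)
    query = set(query)
    target = set(target)
    offenders = sorted((query | target) - background)
    if offenders:
        raise ValueError(f"genes outside background: {offenders[:10]}")
    N = len(background)
    n = len(query)
    K = len(target)
    k = len(query & target)
    a = k
    b = n - k
    c = K - k
    d = N - K - n + k
    # 0.5 continuity only where the raw ratio is undefined (zero denominator);
    # a zero overlap keeps its natural OR of exactly 0
    continuity = b * c == 0
    if continuity:
        odds = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
    else:
        odds = (a * d) / (b * c)
    p = hypergeom_tail(N, K, n, k)
    return EnrichmentRow(name=name, k=k, K=K, n=n, N=N,
                         odds_ratio=float(odds), p=float(p), continuity=continuity)


def ora(
    collection: GeneSetCollection,
    query,
    background,
) -> pd.DataFrame:
    """Over-representation of a query against every set in a collection.

    Sets are intersected with the explicit background before testing; sets
    with empty intersection are dropped.  BH correction across tested sets.
    """
    query = set(query)
    if not query:
        raise ValueError("empty query gene set")
    background = set(background)
    rows = []
    for name, genes in collection:
        target = set(genes) & background
        if not target:
            continue
        rows.append(fisher_enrichment(query & background, target, background, name=name))
    if not rows:
        return pd.DataFrame(
            columns=["name", "k", "K", "n", "N", "odds_ratio", "p", "continuity", "q"]
        ).set_index("name")
    out = pd.DataFrame([vars(r) for r in rows]).set_index("name")
    out["q"] = adjust_bh(out["p"].to_numpy())
    return out.sort_values("p", kind="stable")


def aucell_score(
    rankings: pd.DataFrame,
    module_genes,
    top_fraction: float = 0.05,
) -> pd.Series:
    """AUCell-style module activity per cell.

    rankings is a genes x cells DataFrame of ranks (1 = highest
    expression, each column a permutation of 1..N).  The score is the area
    under the cumulative module-gene recovery curve over the top
    floor(top_fraction * N) ranks, normalized by the window rectangle
    W * min(|M|, W), so a module packed at the very top of the ranking
    scores 1 - (|M| - 1) / (2 W) and a module entirely below the window 0.
    """
    module_genes = [g for g in module_genes if g in rankings.index]
    if not module_genes:
        raise ValueError("no module genes present in the ranking universe")
    N = rankings.shape[0]
    W = int(np.floor(top_fraction * N))
    if W < 1:
        raise ValueError("top_fraction * n_genes must be >= 1")
    M_eff = min(len(module_genes), W)
    ranks = rankings.loc[module_genes].to_numpy(dtype=float)
    inside = ranks <= W
    # each module gene at rank r contributes (W - r + 1) unit-width steps
    area = np.where(inside, W - ranks + 1.0, 0.0).sum(axis=0)
    auc = area / (W * M_eff)
    return pd.Series(auc, index=rankings.columns, name="auc")


def compare_module_scores(
    scores: pd.Series,
    groups: pd.Series,
    cell_types: pd.Series | None = None,
) -> pd.DataFrame:
    """Rank-sum comparison of AUC scores between two groups.

    With cell_types given, the comparison runs within each cell type and
    BH-adjusts across cell types; strata with fewer than two groups or
    fewer than two cells per group are skipped with a warning.
    """
    glabels = pd.unique(groups)
    if len(glabels) != 2:
        raise ValueError("exactly two groups required")
    strata = (
        {ct: scores.index[cell_types == ct] for ct in pd.unique(cell_types)}
        if cell_types is not None
        else {"all": scores.index}
    )
    rows = []
    for ct, cells in strata.items():
        s = scores.loc[cells]
        g = groups.loc[cells]
        x = s[g == glabels[0]]
        y = s[g == glabels[1]]
        if len(x) < 2 or len(y) < 2:
            logger.warning("stratum %r skipped: needs >= 2 cells per group", ct)
            continue
        stat, p = stats.mannwhitneyu(x, y, alternative="two-sided")
        rows.append({"stratum": ct, "statistic": float(stat), "p": float(p),
                     "median_" + str(glabels[0]): float(x.median()),
                     "median_" + str(glabels[1]): float(y.median())})
    if not rows:
        return pd.DataFrame(columns=["stratum", "statistic", "p", "q"]).set_index("stratum")
    out = pd.DataFrame(rows).set_index("stratum")
    out["q"] = adjust_bh(out["p"].to_numpy())
    return out
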
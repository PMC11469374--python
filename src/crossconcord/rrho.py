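"""Signed rank-rank hypergeometric overlap (RRHO).

Two differential-expression signatures defined on a shared gene universe
are each ranked by the signed score sign(log2FC) * -log10(p).  For every
pair of rank thresholds the overlap between the corresponding list
prefixes is scored by the exact hypergeometric upper tail, computed in log
space, and stored as -log10(p).  The map uses the stratified ("split")
construction: the two concordant quadrants scan from the down-most and
up-most ends of both lists, the two discordant quadrants scan opposite
ends, so agreement and opposition are read out separately.

Cells whose overlap falls below its expectation i*j/N store 0 (enrichment
tail only); -log10 values are capped.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

SCORE_CAP = 300.0
CONCORDANT_QUADRANTS = ("down-down", "up-up")
DISCORDANT_QUADRANTS = ("down-up", "up-down")
QUADRANTS = CONCORDANT_QUADRANTS + DISCORDANT_QUADRANTS


def hypergeom_tail(N: int, K: int, n: int, k: int) -> float:
    """Exact hypergeometric upper tail P(X >= k) for overlap k.

    X counts the intersection of a fixed K-subset with a random n-subset of
    an N-element universe.  Computed in log space via the survival function.
    """
    if not (0 <= k <= min(K, n) <= N and K <= N and n <= N and K >= 0 and n >= 0):
        raise ValueError(f"inconsistent hypergeometric counts N={N} K={K} n={n} k={k}")
    if k == 0:
        return 1.0
    return float(np.exp(stats.hypergeom.logsf(k - 1, N, K, n)))


def neglog10_hypergeom_tail(N: int, K: int, n: int, k: int, cap: float = SCORE_CAP) -> float:
    """-log10 of the hypergeometric upper tail, capped."""
    if k == 0:
        return 0.0
    if not (0 <= k <= min(K, n) <= N):
        raise ValueError(f"inconsistent hypergeometric counts N={N} K={K} n={n} k={k}")
    val = -stats.hypergeom.logsf(k - 1, N, K, n) / math.log(10)
    return float(min(val, cap))


def signed_score(p, log2fc, cap: float = SCORE_CAP):
    """Signed ranking score sign(log2FC) * min(-log10 p, cap).

    A zero log2FC is treated as positive sign; p = 0 is capped with a
    warning (the score saturates rather than overflowing).
    """
    p = np.atleast_1d(np.asarray(p, dtype=float))
    log2fc = np.atleast_1d(np.asarray(log2fc, dtype=float))
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if np.any(p == 0):
        logger.warning("p-value of 0 encountered; -log10 p capped at %g", cap)
    with np.errstate(divide="ignore"):
        mag = np.minimum(-np.log10(np.maximum(p, 0.0)), cap)
    sign = np.where(log2fc < 0, -1.0, 1.0)
    out = sign * mag
    return out if out.size > 1 else float(out[0])


@dataclass
class RankedSignature:
    """Genes strictly ordered by signed score (up-most first).

    Ties in score are broken by lexicographic gene id, recorded in
    ``tie_rule`` so the ordering is reproducible.
    """

    genes: np.ndarray  # ordered, up-most (most positive score) first
    scores: np.ndarray  # aligned with genes
    tie_rule: str = "lexicographic gene id"

    @classmethod
    def from_table(cls, genes, p, log2fc, cap: float = SCORE_CAP) -> "RankedSignature":
        genes = np.asarray(genes, dtype=object)
        if len(set(genes)) != len(genes):
            raise ValueError("duplicate genes in signature")
        scores = np.atleast_1d(signed_score(p, log2fc, cap=cap))
        order = np.lexsort((genes, -scores))
        return cls(genes=genes[order], scores=scores[order])

    @classmethod
    def from_de_table(cls, de: pd.DataFrame, cap: float = SCORE_CAP) -> "RankedSignature":
        return cls.from_table(de.index.to_numpy(), de["p"].to_numpy(), de["log2FC"].to_numpy(), cap)

    def __len__(self) -> int:
        return len(self.genes)


def map_orthologs(
    symbols_a,
    symbols_b,
    ortholog_map: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Align two cohorts' symbol spaces onto a shared gene universe.

    Without an explicit map, symbols are matched case-insensitively;
    symbols duplicated (case-insensitively) on either side are dropped with
    a warning, so the result is one-to-one.  With a map (columns symbol_a,
    symbol_b) only pairs present in both symbol lists are kept, again
    reduced to one-to-one.  Returns a DataFrame with columns key (canonical
    upper-case id), symbol_a, symbol_b.
    """
    symbols_a = list(symbols_a)
    symbols_b = list(symbols_b)
    if len(symbols_a) == 0 or len(symbols_b) == 0:
        raise ValueError("symbol lists must be nonempty")

    def unique_map(symbols, side):
        keyed: dict[str, str] = {}
        dropped = set()
        for s in symbols:
            key = str(s).upper()
            if key in keyed and keyed[key] != s:
                dropped.add(key)
            elif key in keyed:
                dropped.add(key)
            else:
                keyed[key] = s
        for key in dropped:
            keyed.pop(key, None)
        if dropped:
            logger.warning("dropped %d duplicated symbols on side %s", len(dropped), side)
        return keyed

    map_a = unique_map(symbols_a, "a")
    map_b = unique_map(symbols_b, "b")

    if ortholog_map is None:
        keys = sorted(set(map_a) & set(map_b))
        pairs = [(k, map_a[k], map_b[k]) for k in keys]
    else:
        counts_a = ortholog_map["symbol_a"].str.upper().value_counts()
        counts_b = ortholog_map["symbol_b"].str.upper().value_counts()
        pairs = []
        seen = set()
        for _, row in ortholog_map.iterrows():
            ka, kb = str(row["symbol_a"]).upper(), str(row["symbol_b"]).upper()
            if counts_a[ka] > 1 or counts_b[kb] > 1:
                continue  # many-to-many dropped
            if ka in map_a and kb in map_b and ka not in seen:
                pairs.append((ka, map_a[ka], map_b[kb]))
                seen.add(ka)
        pairs.sort()
    if not pairs:
        raise ValueError("no shared genes between the two symbol spaces")
    return pd.DataFrame(pairs, columns=["key", "symbol_a", "symbol_b"])


@dataclass
class RRHOMap:
    """Grids of -log10 hypergeometric overlap over rank-threshold pairs.

    One grid per quadrant, each of shape (ceil(N/step), ceil(N/step));
    grids[q][i, j] scores the overlap of the first thresholds[i] genes of
    signature a's quadrant-specific ordering with the first thresholds[j]
    of signature b's.  Concordant quadrants are down-down and up-up.
    """

    step: int
    n_genes: int
    thresholds: np.ndarray
    grids: dict[str, np.ndarray]
    summaries: dict[str, dict] = field(default_factory=dict)
    gene_sets: dict[str, list[str]] = field(default_factory=dict)

    def max_value(self, quadrants=QUADRANTS) -> float:
        return max(self.summaries[q]["max"] for q in quadrants)

    def signed_frames(self) -> dict[str, pd.DataFrame]:
        """Per-quadrant DataFrames; discordant quadrants carry negative sign."""
        out = {}
        for q, grid in self.grids.items():
            sgn = 1.0 if q in CONCORDANT_QUADRANTS else -1.0
            out[q] = pd.DataFrame(
                sgn * grid, index=self.thresholds, columns=self.thresholds
            )
        return out


def _orderings(sig: RankedSignature) -> dict[str, np.ndarray]:
    """Quadrant-end orderings: 'up' = most positive first, 'down' = most negative
    first, ties broken by lexicographic gene id in both."""
    down = np.lexsort((sig.genes, sig.scores))
    return {"up": sig.genes, "down": sig.genes[down]}


def compute_rrho_map(
    sig_a: RankedSignature,
    sig_b: RankedSignature,
    step: int | None = None,
    cap: float = SCORE_CAP,
) -> RRHOMap:
    """Stratified (split) RRHO map between two signatures on one universe.

    step defaults to floor(sqrt(N)).  Each cell stores
    -log10 P(X >= k) for the hypergeometric overlap k between the two rank
    prefixes, or 0 when k is below its expectation i*j/N.
    """
    genes_a = set(sig_a.genes)
    if genes_a != set(sig_b.genes):
        raise ValueError("signatures must share an identical gene universe")
    N = len(sig_a)
    if step is None:
        step = max(1, int(math.floor(math.sqrt(N))))
    n_cells = math.ceil(N / step)
    thresholds = np.minimum(np.arange(1, n_cells + 1) * step, N)

    ord_a = _orderings(sig_a)
    ord_b = _orderings(sig_b)
    edges = np.concatenate([[0], thresholds]).astype(float)

    grids: dict[str, np.ndarray] = {}
    summaries: dict[str, dict] = {}
    gene_sets: dict[str, list[str]] = {}
    for qa, qb in (("down", "down"), ("up", "up"), ("down", "up"), ("up", "down")):
        quad = f"{qa}-{qb}"
        pos_b = {g: i for i, g in enumerate(ord_b[qb])}
        pos_b_of_a = np.array([pos_b[g] for g in ord_a[qa]], dtype=float)
        # k(t_i, t_j) = #{genes in a-prefix t_i with b-position < t_j}
        counts, _, _ = np.histogram2d(
            np.arange(N, dtype=float), pos_b_of_a, bins=[edges, edges]
        )
        k_grid = counts.cumsum(axis=0).cumsum(axis=1)
        grid = np.zeros((n_cells, n_cells))
        expectation = np.outer(thresholds, thresholds) / N
        above = k_grid > expectation
        if above.any():
            I, J = np.nonzero(above)
            logsf = stats.hypergeom.logsf(
                k_grid[I, J] - 1, N, thresholds[I], thresholds[J]
            )
            grid[I, J] = np.minimum(-logsf / math.log(10), cap)
        grids[quad] = grid
        am = np.unravel_index(np.argmax(grid), grid.shape)
        summaries[quad] = {
            "max": float(grid[am]),
            "argmax_i": int(thresholds[am[0]]),
            "argmax_j": int(thresholds[am[1]]),
        }
        ti, tj = summaries[quad]["argmax_i"], summaries[quad]["argmax_j"]
        prefix_a = set(ord_a[qa][:ti])
        prefix_b = set(ord_b[qb][:tj])
        gene_sets[quad] = sorted(prefix_a & prefix_b)
    return RRHOMap(
        step=step, n_genes=N, thresholds=thresholds,
        grids=grids, summaries=summaries, gene_sets=gene_sets,
    )


def quadrant_genes(rrho_map: RRHOMap, quadrant: str) -> list[str]:
    """Overlap genes at the quadrant's best (argmax) rank-threshold cell."""
    if quadrant not in QUADRANTS:
        raise ValueError(f"unknown quadrant {quadrant!r}; expected one of {QUADRANTS}")
    return list(rrho_map.gene_sets[quadrant])


def align_signatures(
    de_a: pd.DataFrame,
    de_b: pd.DataFrame,
    ortholog_map: pd.DataFrame | None = None,
    cap: float = SCORE_CAP,
) -> tuple[RankedSignature, RankedSignature]:
    """Build two comparable signatures on the shared ortholog universe.

    DE tables are indexed by cohort-specific symbols; genes are renamed to
    the canonical (upper-case) shared key before ranking.
    """
    aligned = map_orthologs(de_a.index, de_b.index, ortholog_map)
    sub_a = de_a.loc[aligned["symbol_a"]]
    sub_b = de_b.loc[aligned["symbol_b"]]
    keys = aligned["key"].to_numpy()
    sig_a = RankedSignature.from_table(keys, sub_a["p"].to_numpy(), sub_a["log2FC"].to_numpy(), cap)
    sig_b = RankedSignature.from_table(keys, sub_b["p"].to_numpy(), sub_b["log2FC"].to_numpy(), cap)
    return sig_a, sig_b
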
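"""Weighted co-expression module detection and hub identification.

The network pipeline follows the standard weighted-correlation recipe:
unsigned soft-thresholded adjacency A_ij = |cor(x_i, x_j)|^beta over the
most variable genes, topological overlap TOM_ij = (sum_u A_iu A_uj + A_ij)
/ (min(k_i, k_j) + 1 - A_ij), average-linkage clustering of 1 - TOM with a
static height cut and eigengene-based merging, then per-module eigengenes
(first principal component) and kME (gene-eigengene correlation).

Hubs come from a mutual-information network: pairwise MI by
equal-frequency binning, weak edges thresholded away, and indirect edges
pruned by the data-processing inequality (within every triangle the
weakest edge is removed if it is weaker than both others).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from sklearn.metrics import mutual_info_score

from .containers import ExpressionMatrix

logger = logging.getLogger(__name__)

UNASSIGNED = "grey"

# size-ranked module colors, standard palette order
MODULE_COLORS = (
    "turquoise", "blue", "brown", "yellow", "green", "red", "black", "pink",
    "magenta", "purple", "greenyellow", "tan", "salmon", "cyan",
    "midnightblue", "lightcyan", "grey60", "lightgreen", "lightyellow",
    "royalblue", "darkred", "darkgreen", "darkturquoise", "darkgrey",
    "orange", "darkorange", "white", "skyblue", "saddlebrown", "steelblue",
    "paleturquoise", "violet", "darkolivegreen", "darkmagenta", "yellowgreen",
)


def _values(matrix) -> pd.DataFrame:
    return matrix.values if isinstance(matrix, ExpressionMatrix) else matrix


def select_variable_genes(matrix, n: int = 5000) -> list[str]:
    """Top-n genes by variance across all samples; ties broken by gene id."""
    if n <= 0:
        raise ValueError("n must be positive")
    values = _values(matrix)
    if n > len(values):
        raise ValueError(f"n={n} exceeds total genes {len(values)}")
    var = values.var(axis=1, ddof=1)
    order = sorted(values.index, key=lambda g: (-var[g], g))
    return order[:n]


def adjacency(matrix, beta: float) -> pd.DataFrame:
    """Unsigned soft-thresholded adjacency |cor|^beta with unit diagonal.

    Zero-variance genes get zero correlation to everything (warning).
    """
    values = _values(matrix)
    if values.shape[1] < 3:
        raise ValueError("adjacency requires at least 3 samples")
    arr = values.to_numpy(dtype=float)
    sd = arr.std(axis=1)
    zero_var = sd == 0
    if zero_var.any():
        logger.warning("%d zero-variance genes: correlations set to 0", zero_var.sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(arr)
    corr[np.isnan(corr)] = 0.0
    A = np.abs(np.clip(corr, -1, 1)) ** beta
    np.fill_diagonal(A, 1.0)
    return pd.DataFrame(A, index=values.index, columns=values.index)


def scale_free_fit(k: np.ndarray, n_bins: int = 10) -> tuple[float, float]:
    """Scale-free topology fit of a connectivity vector.

    Bins k into n_bins equal-width bins, regresses log10 p(k) on
    log10 mean(k) over occupied bins; returns (R^2, slope).
    """
    k = np.asarray(k, dtype=float)
    k = k[k > 0]
    if len(k) < n_bins:
        return 0.0, 0.0
    edges = np.linspace(k.min(), k.max() + 1e-12, n_bins + 1)
    which = np.clip(np.digitize(k, edges) - 1, 0, n_bins - 1)
    xs, ys = [], []
    for b in range(n_bins):
        mask = which == b
        if mask.sum() == 0:
            continue
        xs.append(np.log10(k[mask].mean()))
        ys.append(np.log10(mask.sum() / len(k)))
    if len(xs) < 3:
        return 0.0, 0.0
    xs, ys = np.asarray(xs), np.asarray(ys)
    slope, intercept = np.polyfit(xs, ys, 1)
    r = np.corrcoef(xs, ys)[0, 1]
    return float(r * r), float(slope)


def pick_soft_threshold(
    matrix,
    powers=range(1, 21),
    r2_target: float = 0.8,
    fallback: float = 6.0,
) -> float:
    """Smallest power whose degree distribution is approximately scale-free.

    A power qualifies when the log-log fit of the binned degree
    distribution reaches R^2 >= r2_target with negative slope; if none
    does, the conventional fallback power (6) is returned with a warning.
    """
    values = _values(matrix)
    if values.shape[1] < 10:
        raise ValueError("soft-threshold selection requires >= 10 samples")
    arr = values.to_numpy(dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.abs(np.corrcoef(arr))
    corr[np.isnan(corr)] = 0.0
    np.fill_diagonal(corr, 0.0)
    for beta in powers:
        k = (corr ** beta).sum(axis=1)
        r2, slope = scale_free_fit(k)
        if r2 >= r2_target and slope < 0:
            return float(beta)
    logger.warning("no power reached scale-free R^2 >= %.2f; falling back to %g",
                   r2_target, fallback)
    return float(fallback)


def tom(A) -> pd.DataFrame:
    """Topological overlap matrix of an adjacency matrix.

    TOM_ij = (sum_{u != i,j} A_iu A_uj + A_ij) / (min(k_i, k_j) + 1 - A_ij)
    with k_i the connectivity excluding the diagonal; diagonal set to 1.
    """
    index = A.index if isinstance(A, pd.DataFrame) else None
    A = np.asarray(A, dtype=float)
    k = A.sum(axis=0) - np.diag(A)
    L = A @ A - 2.0 * A  # sum over u != i,j of A_iu A_uj, given unit diagonal
    num = L + A
    den = np.minimum.outer(k, k) + 1.0 - A
    with np.errstate(invalid="ignore", divide="ignore"):
        T = np.where(den > 0, num / den, 0.0)
    np.fill_diagonal(T, 1.0)
    T = np.clip((T + T.T) / 2.0, 0.0, 1.0)
    if index is not None:
        return pd.DataFrame(T, index=index, columns=index)
    return pd.DataFrame(T)


def module_eigengene(
    matrix, module_labels: pd.Series
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Module eigengenes and kME.

    The eigengene is the first right singular vector of the module's
    gene-standardized expression block, unit norm over samples, signed to
    correlate positively with the module's mean expression.  kME is the
    Pearson correlation of every gene with every eigengene.
    """
    values = _values(matrix)
    modules = [m for m in pd.unique(module_labels) if m and m != UNASSIGNED]
    eig = {}
    for mod in modules:
        genes = module_labels.index[module_labels == mod]
        block = values.loc[genes].to_numpy(dtype=float)
        sd = block.std(axis=1, ddof=1, keepdims=True)
        sd[sd == 0] = 1.0
        z = (block - block.mean(axis=1, keepdims=True)) / sd
        if len(genes) == 1:
            v = z[0]
            v = v / np.linalg.norm(v) if np.linalg.norm(v) > 0 else v
        else:
            _, _, vt = np.linalg.svd(z, full_matrices=False)
            v = vt[0]
        mean_expr = block.mean(axis=0)
        if np.corrcoef(v, mean_expr)[0, 1] < 0:
            v = -v
        eig[mod] = v
    eigengenes = pd.DataFrame(eig, index=values.columns).T
    if eigengenes.empty:
        return eigengenes, pd.DataFrame(index=values.index)
    arr = values.to_numpy(dtype=float)
    zc = arr - arr.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(zc, axis=1)
    norms[norms == 0] = 1.0
    E = eigengenes.to_numpy()
    Ec = E - E.mean(axis=1, keepdims=True)
    enorm = np.linalg.norm(Ec, axis=1)
    enorm[enorm == 0] = 1.0
    kme = (zc / norms[:, None]) @ (Ec / enorm[:, None]).T
    kme = pd.DataFrame(kme, index=values.index, columns=eigengenes.index)
    return eigengenes, kme


def detect_modules(
    tom_matrix: pd.DataFrame,
    min_size: int = 30,
    merge_height: float = 0.15,
    matrix=None,
    cut_height: float = 0.99,
) -> pd.Series:
    """Cluster the TOM dissimilarity into modules.

    Average-linkage hierarchical clustering on 1 - TOM with a static cut
    at cut_height (branches merging above it stay separate; noise-level
    TOM dissimilarities sit just below 1, so 0.99 splits real modules off
    the background), clusters below min_size left unassigned ("grey").
    If an expression matrix is supplied, modules whose eigengenes
    correlate above 1 - merge_height are merged iteratively.  Modules are
    named by size rank from a fixed color palette.
    """
    genes = tom_matrix.index
    D = 1.0 - tom_matrix.to_numpy(dtype=float)
    np.fill_diagonal(D, 0.0)
    condensed = squareform((D + D.T) / 2.0, checks=False)
    Z = hierarchy.linkage(condensed, method="average")
    raw = hierarchy.fcluster(Z, t=cut_height, criterion="distance")
    labels = pd.Series(raw.astype(object), index=genes)
    sizes = labels.value_counts()
    labels[labels.map(sizes) < min_size] = UNASSIGNED

    if matrix is not None:
        labels = _merge_by_eigengene(matrix, labels, merge_height)

    assigned = labels[labels != UNASSIGNED]
    if assigned.empty:
        logger.warning("no module reached min_size=%d; all genes unassigned", min_size)
        return pd.Series(UNASSIGNED, index=genes)
    ranked = assigned.value_counts().index
    rename = {old: MODULE_COLORS[i % len(MODULE_COLORS)] for i, old in enumerate(ranked)}
    rename[UNASSIGNED] = UNASSIGNED
    return labels.map(rename)


def _merge_by_eigengene(matrix, labels: pd.Series, merge_height: float) -> pd.Series:
    labels = labels.copy()
    while True:
        modules = [m for m in pd.unique(labels) if m != UNASSIGNED]
        if len(modules) < 2:
            return labels
        eigengenes, _ = module_eigengene(matrix, labels)
        corr = np.corrcoef(eigengenes.loc[modules].to_numpy())
        np.fill_diagonal(corr, -np.inf)
        i, j = np.unravel_index(np.argmax(corr), corr.shape)
        if corr[i, j] <= 1.0 - merge_height:
            return labels
        labels[labels == modules[j]] = modules[i]


def equal_frequency_bins(x: np.ndarray, n_bins: int) -> np.ndarray:
    """Rank-based equal-frequency binning; ties broken by original order."""
    n = len(x)
    ranks = np.empty(n, dtype=int)
    ranks[np.argsort(x, kind="stable")] = np.arange(n)
    return (ranks * n_bins) // n


def pairwise_mi(values: pd.DataFrame) -> pd.DataFrame:
    """Pairwise mutual information (nats) via equal-frequency binning.

    Bin count floor(sqrt(n_samples)), the usual coarse rule for MI network
    inference at moderate sample sizes.
    """
    arr = values.to_numpy(dtype=float)
    n_genes, n_samples = arr.shape
    n_bins = max(2, int(np.floor(np.sqrt(n_samples))))
    binned = np.vstack([equal_frequency_bins(arr[i], n_bins) for i in range(n_genes)])
    mi = np.zeros((n_genes, n_genes))
    for i in range(n_genes):
        for j in range(i + 1, n_genes):
            mi[i, j] = mi[j, i] = mutual_info_score(binned[i], binned[j])
    return pd.DataFrame(mi, index=values.index, columns=values.index)


def mi_permutation_threshold(
    values: pd.DataFrame, n_perm: int = 100, quantile: float = 0.95, seed: int = 0
) -> float:
    """MI magnitude expected under independence, by sample permutation."""
    rng = np.random.default_rng(seed)
    arr = values.to_numpy(dtype=float)
    n_genes, n_samples = arr.shape
    n_bins = max(2, int(np.floor(np.sqrt(n_samples))))
    null = []
    for _ in range(n_perm):
        i, j = rng.choice(n_genes, size=2, replace=False)
        x = equal_frequency_bins(arr[i], n_bins)
        y = equal_frequency_bins(rng.permutation(arr[j]), n_bins)
        null.append(mutual_info_score(x, y))
    return float(np.quantile(null, quantile))


def mi_network_dpi(
    matrix,
    genes=None,
    mi_threshold: float = 0.0,
    dpi_tolerance: float = 0.0,
) -> pd.DataFrame:
    """Mutual-information network pruned by the data-processing inequality.

    Edges with MI below mi_threshold are dropped; then, in every remaining
    triangle, the weakest edge is marked for removal if its MI is below
    (1 - dpi_tolerance) times both other edges' MI.  Marked edges are
    removed only after all triangles are scanned, so an edge that is the
    strongest in every triangle containing it is never removed.

    Returns an edge list DataFrame (gene_a, gene_b, mi).
    """
    values = _values(matrix)
    if genes is not None:
        values = values.loc[list(genes)]
    if len(values) < 2:
        raise ValueError("MI network requires at least 2 genes")
    mi = pairwise_mi(values)
    ids = list(values.index)
    edges: dict[tuple[str, str], float] = {}
    for i, j in itertools.combinations(range(len(ids)), 2):
        m = mi.iloc[i, j]
        if m >= mi_threshold:
            edges[(ids[i], ids[j])] = float(m)

    neighbors: dict[str, set[str]] = {g: set() for g in ids}
    for a, b in edges:
        neighbors[a].add(b)
        neighbors[b].add(a)

    def key(a, b):
        return (a, b) if (a, b) in edges else (b, a)

    to_remove: set[tuple[str, str]] = set()
    for a, b in edges:
        common = neighbors[a] & neighbors[b]
        for c in common:
            e_ab = edges[key(a, b)]
            e_ac = edges[key(a, c)]
            e_bc = edges[key(b, c)]
            weakest = min(e_ab, e_ac, e_bc)
            others = sorted([e_ab, e_ac, e_bc])[1:]
            if weakest < min(others) * (1.0 - dpi_tolerance):
                for pair, val in ((key(a, b), e_ab), (key(a, c), e_ac), (key(b, c), e_bc)):
                    if val == weakest:
                        to_remove.add(pair)
                        break
    kept = [(a, b, m) for (a, b), m in edges.items() if (a, b) not in to_remove]
    out = pd.DataFrame(kept, columns=["gene_a", "gene_b", "mi"])
    return out.sort_values(["gene_a", "gene_b"]).reset_index(drop=True)


@dataclass
class HubSet:
    """Per-module hub genes with condition-specific and DE flags."""

    hubs: dict[str, pd.DataFrame] = field(default_factory=dict)
    mi_edges: pd.DataFrame | None = None


def _mi_degree(edge_list: pd.DataFrame, genes: list[str]) -> pd.Series:
    deg = pd.Series(0.0, index=genes)
    if edge_list is None or edge_list.empty:
        return deg
    sub = edge_list[edge_list["gene_a"].isin(genes) & edge_list["gene_b"].isin(genes)]
    for col in ("gene_a", "gene_b"):
        sums = sub.groupby(col)["mi"].sum()
        deg = deg.add(sums.reindex(genes, fill_value=0.0), fill_value=0.0)
    return deg


def identify_hubs(
    kme: pd.DataFrame,
    module_labels: pd.Series,
    top_k: int = 11,
    de_table: pd.DataFrame | None = None,
    condition_networks: dict[str, pd.DataFrame] | None = None,
    mi_edges: pd.DataFrame | None = None,
) -> HubSet:
    """Rank intramodular hubs and flag condition-specific ones.

    Genes are ranked within each module by intramodular MI degree (summed
    retained-edge MI) when an edge list is available, else by kME.  With
    ``condition_networks`` = {"case": edges, "control": edges}, a hub is
    condition-specific if it ranks in the case network's top_k but falls
    outside the control network's top 2*top_k.  DE hubs are flagged from
    de_table's up/down calls.
    """
    modules = [m for m in pd.unique(module_labels) if m and m != UNASSIGNED]
    if not modules:
        raise ValueError("no modules to identify hubs in")
    out = HubSet(mi_edges=mi_edges)
    for mod in modules:
        genes = list(module_labels.index[module_labels == mod])
        k = min(top_k, len(genes))
        if top_k > len(genes):
            logger.warning("top_k=%d exceeds module %s size %d; clipped", top_k, mod, len(genes))
        if mi_edges is not None and not mi_edges.empty:
            score = _mi_degree(mi_edges, genes)
        else:
            score = kme.loc[genes, mod].abs() if mod in kme.columns else pd.Series(0.0, index=genes)
        ranking = score.sort_values(ascending=False, kind="stable")
        hubs = ranking.index[:k].tolist()

        specific = {g: False for g in hubs}
        if condition_networks is not None:
            case_deg = _mi_degree(condition_networks["case"], genes)
            ctrl_deg = _mi_degree(condition_networks["control"], genes)
            case_rank = case_deg.sort_values(ascending=False, kind="stable").index.tolist()
            ctrl_rank = ctrl_deg.sort_values(ascending=False, kind="stable").index.tolist()
            case_hubs = case_rank[:k]
            ctrl_top = set(ctrl_rank[: 2 * top_k])
            specific = {g: (g in case_hubs and g not in ctrl_top) for g in hubs}

        is_de = {g: False for g in hubs}
        if de_table is not None:
            for g in hubs:
                if g in de_table.index and de_table.loc[g, "class"] in ("up", "down"):
                    is_de[g] = True
        out.hubs[mod] = pd.DataFrame(
            {
                "gene": hubs,
                "score": [float(score[g]) for g in hubs],
                "rank": np.arange(1, len(hubs) + 1),
                "condition_specific": [specific[g] for g in hubs],
                "is_de": [is_de[g] for g in hubs],
            }
        ).set_index("gene")
    return out
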
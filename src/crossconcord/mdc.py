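"""Module differential connectivity (MDC) with a two-scheme permutation test.

For a module's genes, connectivity within a sample group is summarized by
the sum of the lower-triangular entries of the soft-thresholded adjacency
computed on that group's samples.  MDC is the case/control ratio of those
sums: > 1 indicates gain of connectivity in the case group, < 1 loss.

Significance comes from permutation under two shuffling schemes:

* shuffle_samples — case/control labels permuted over the pooled samples
  (non-random nodes, random connections);
* shuffle_genes — the module replaced by random same-size gene sets from
  the analyzed universe (random nodes, non-random connections).

Each scheme yields an add-one two-sided p-value on the log-ratio scale;
the final per-module p is the conservative maximum of the two, adjusted
across modules by Benjamini-Hochberg, with calls at q < 0.05.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix
from .demod import adjust_bh

logger = logging.getLogger(__name__)

SCHEMES = ("shuffle_samples", "shuffle_genes")
Q_SIGNIFICANT = 0.05


def _lower_sum_adjacency(values: np.ndarray, beta: float) -> float:
    """Sum of lower-triangular |cor|^beta entries (diagonal excluded)."""
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(values)
    corr[np.isnan(corr)] = 0.0
    A = np.abs(np.clip(corr, -1, 1)) ** beta
    return float(np.tril(A, k=-1).sum())


def mdc_ratio(A_case: np.ndarray, A_ctrl: np.ndarray) -> float:
    """Ratio of summed lower-triangular adjacency, case over control."""
    A_case = np.asarray(A_case, dtype=float)
    A_ctrl = np.asarray(A_ctrl, dtype=float)
    if A_case.shape != A_ctrl.shape or A_case.shape[0] < 2:
        raise ValueError("adjacency submatrices must share shape and have >= 2 genes")
    num = float(np.tril(A_case, k=-1).sum())
    den = float(np.tril(A_ctrl, k=-1).sum())
    if den == 0:
        raise ValueError("disconnected control module: zero control connectivity")
    return num / den


def _observed_mdc(values: pd.DataFrame, case: list[str], ctrl: list[str], beta: float) -> float:
    num = _lower_sum_adjacency(values[case].to_numpy(), beta)
    den = _lower_sum_adjacency(values[ctrl].to_numpy(), beta)
    if den == 0:
        raise ValueError("disconnected control module: zero control connectivity")
    return num / den


def permute_mdc(
    matrix,
    case_samples: list[str],
    ctrl_samples: list[str],
    module_genes: list[str],
    beta: float,
    scheme: str = "shuffle_samples",
    n_perm: int = 1000,
    seed: int = 0,
    universe_genes: list[str] | None = None,
) -> tuple[np.ndarray, float, float]:
    """Permutation null and p-value for one module under one scheme.

    Returns (null ratios, two-sided p on the log scale, observed ratio).
    p = (1 + #{|log null| >= |log observed|}) / (1 + n_perm).
    """
    if scheme not in SCHEMES:
        raise ValueError(f"unknown scheme {scheme!r}")
    if n_perm < 10:
        raise ValueError("n_perm must be >= 10")
    if len(case_samples) < 3 or len(ctrl_samples) < 3:
        raise ValueError("both sample groups must have >= 3 samples")
    values = matrix.values if isinstance(matrix, ExpressionMatrix) else matrix
    missing = [g for g in module_genes if g not in values.index]
    if missing:
        raise ValueError(f"module genes absent from matrix: {missing[:5]}")
    sub = values.loc[list(module_genes)]
    observed = _observed_mdc(sub, case_samples, ctrl_samples, beta)

    # each permutation has its own derived stream, so the first B draws are
    # identical for any n_perm >= B (p estimates are nested in n_perm)
    null = np.empty(n_perm)
    if scheme == "shuffle_samples":
        pooled = np.array(list(case_samples) + list(ctrl_samples))
        n_case = len(case_samples)
        for b in range(n_perm):
            perm = np.random.default_rng([seed, b]).permutation(pooled)
            null[b] = _observed_mdc(sub, list(perm[:n_case]), list(perm[n_case:]), beta)
    else:
        universe = list(universe_genes) if universe_genes is not None else list(values.index)
        if len(universe) < len(module_genes):
            raise ValueError("universe smaller than module")
        for b in range(n_perm):
            pick = np.random.default_rng([seed, b]).choice(
                len(universe), size=len(module_genes), replace=False
            )
            rand = values.loc[[universe[i] for i in pick]]
            null[b] = _observed_mdc(rand, case_samples, ctrl_samples, beta)

    log_obs = abs(np.log(observed))
    log_null = np.abs(np.log(null))
    p = (1.0 + float(np.sum(log_null >= log_obs))) / (1.0 + n_perm)
    return null, p, observed


def mdc_test(
    matrix,
    case_group: str,
    control_group: str,
    module_labels: pd.Series,
    beta: float,
    n_perm: int = 1000,
    seed: int = 0,
    sex: str | None = None,
    q_threshold: float = Q_SIGNIFICANT,
    universe_genes: list[str] | None = None,
) -> pd.DataFrame:
    """MDC with both permutation schemes for every module, BH across modules.

    Returns a DataFrame indexed by module with columns mdc, p_samples,
    p_genes, p_final (max of the two), q, call in {gain, loss, none},
    n_perm.
    """
    if not isinstance(matrix, ExpressionMatrix):
        raise TypeError("mdc_test needs an ExpressionMatrix with sample annotations")
    case = matrix.samples_where(group=case_group, sex=sex)
    ctrl = matrix.samples_where(group=control_group, sex=sex)
    modules = [m for m in pd.unique(module_labels) if m and m != "grey"]
    if not modules:
        raise ValueError("no modules to test")
    if universe_genes is None:
        universe_genes = list(module_labels.index)
    universe = [g for g in universe_genes if g in matrix.values.index]
    rng = np.random.default_rng(seed)
    rows = []
    for mod in modules:
        genes = [g for g in module_labels.index[module_labels == mod]]
        present = [g for g in genes if g in matrix.values.index]
        if len(present) < len(genes):
            logger.warning("module %s: %d genes absent from matrix", mod, len(genes) - len(present))
        if len(present) < 2:
            logger.warning("module %s skipped: fewer than 2 genes present", mod)
            continue
        seed_s, seed_g = int(rng.integers(2**31)), int(rng.integers(2**31))
        _, p_s, observed = permute_mdc(
            matrix, case, ctrl, present, beta, "shuffle_samples", n_perm, seed_s
        )
        _, p_g, _ = permute_mdc(
            matrix, case, ctrl, present, beta, "shuffle_genes", n_perm, seed_g,
            universe_genes=universe,
        )
        rows.append({"module": mod, "mdc": observed, "p_samples": p_s, "p_genes": p_g,
                     "p_final": max(p_s, p_g), "n_perm": n_perm})
    result = pd.DataFrame(rows).set_index("module")
    result["q"] = adjust_bh(result["p_final"].to_numpy())
    calls = np.full(len(result), "none", dtype=object)
    sig = result["q"].to_numpy() < q_threshold
    mdc_vals = result["mdc"].to_numpy()
    calls[sig & (mdc_vals > 1)] = "gain"
    calls[sig & (mdc_vals < 1)] = "loss"
    result["call"] = calls
    return result
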
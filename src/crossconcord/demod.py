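"""Moderated differential expression.

Gene-wise two-group comparisons on log2 expression with empirical-Bayes
variance moderation: the gene-wise residual variances s2_g are shrunk
toward a prior s0_sq with prior weight d0 degrees of freedom,

    posterior s2_g = (d0 * s0_sq + df * s2_g) / (d0 + df),

and the moderated t statistic log2FC / sqrt(posterior s2 * (1/n_a + 1/n_b))
is referred to a t distribution with d0 + df degrees of freedom.  (d0,
s0_sq) are estimated by the method of moments on log variances, inverting
the trigamma function by bisection.

Differential-expression calls use the fixed thresholds p < 0.01 and
|log2FC| > 0.26, both strict.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .containers import ExpressionMatrix, ModerationParams

P_THRESHOLD = 0.01
LFC_THRESHOLD = 0.26


def fit_linear_de(
    matrix: ExpressionMatrix,
    contrast: tuple[str, str],
    sex: str | None = None,
) -> pd.DataFrame:
    """Two-group linear fit per gene.

    contrast is (reference_group, test_group); log2FC = mean(test) -
    mean(reference).  If ``sex`` is given the comparison is restricted to
    samples of that sex (sex stratification by subsetting).

    Returns a DataFrame indexed by gene with columns log2FC, s2, df, n_a, n_b.
    """
    group_a, group_b = contrast
    samples_a = matrix.samples_where(group=group_a, sex=sex)
    samples_b = matrix.samples_where(group=group_b, sex=sex)
    for g, s in ((group_a, samples_a), (group_b, samples_b)):
        if len(s) == 0:
            raise ValueError(f"group {g!r} absent" + (f" for sex {sex!r}" if sex else ""))
        if len(s) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 samples")
    xa = matrix.values[samples_a].to_numpy()
    xb = matrix.values[samples_b].to_numpy()
    na, nb = xa.shape[1], xb.shape[1]
    df = na + nb - 2
    if df <= 0:
        raise ValueError("nonpositive residual degrees of freedom")
    lfc = xb.mean(axis=1) - xa.mean(axis=1)
    ssa = ((xa - xa.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    ssb = ((xb - xb.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    s2 = (ssa + ssb) / df
    return pd.DataFrame(
        {"log2FC": lfc, "s2": s2, "df": float(df), "n_a": na, "n_b": nb},
        index=matrix.gene_ids,
    )


def _trigamma_inverse(y: float, tol: float = 1e-8) -> float:
    """Solve trigamma(x) = y for x > 0 by bisection."""
    if y <= 0:
        return np.inf
    lo, hi = 1e-8, 1e8
    while special.polygamma(1, lo) < y:
        lo /= 2
    while special.polygamma(1, hi) > y:
        hi *= 2
    while hi - lo > tol * max(1.0, lo):
        mid = 0.5 * (lo + hi)
        if special.polygamma(1, mid) > y:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def estimate_prior(s2: np.ndarray, df: float) -> ModerationParams:
    """Method-of-moments fit of the scaled inverse-chi-square variance prior.

    Works on e_g = log s2_g - digamma(df/2) + log(df/2), whose mean and
    excess variance over trigamma(df/2) identify (d0, s0_sq).  Zero
    variances are floored at the 1st percentile of positive variances; an
    all-zero variance vector is degenerate.
    """
    s2 = np.asarray(s2, dtype=float)
    if np.all(s2 <= 0):
        raise ValueError("degenerate variances: all gene variances are zero")
    positive = s2[s2 > 0]
    floor = np.percentile(positive, 1)
    s2 = np.maximum(s2, floor)
    z = np.log(s2)
    e = z - special.digamma(df / 2) + np.log(df / 2)
    evar = e.var(ddof=1)
    resid = evar - special.polygamma(1, df / 2)
    if resid <= 0:
        d0 = np.inf
        s0_sq = float(np.exp(e.mean()))
    else:
        d0 = 2.0 * _trigamma_inverse(float(resid))
        s0_sq = float(np.exp(e.mean() + special.digamma(d0 / 2) - np.log(d0 / 2)))
    return ModerationParams(d0=float(d0), s0_sq=s0_sq, df_residual=float(df))


def moderate_variances(
    s2: np.ndarray,
    df: float,
    log2fc: np.ndarray,
    n_a: int,
    n_b: int,
    params: ModerationParams | None = None,
) -> tuple[ModerationParams, np.ndarray, np.ndarray, np.ndarray]:
    """Shrink variances and compute moderated t and p per gene.

    If ``params`` is given (e.g. d0 forced to 0 or inf) it is used as-is;
    otherwise the prior is estimated from the data.  Returns (params,
    posterior variances, moderated t, two-sided p).
    """
    s2 = np.asarray(s2, dtype=float)
    log2fc = np.asarray(log2fc, dtype=float)
    if params is None:
        params = estimate_prior(s2, df)
    d0, s0 = params.d0, params.s0_sq
    if np.isinf(d0):
        post = np.full_like(s2, s0)
        total_df = np.inf
    else:
        post = (d0 * s0 + df * s2) / (d0 + df)
        total_df = d0 + df
    se = np.sqrt(post * (1.0 / n_a + 1.0 / n_b))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, log2fc / se, 0.0)
    p = 2.0 * stats.t.sf(np.abs(t), total_df)
    return params, post, t, p


def adjust_bh(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def classify_de(
    log2fc,
    p,
    p_thresh: float = P_THRESHOLD,
    lfc_thresh: float = LFC_THRESHOLD,
) -> np.ndarray:
    """Call genes up / down / ns with strict thresholds on p and |log2FC|."""
    log2fc = np.atleast_1d(np.asarray(log2fc, dtype=float))
    p = np.atleast_1d(np.asarray(p, dtype=float))
    if not (np.isfinite(log2fc).all() and np.isfinite(p).all()):
        raise ValueError("log2FC and p must be finite")
    calls = np.full(log2fc.shape, "ns", dtype=object)
    sig = p < p_thresh
    calls[sig & (log2fc > lfc_thresh)] = "up"
    calls[sig & (log2fc < -lfc_thresh)] = "down"
    return calls


def run_de(
    matrix: ExpressionMatrix,
    contrast: tuple[str, str],
    sex: str | None = None,
    p_thresh: float = P_THRESHOLD,
    lfc_thresh: float = LFC_THRESHOLD,
    use_q_for_calls: bool = False,
) -> pd.DataFrame:
    """Full moderated DE table for one contrast.

    Columns: gene (index), log2FC, t, p, q, class, contrast.  By default
    the unadjusted p feeds the up/down call (q is reported alongside); set
    use_q_for_calls to call on the BH-adjusted q instead.
    """
    fit = fit_linear_de(matrix, contrast, sex=sex)
    _, _, t, p = moderate_variances(
        fit["s2"].to_numpy(), float(fit["df"].iloc[0]), fit["log2FC"].to_numpy(),
        int(fit["n_a"].iloc[0]), int(fit["n_b"].iloc[0]),
    )
    q = adjust_bh(p)
    calls = classify_de(
        fit["log2FC"].to_numpy(), q if use_q_for_calls else p, p_thresh, lfc_thresh
    )
    label = f"{contrast[0]}_vs_{contrast[1]}" + (f"_{sex}" if sex else "")
    return pd.DataFrame(
        {"log2FC": fit["log2FC"], "t": t, "p": p, "q": q, "class": calls, "contrast": label},
        index=fit.index,
    )


def summarize_biotypes(de: pd.DataFrame, gene_annotations: pd.DataFrame) -> pd.DataFrame:
    """Biotype counts and proportions among differentially expressed genes.

    Considers the union of up- and down-called genes; proportions sum to 1
    when that set is nonempty.
    """
    de_genes = de.index[de["class"].isin(["up", "down"])]
    if len(de_genes) == 0:
        return pd.DataFrame(columns=["count", "proportion"])
    missing = [g for g in de_genes if g not in gene_annotations.index
               or pd.isna(gene_annotations.loc[g, "biotype"])]
    if missing:
        raise ValueError(f"genes missing biotype annotation: {missing}")
    counts = gene_annotations.loc[de_genes, "biotype"].value_counts()
    out = pd.DataFrame({"count": counts, "proportion": counts / counts.sum()})
    out.index.name = "biotype"
    return out
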
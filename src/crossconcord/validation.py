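"""Simulation studies that quantify the pipeline's operating characteristics.

Each function plants known structure with the synthetic generator, runs the
corresponding statistic end to end, and reports a recovery or error rate:
type-I calibration and power of the MDC permutation test, adjusted Rand
index of module detection, the sex-specific RRHO concordance motif,
data-processing-inequality pruning of indirect MI edges, and recovery of
the variance-moderation hyperparameters.  The analysis drivers and the
package's validation suite both run these at their own problem sizes.
"""

from __future__ import annotations

import numpy as np
from scipy import stats
from sklearn.metrics import adjusted_rand_score

from . import coexpr, demod, mdc, rrho, synthgen
from .synthgen import ModuleSpec, SyntheticDesign


def _null_design(n_genes: int, n_per_group: int, modules=()) -> SyntheticDesign:
    return SyntheticDesign(
        n_genes=n_genes, groups=("control", "case"), n_per_group=n_per_group,
        frac_concordant_up=0, frac_concordant_down=0, frac_discordant=0,
        frac_unique_a=0, frac_unique_b=0, modules=modules,
    )


def mdc_type1_rate(
    n_sim: int = 200,
    module_size: int = 40,
    n_genes: int = 200,
    n_per_group: int = 10,
    n_perm: int = 100,
    alpha: float = 0.05,
    seed: int = 0,
) -> float:
    """Rejection rate of the conjunctive MDC p-value on exchangeable noise.

    The "module" is an arbitrary gene set in a pure-noise matrix, so both
    shuffling schemes' nulls match the observed sampling distribution; a
    calibrated test rejects at close to alpha.  n_per_group is per sex
    (two sexes), giving 2 * n_per_group samples per group.
    """
    rng = np.random.default_rng(seed)
    design = _null_design(n_genes, n_per_group)
    rejections = 0
    for _ in range(n_sim):
        matrix, _ = synthgen.generate_cohort(design, seed=int(rng.integers(2**31)))
        case = matrix.samples_where(group="case")
        ctrl = matrix.samples_where(group="control")
        genes = list(matrix.gene_ids[:module_size])
        _, p_s, _ = mdc.permute_mdc(matrix, case, ctrl, genes, beta=6,
                                    scheme="shuffle_samples", n_perm=n_perm,
                                    seed=int(rng.integers(2**31)))
        _, p_g, _ = mdc.permute_mdc(matrix, case, ctrl, genes, beta=6,
                                    scheme="shuffle_genes", n_perm=n_perm,
                                    seed=int(rng.integers(2**31)),
                                    universe_genes=list(matrix.gene_ids))
        if max(p_s, p_g) < alpha:
            rejections += 1
    return rejections / n_sim


def mdc_power_gain(
    n_sim: int = 100,
    module_size: int = 40,
    n_genes: int = 200,
    n_per_group: int = 15,
    r_control: float = 0.2,
    r_treatment: float = 0.6,
    n_perm: int = 100,
    seed: int = 0,
) -> float:
    """Fraction of simulations where a planted connectivity gain is called.

    A module whose within-module correlation rises from r_control to
    r_treatment in the case group should be called "gain" at q < 0.05.
    """
    rng = np.random.default_rng(seed)
    design = _null_design(
        n_genes, n_per_group,
        modules=(ModuleSpec(module_size, r_control, r_treatment, "case"),),
    )
    hits = 0
    for _ in range(n_sim):
        matrix, truth = synthgen.generate_cohort(design, seed=int(rng.integers(2**31)))
        labels = truth.module_of[truth.module_of == "M1"]
        result = mdc.mdc_test(
            matrix, "case", "control", labels, beta=6, n_perm=n_perm,
            seed=int(rng.integers(2**31)), universe_genes=list(matrix.gene_ids),
        )
        if result.loc["M1", "call"] == "gain":
            hits += 1
    return hits / n_sim


def module_recovery_ari(
    n_genes: int = 600,
    sizes: tuple[int, ...] = (60, 100, 120, 150),
    r: float = 0.6,
    n_per_group: int = 25,
    seed: int = 0,
) -> float:
    """Adjusted Rand index of detected vs planted modules.

    Four equicorrelated modules (r in every group) among noise genes;
    2 groups x 2 sexes x n_per_group samples.  Detection runs the full
    adjacency -> TOM -> tree-cut path at beta = 6.
    """
    design = _null_design(
        n_genes, n_per_group,
        modules=tuple(ModuleSpec(s, r, r, "case") for s in sizes),
    )
    matrix, truth = synthgen.generate_cohort(design, seed=seed)
    T = coexpr.tom(coexpr.adjacency(matrix, beta=6))
    labels = coexpr.detect_modules(T, min_size=30, matrix=matrix.values)
    return float(adjusted_rand_score(truth.module_of.to_numpy(), labels.to_numpy()))


def moderation_recovery(
    n_genes: int = 5000,
    d0_true: float = 4.0,
    s0_true: float = 1.0,
    df: int = 10,
    seed: int = 0,
) -> dict:
    """Recover (d0, s0_sq) from variances drawn from the moderation model,
    and KS-test uniformity of null p-values on generated expression data."""
    rng = np.random.default_rng(seed)
    v = d0_true * s0_true / rng.chisquare(d0_true, n_genes)
    s2 = v * rng.chisquare(df, n_genes) / df
    params = demod.estimate_prior(s2, df)

    design = _null_design(2000, 8)
    matrix, _ = synthgen.generate_cohort(design, seed=int(rng.integers(2**31)))
    de = demod.run_de(matrix, ("control", "case"))
    ks_p = float(stats.kstest(de["p"], "uniform").pvalue)
    return {"d0": float(params.d0), "s0_sq": float(params.s0_sq), "ks_p": ks_p}


def sex_specific_rrho_rate(
    n_seeds: int = 50,
    n_genes: int = 600,
    n_per_group: int = 10,
    frac_concordant: float = 0.25,
    seed: int = 0,
) -> float:
    """How often female-only planted concordance shows up as FF > MM RRHO.

    Concordant effects (both directions) are planted in the female samples
    of both cohorts; male samples carry no effects.  For each seed the
    concordant-quadrant maximum of the female-female map is compared with
    the male-male map's.
    """
    rng = np.random.default_rng(seed)
    conc = SyntheticDesign(
        n_genes=n_genes, groups=("control", "case"), n_per_group=n_per_group,
        sexes=("F",),
        frac_concordant_up=frac_concordant / 2,
        frac_concordant_down=frac_concordant / 2,
        frac_discordant=0, frac_unique_a=0, frac_unique_b=0,
    )
    null = SyntheticDesign(
        n_genes=n_genes, groups=("control", "case"), n_per_group=n_per_group,
        sexes=("M",),
        frac_concordant_up=0, frac_concordant_down=0,
        frac_discordant=0, frac_unique_a=0, frac_unique_b=0,
    )
    wins = 0
    for _ in range(n_seeds):
        sF = int(rng.integers(2**31))
        sM = int(rng.integers(2**31))
        maxima = {}
        for label, design, s in (("F", conc, sF), ("M", null, sM)):
            mat_a, mat_b, orth, _ = synthgen.generate_pair(design, design, seed=s)
            de_a = demod.run_de(mat_a, ("control", "case"), sex=label)
            de_b = demod.run_de(mat_b, ("control", "case"), sex=label)
            sig_a, sig_b = rrho.align_signatures(de_a, de_b, orth)
            m = rrho.compute_rrho_map(sig_a, sig_b)
            maxima[label] = max(
                m.summaries[q]["max"] for q in rrho.CONCORDANT_QUADRANTS
            )
        if maxima["F"] > maxima["M"]:
            wins += 1
    return wins / n_seeds


def dpi_prune_rate(
    n_runs: int = 100,
    n_samples: int = 200,
    r: float = 0.8,
    seed: int = 0,
) -> float:
    """How often DPI removes the indirect edge of a Gaussian chain X->Y->Z."""
    rng = np.random.default_rng(seed)
    import pandas as pd

    removed = 0
    for _ in range(n_runs):
        x = rng.standard_normal(n_samples)
        y = r * x + np.sqrt(1 - r**2) * rng.standard_normal(n_samples)
        z = r * y + np.sqrt(1 - r**2) * rng.standard_normal(n_samples)
        values = pd.DataFrame(
            np.vstack([x, y, z]), index=["X", "Y", "Z"],
            columns=[f"s{i}" for i in range(n_samples)],
        )
        edges = coexpr.mi_network_dpi(values, mi_threshold=0.0)
        pairs = {tuple(sorted(p)) for p in edges[["gene_a", "gene_b"]].to_numpy()}
        if ("X", "Z") not in pairs:
            removed += 1
    return removed / n_runs


def de_null_calibration(
    n_genes: int = 2000,
    n_per_group: int = 10,
    p_thresh: float = 0.01,
    seed: int = 0,
) -> float:
    """Fraction of null genes called at p < p_thresh (should be ~ p_thresh)."""
    design = _null_design(n_genes, n_per_group)
    matrix, _ = synthgen.generate_cohort(design, seed=seed)
    de = demod.run_de(matrix, ("control", "case"))
    return float((de["p"] < p_thresh).mean())
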
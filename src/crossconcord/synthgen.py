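"""Synthetic paired-cohort expression data with planted truth.

Emulates the study design the downstream statistics target: two cohorts
("human"-like and "rodent"-like) each with a control group and three
opioid-exposure stages, both sexes, planted differential-expression effects
that are concordant, discordant or cohort-unique across the pair, and
planted correlation modules whose connectivity can differ between groups.

Module genes follow an equicorrelated latent-factor construction: gene g in
module m is sqrt(r) * f_m + sqrt(1-r) * eps_g with a shared per-sample
factor f_m, which gives exactly r expected pairwise correlation and is
therefore analytically checkable.  All randomness flows through explicit
numpy Generators seeded from a single integer; there is no global state.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix

DE_CLASSES = ("conc_up", "conc_down", "disc", "unique_a", "unique_b", "null")

DEFAULT_BIOTYPE_PROPS = {
    "protein_coding": 0.892,
    "lncRNA": 0.075,
    "pseudogene": 0.033,
}


@dataclass
class ModuleSpec:
    """A planted co-expression module.

    r_control applies to samples of every group except ``group``, whose
    samples use r_treatment; r_treatment > r_control plants a connectivity
    gain in that group, r_treatment < r_control a loss.
    """

    size: int
    r_control: float
    r_treatment: float
    group: str

    def __post_init__(self) -> None:
        if self.size < 3:
            raise ValueError("module size must be >= 3")
        for r in (self.r_control, self.r_treatment):
            if not (-1 < r < 1):
                raise ValueError("module correlations must lie in (-1, 1)")

    @property
    def change(self) -> str:
        if self.r_treatment > self.r_control:
            return "gain"
        if self.r_treatment < self.r_control:
            return "loss"
        return "none"


@dataclass
class SyntheticDesign:
    """Parameters of one simulated cohort.

    Defaults mirror the emulated study design: a control group plus
    intoxication / withdrawal / abstinence exposure stages, both sexes,
    10 samples per group per sex, and a biotype mix dominated by
    protein-coding genes.  Effect sizes are log2 fold changes drawn from
    N(effect_mean, effect_sd) (magnitudes, sign set by the effect class);
    noise_sd is the residual log2 standard deviation.
    """

    n_genes: int = 2000
    groups: tuple[str, ...] = ("control", "intoxication", "withdrawal", "abstinence")
    n_per_group: int = 10
    sexes: tuple[str, ...] = ("F", "M")
    frac_concordant_up: float = 0.05
    frac_concordant_down: float = 0.05
    frac_discordant: float = 0.02
    frac_unique_a: float = 0.02
    frac_unique_b: float = 0.02
    effect_mean: float = 1.0
    effect_sd: float = 0.2
    noise_sd: float = 0.5
    modules: tuple[ModuleSpec, ...] = ()
    biotype_props: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_BIOTYPE_PROPS))
    ortholog_coverage: float = 0.9
    seed: int = 0

    def __post_init__(self) -> None:
        self.groups = tuple(self.groups)
        self.sexes = tuple(self.sexes)
        self.modules = tuple(
            m if isinstance(m, ModuleSpec) else ModuleSpec(**m) for m in self.modules
        )
        self.validate()

    def validate(self) -> None:
        fracs = self.de_fractions()
        total = sum(fracs.values())
        if total > 1 + 1e-9:
            raise ValueError(f"DE-class proportions sum to {total:.3f} > 1")
        if abs(sum(self.biotype_props.values()) - 1.0) > 1e-9:
            raise ValueError("biotype_props must sum to 1")
        if not (0 < self.ortholog_coverage <= 1):
            raise ValueError("ortholog_coverage must lie in (0, 1]")
        if self.n_per_group < 3:
            raise ValueError("n_per_group must be >= 3")
        if len(self.groups) < 2:
            raise ValueError("need a control group and at least one other")
        if sum(m.size for m in self.modules) > self.n_genes:
            raise ValueError("module overlap: module sizes exceed available genes")
        for m in self.modules:
            if m.group not in self.groups:
                raise ValueError(f"module group {m.group!r} not in design groups")

    def de_fractions(self) -> dict[str, float]:
        return {
            "conc_up": self.frac_concordant_up,
            "conc_down": self.frac_concordant_down,
            "disc": self.frac_discordant,
            "unique_a": self.frac_unique_a,
            "unique_b": self.frac_unique_b,
        }

    @property
    def control_group(self) -> str:
        return self.groups[0]

    @property
    def n_samples(self) -> int:
        return len(self.groups) * len(self.sexes) * self.n_per_group

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class SyntheticTruth:
    """Planted per-gene and per-module ground truth.

    classes : per-gene concordance class (canonical upper-case gene key).
    true_lfc : cohort label -> DataFrame (genes x non-control groups) of
        true log2 fold changes vs control.
    module_of : per-gene module id ("" for none).
    module_changes : DataFrame indexed by module id with columns
        group / change in {gain, loss, none}.
    """

    classes: pd.Series
    true_lfc: dict[str, pd.DataFrame]
    module_of: pd.Series
    module_changes: pd.DataFrame

    def to_json(self) -> str:
        payload = {
            "classes": self.classes.to_dict(),
            "true_lfc": {c: df.to_dict(orient="index") for c, df in self.true_lfc.items()},
            "module_of": self.module_of.to_dict(),
            "module_changes": self.module_changes.to_dict(orient="index"),
        }
        return json.dumps(payload, indent=1, sort_keys=True)


def _canonical_genes(n_genes: int) -> list[str]:
    width = max(5, len(str(n_genes)))
    return [f"GENE{i:0{width}d}" for i in range(1, n_genes + 1)]


def _plant_truth(design: SyntheticDesign, rng: np.random.Generator) -> SyntheticTruth:
    """Draw the shared (cohort-pair) truth: classes, magnitudes, modules."""
    genes = _canonical_genes(design.n_genes)
    fracs = design.de_fractions()
    counts = {k: int(round(v * design.n_genes)) for k, v in fracs.items()}
    order = rng.permutation(design.n_genes)
    classes = np.array(["null"] * design.n_genes, dtype=object)
    pos = 0
    for cls in ("conc_up", "conc_down", "disc", "unique_a", "unique_b"):
        classes[order[pos : pos + counts[cls]]] = cls
        pos += counts[cls]
    classes = pd.Series(classes, index=genes, name="class")

    magnitudes = np.abs(rng.normal(design.effect_mean, design.effect_sd, design.n_genes))
    sign_a = np.zeros(design.n_genes)
    sign_b = np.zeros(design.n_genes)
    sign_a[classes == "conc_up"] = 1.0
    sign_b[classes == "conc_up"] = 1.0
    sign_a[classes == "conc_down"] = -1.0
    sign_b[classes == "conc_down"] = -1.0
    # discordant genes: random direction in cohort a, flipped in cohort b
    disc = classes == "disc"
    disc_sign = rng.choice([-1.0, 1.0], size=int(disc.sum()))
    sign_a[disc.to_numpy()] = disc_sign
    sign_b[disc.to_numpy()] = -disc_sign
    uniq_a = classes == "unique_a"
    sign_a[uniq_a.to_numpy()] = rng.choice([-1.0, 1.0], size=int(uniq_a.sum()))
    uniq_b = classes == "unique_b"
    sign_b[uniq_b.to_numpy()] = rng.choice([-1.0, 1.0], size=int(uniq_b.sum()))

    noncontrol = [g for g in design.groups if g != design.control_group]
    lfc_a = pd.DataFrame(
        np.outer(sign_a * magnitudes, np.ones(len(noncontrol))), index=genes, columns=noncontrol
    )
    lfc_b = pd.DataFrame(
        np.outer(sign_b * magnitudes, np.ones(len(noncontrol))), index=genes, columns=noncontrol
    )

    # disjoint module allocation over a fresh permutation of genes
    module_of = pd.Series([""] * design.n_genes, index=genes, name="module")
    alloc = rng.permutation(design.n_genes)
    pos = 0
    changes = []
    for i, mod in enumerate(design.modules, start=1):
        mid = f"M{i}"
        idx = alloc[pos : pos + mod.size]
        if len(idx) < mod.size:
            raise ValueError("module overlap: module sizes exceed available genes")
        module_of.iloc[idx] = mid
        pos += mod.size
        changes.append({"module": mid, "group": mod.group, "change": mod.change})
    module_changes = (
        pd.DataFrame(changes).set_index("module")
        if changes
        else pd.DataFrame(columns=["group", "change"])
    )
    return SyntheticTruth(
        classes=classes,
        true_lfc={"a": lfc_a, "b": lfc_b},
        module_of=module_of,
        module_changes=module_changes,
    )


def _synthesize(
    design: SyntheticDesign,
    cohort_label: str,
    truth_lfc: pd.DataFrame,
    module_of: pd.Series,
    symbols: pd.Series,
    rng: np.random.Generator,
) -> ExpressionMatrix:
    """Build one cohort's matrix from planted truth."""
    n_genes = design.n_genes
    sample_rows = []
    for group in design.groups:
        for sex in design.sexes:
            for i in range(1, design.n_per_group + 1):
                sid = f"{cohort_label}_{group}_{sex}_{i:02d}"
                sample_rows.append({"sample": sid, "group": group, "sex": sex, "cohort": cohort_label})
    sample_annotations = pd.DataFrame(sample_rows).set_index("sample")
    n_samples = len(sample_annotations)

    baseline = rng.normal(7.0, 2.0, n_genes)
    values = np.empty((n_genes, n_samples))

    module_ids = [m for m in module_of.unique() if m]
    module_index = {mid: np.flatnonzero((module_of == mid).to_numpy()) for mid in module_ids}
    spec_by_id = {f"M{i}": m for i, m in enumerate(design.modules, start=1)}

    groups_arr = sample_annotations["group"].to_numpy()
    for j in range(n_samples):
        eps = rng.standard_normal(n_genes)
        col = eps.copy()
        for mid in module_ids:
            spec = spec_by_id[mid]
            r = spec.r_treatment if groups_arr[j] == spec.group else spec.r_control
            f = rng.standard_normal()
            idx = module_index[mid]
            col[idx] = np.sqrt(abs(r)) * np.sign(r) * f + np.sqrt(1 - abs(r)) * eps[idx]
        values[:, j] = baseline + design.noise_sd * col

    # planted log2FC shifts in non-control groups
    for group in design.groups[1:]:
        cols = np.flatnonzero(groups_arr == group)
        values[:, cols] += truth_lfc[group].to_numpy()[:, None]

    gene_ids = symbols.to_numpy()
    gene_annotations = pd.DataFrame(
        {
            "symbol": gene_ids,
            "biotype": rng.choice(
                list(design.biotype_props), size=n_genes, p=list(design.biotype_props.values())
            ),
        },
        index=pd.Index(gene_ids, name="gene"),
    )
    vdf = pd.DataFrame(values, index=gene_annotations.index, columns=sample_annotations.index)
    return ExpressionMatrix(vdf, sample_annotations, gene_annotations)


def generate_cohort(
    design: SyntheticDesign, cohort_label: str = "a", seed: int | None = None
) -> tuple[ExpressionMatrix, SyntheticTruth]:
    """Generate one cohort with planted DE effects and modules.

    Identical (design, seed) pairs yield bit-identical output.  The cohort
    is generated as the "a" side of a virtual pair: conc_up / conc_down /
    disc / unique_a genes carry effects, unique_b genes are silent here.
    """
    seed = design.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    truth = _plant_truth(design, rng)
    genes = truth.classes.index
    symbols = pd.Series(genes, index=genes)
    matrix = _synthesize(design, cohort_label, truth.true_lfc["a"], truth.module_of, symbols, rng)
    truth.true_lfc = {cohort_label: truth.true_lfc["a"]}
    return matrix, truth


def generate_pair(
    design_a: SyntheticDesign,
    design_b: SyntheticDesign,
    seed: int | None = None,
    label_a: str = "human",
    label_b: str = "rodent",
) -> tuple[ExpressionMatrix, ExpressionMatrix, pd.DataFrame, SyntheticTruth]:
    """Generate two cohorts sharing planted concordance structure.

    Concordant genes receive same-sign true effects in both cohorts,
    discordant genes opposite signs, unique_a / unique_b effects in a single
    cohort.  Cohort a gene symbols are upper-case, cohort b title-case
    (exercising case-insensitive ortholog matching); the returned ortholog
    map is a two-column DataFrame (symbol_a, symbol_b) covering
    ortholog_coverage of the genes.
    """
    if design_a.groups != design_b.groups:
        raise ValueError("cohort designs must share group labels")
    if design_a.n_genes != design_b.n_genes:
        raise ValueError("cohort designs must share n_genes")
    for key in ("frac_concordant_up", "frac_concordant_down", "frac_discordant",
                "frac_unique_a", "frac_unique_b"):
        if getattr(design_a, key) != getattr(design_b, key):
            raise ValueError(f"cohort designs must share {key}")

    seed = design_a.seed if seed is None else seed
    master = np.random.default_rng(seed)
    truth = _plant_truth(design_a, master)
    genes = truth.classes.index
    symbols_a = pd.Series([g.upper() for g in genes], index=genes)
    symbols_b = pd.Series([g.capitalize() for g in genes], index=genes)

    rng_a = np.random.default_rng(master.integers(2**31))
    rng_b = np.random.default_rng(master.integers(2**31))
    mat_a = _synthesize(design_a, label_a, truth.true_lfc["a"], truth.module_of, symbols_a, rng_a)
    mat_b = _synthesize(design_b, label_b, truth.true_lfc["b"], truth.module_of, symbols_b, rng_b)

    n_mapped = int(round(design_a.ortholog_coverage * design_a.n_genes))
    mapped = master.permutation(design_a.n_genes)[:n_mapped]
    mapped.sort()
    orthologs = pd.DataFrame(
        {"symbol_a": symbols_a.iloc[mapped].to_numpy(), "symbol_b": symbols_b.iloc[mapped].to_numpy()}
    )
    truth.true_lfc = {label_a: truth.true_lfc["a"], label_b: truth.true_lfc["b"]}
    return mat_a, mat_b, orthologs, truth


@dataclass
class CellProfileMatrix:
    """Per-cell expression profiles for gene-set recovery scoring."""

    values: pd.DataFrame  # genes x cells
    cell_types: pd.Series  # per cell

    def rankings(self) -> pd.DataFrame:
        """Per-cell gene ranks, 1 = highest expression; ties broken by order."""
        return self.values.rank(axis=0, ascending=False, method="first").astype(int)


def generate_cell_profiles(
    n_cells: int,
    cell_types: list[str],
    module_genes: list[str],
    enriched_types: list[str],
    seed: int,
    universe: list[str] | None = None,
    n_genes: int = 1000,
    enrichment_strength: float = 2.0,
) -> CellProfileMatrix:
    """Simulate per-cell profiles where some cell types over-express a module.

    Cells of enriched types add Uniform(0, enrichment_strength) to module
    genes on top of Uniform(0, 1) background, pushing them to elevated rank
    positions; all other genes (and all genes in non-enriched cells) are
    exchangeable, so their rankings are uniform.
    """
    if len(module_genes) == 0:
        raise ValueError("module_genes must be nonempty")
    if not set(enriched_types) <= set(cell_types):
        raise ValueError("enriched_types must be a subset of cell_types")
    rng = np.random.default_rng(seed)
    if universe is None:
        universe = _canonical_genes(max(n_genes, len(module_genes)))
        universe = sorted(set(universe) | set(module_genes))
    if not set(module_genes) <= set(universe):
        raise ValueError("module_genes must lie in the gene universe")
    universe = list(universe)
    midx = np.array([universe.index(g) for g in module_genes])

    types = pd.Series(
        rng.choice(cell_types, size=n_cells), index=[f"cell{i:04d}" for i in range(n_cells)]
    )
    values = rng.random((len(universe), n_cells))
    enriched_cols = np.flatnonzero(types.isin(enriched_types).to_numpy())
    for j in enriched_cols:
        values[midx, j] += rng.uniform(0.0, enrichment_strength, size=len(midx))
    vdf = pd.DataFrame(values, index=pd.Index(universe, name="gene"), columns=types.index)
    return CellProfileMatrix(vdf, types)
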
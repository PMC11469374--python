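"""Shared in-memory containers.

The expression container is deliberately thin: a genes x samples values
DataFrame plus two annotation tables keyed 1:1 to its axes.  Differential
expression results, module assignments and enrichment tables are plain
pandas objects with documented columns rather than bespoke classes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

SAMPLE_ANNOTATION_COLUMNS = ("group", "sex", "cohort")
GENE_ANNOTATION_COLUMNS = ("symbol", "biotype")


@dataclass
class ExpressionMatrix:
    """Log2-scale expression, genes as rows, samples as columns.

    Attributes
    ----------
    values : pd.DataFrame
        Gene x sample matrix of finite log2 expression values.
    sample_annotations : pd.DataFrame
        Indexed by sample id; columns include ``group``, ``sex``, ``cohort``.
    gene_annotations : pd.DataFrame
        Indexed by gene id; columns include ``symbol``, ``biotype``.
    """

    values: pd.DataFrame
    sample_annotations: pd.DataFrame
    gene_annotations: pd.DataFrame

    def __post_init__(self) -> None:
        self.values.index.name = "gene"
        self.values.columns.name = "sample"
        self.sample_annotations.index.name = "sample"
        self.gene_annotations.index.name = "gene"
        self.validate()

    def validate(self) -> None:
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicated gene ids: {dups[:5]}")
        if self.values.columns.has_duplicates:
            dups = self.values.columns[self.values.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicated sample ids: {dups[:5]}")
        if not np.isfinite(self.values.to_numpy(dtype=float)).all():
            raise ValueError("expression values must be finite")
        if not self.sample_annotations.index.equals(self.values.columns):
            raise ValueError("sample annotations not keyed 1:1 to sample ids")
        if not self.gene_annotations.index.equals(self.values.index):
            raise ValueError("gene annotations not keyed 1:1 to gene ids")

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    def samples_where(self, group: str | None = None, sex: str | None = None) -> list[str]:
        """Sample ids matching the given group and/or sex."""
        mask = pd.Series(True, index=self.sample_annotations.index)
        if group is not None:
            mask &= self.sample_annotations["group"] == group
        if sex is not None:
            mask &= self.sample_annotations["sex"] == sex
        return list(self.sample_annotations.index[mask])

    def subset_genes(self, genes) -> "ExpressionMatrix":
        genes = list(genes)
        return ExpressionMatrix(
            self.values.loc[genes],
            self.sample_annotations,
            self.gene_annotations.loc[genes],
        )

    def subset_samples(self, samples) -> "ExpressionMatrix":
        samples = list(samples)
        return ExpressionMatrix(
            self.values[samples],
            self.sample_annotations.loc[samples],
            self.gene_annotations,
        )


@dataclass
class ModerationParams:
    """Empirical-Bayes variance moderation hyperparameters.

    d0 is the prior degrees of freedom (np.inf allowed: complete shrinkage),
    s0_sq the prior variance in log2 units squared, df_residual the residual
    degrees of freedom shared by all genes in the balanced two-group design.
    """

    d0: float
    s0_sq: float
    df_residual: float

    def __post_init__(self) -> None:
        if not (self.d0 >= 0):
            raise ValueError("d0 must be >= 0 (np.inf allowed)")
        if not (self.s0_sq > 0):
            raise ValueError("s0_sq must be > 0")


@dataclass
class GeneSetCollection:
    """Named gene sets (e.g. parsed from a GMT file)."""

    sets: dict[str, list[str]] = field(default_factory=dict)
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if len(genes) == 0:
                raise ValueError(f"gene set {name!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.items())
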
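"""Readers and writers for the pipeline's plain-text formats.

Expression matrices travel as a TSV (genes as rows, first column the gene
id, header row the sample ids) with sidecar sample- and gene-annotation
TSVs.  DE tables, module assignments and ortholog maps are flat TSVs;
gene-set collections use the standard GMT layout (name, description,
genes...).  Readers validate structure and name offending line numbers;
write-then-read round-trips values to full precision.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix, GeneSetCollection


def _check_unique(index: pd.Index, what: str, header_lines: int = 1) -> None:
    if index.has_duplicates:
        dup_mask = index.duplicated(keep=False)
        lines = [i + header_lines + 1 for i in np.flatnonzero(dup_mask)]
        names = index[dup_mask].unique().tolist()
        raise ValueError(f"duplicated {what} ids {names[:5]} at lines {lines[:10]}")


def write_expression_tsv(matrix: ExpressionMatrix, outdir, prefix: str = "expression") -> dict:
    """Write matrix + sidecar annotations; returns the paths written."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "matrix": outdir / f"{prefix}.tsv",
        "samples": outdir / f"{prefix}.samples.tsv",
        "genes": outdir / f"{prefix}.genes.tsv",
    }
    values = matrix.values.copy()
    values.index.name = "gene"
    values.to_csv(paths["matrix"], sep="\t", float_format=None)
    sa = matrix.sample_annotations.copy()
    sa.index.name = "sample"
    sa.to_csv(paths["samples"], sep="\t")
    ga = matrix.gene_annotations.copy()
    ga.index.name = "gene"
    ga.to_csv(paths["genes"], sep="\t")
    return {k: str(v) for k, v in paths.items()}


def read_expression_tsv(outdir, prefix: str = "expression") -> ExpressionMatrix:
    """Read a matrix written by write_expression_tsv."""
    outdir = Path(outdir)
    mpath = outdir / f"{prefix}.tsv"
    values = pd.read_csv(mpath, sep="\t", index_col=0)
    values.index.name = "gene"
    values.columns.name = "sample"
    _check_unique(values.index, "gene")
    _check_unique(pd.Index(values.columns), "sample")
    bad_cols = [c for c in values.columns if values[c].dtype == object]
    for col in bad_cols:
        for i, v in enumerate(values[col]):
            try:
                float(v)
            except (TypeError, ValueError):
                raise ValueError(
                    f"non-numeric cell {v!r} at line {i + 2}, column {col} in {mpath}"
                ) from None
        values[col] = values[col].astype(float)
    samples = pd.read_csv(outdir / f"{prefix}.samples.tsv", sep="\t", index_col=0)
    genes = pd.read_csv(outdir / f"{prefix}.genes.tsv", sep="\t", index_col=0)
    return ExpressionMatrix(values, samples.loc[values.columns], genes.loc[values.index])


def write_de_tsv(de: pd.DataFrame, path) -> str:
    out = de.copy()
    out.index.name = "gene"
    out.to_csv(path, sep="\t")
    return str(path)


def read_de_tsv(path) -> pd.DataFrame:
    de = pd.read_csv(path, sep="\t", index_col=0)
    _check_unique(de.index, "gene")
    required = {"log2FC", "p"}
    missing = required - set(de.columns)
    if missing:
        raise ValueError(f"DE table {path} missing columns {sorted(missing)}")
    return de


def read_gmt(path) -> GeneSetCollection:
    """Parse a GMT file: one set per line, tab-separated name, description, genes."""
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    text = Path(path).read_text()
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\r\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"GMT parse error at line {lineno} of {path}: "
                             f"expected >= 3 tab-separated fields, got {len(fields)}")
        name, desc, *genes = fields
        genes = [g for g in genes if g]
        if name in sets:
            raise ValueError(f"duplicate gene-set name {name!r} at line {lineno} of {path}")
        if not genes:
            raise ValueError(f"empty gene set {name!r} at line {lineno} of {path}")
        sets[name] = genes
        descriptions[name] = desc
    return GeneSetCollection(sets=sets, descriptions=descriptions)


def write_gmt(collection: GeneSetCollection, path) -> str:
    lines = []
    for name, genes in collection:
        desc = collection.descriptions.get(name, "")
        lines.append("\t".join([name, desc, *genes]))
    Path(path).write_text("\n".join(lines) + "\n")
    return str(path)


def read_ortholog_tsv(path) -> pd.DataFrame:
    """Two-column symbol map; a 'symbol_a<TAB>symbol_b' header is optional."""
    df = pd.read_csv(path, sep="\t", header=None, dtype=str)
    if df.shape[1] != 2:
        raise ValueError(f"ortholog map {path} must have exactly 2 columns, got {df.shape[1]}")
    if list(df.iloc[0]) == ["symbol_a", "symbol_b"]:
        df = df.iloc[1:].reset_index(drop=True)
    df.columns = ["symbol_a", "symbol_b"]
    if df.isna().any().any():
        bad = int(df.isna().any(axis=1).idxmax()) + 1
        raise ValueError(f"missing symbol at line {bad} of {path}")
    return df


def write_ortholog_tsv(orthologs: pd.DataFrame, path) -> str:
    orthologs[["symbol_a", "symbol_b"]].to_csv(path, sep="\t", index=False)
    return str(path)


def write_truth_json(truth, path) -> str:
    Path(path).write_text(truth.to_json())
    return str(path)


def write_json(obj, path) -> str:
    Path(path).write_text(json.dumps(obj, indent=1, sort_keys=True, default=str))
    return str(path)
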
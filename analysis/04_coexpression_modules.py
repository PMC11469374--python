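"""Co-expression modules, eigengenes and hubs in the human cohort.

Soft-thresholded adjacency over the most variable genes, TOM clustering
with a static cut, eigengene/kME computation, and MI-network hubs per
module (pooled samples, DPI-pruned).  The planted modules should surface
as the three largest detected colors.
"""

import argparse
import importlib

import pandas as pd

from crossconcord import coexpr, io

common = importlib.import_module("00_common")


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--n-genes", type=int, default=1200)
    parser.add_argument("--beta", type=float, default=6.0)
    args = parser.parse_args()

    matrix = io.read_expression_tsv(common.RESULTS / "data", "cohort_a")
    outdir = common.RESULTS / "modules"
    outdir.mkdir(parents=True, exist_ok=True)

    selected = coexpr.select_variable_genes(
        matrix, n=min(args.n_genes, len(matrix.gene_ids))
    )
    sub = matrix.subset_genes(selected)
    T = coexpr.tom(coexpr.adjacency(sub, args.beta))
    labels = coexpr.detect_modules(T, min_size=30, matrix=sub.values)
    eigengenes, kme = coexpr.module_eigengene(sub.values, labels)

    labels.rename("module").to_frame().to_csv(outdir / "modules.tsv", sep="\t")
    eigengenes.to_csv(outdir / "eigengenes.tsv", sep="\t")
    kme.to_csv(outdir / "kme.tsv", sep="\t")

    sizes = labels.value_counts()
    print("module sizes:")
    print(sizes.to_string())

    hub_rows = []
    for mod in [m for m in sizes.index if m != coexpr.UNASSIGNED]:
        genes = list(labels.index[labels == mod])
        edges = coexpr.mi_network_dpi(sub.values, genes)
        hubset = coexpr.identify_hubs(kme, labels[labels == mod], mi_edges=edges)
        df = hubset.hubs[mod].reset_index()
        df.insert(0, "module", mod)
        hub_rows.append(df)
    if hub_rows:
        hubs = pd.concat(hub_rows, ignore_index=True)
        hubs.to_csv(outdir / "hubs.tsv", sep="\t", index=False)
        print("\ntop hub per module:")
        print(hubs.groupby("module").head(1).to_string(index=False))


if __name__ == "__main__":
    main()
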
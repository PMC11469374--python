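"""DE-in-module enrichment and AUCell-style cell-type scoring.

Fisher tests of each stage's DE transcripts against each module over the
analyzed-gene background, then a simulated cell-profile experiment: the
withdrawal-gain module's genes are over-expressed in MSN-like cells, and
the per-cell recovery-curve AUC separates those cells from glia.
"""

import argparse
import importlib

import pandas as pd

from crossconcord import coexpr, demod, enrich, io, synthgen
from crossconcord.pipeline import stage_seed

common = importlib.import_module("00_common")


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--seed", type=int, default=7)
    args = parser.parse_args()

    matrix = io.read_expression_tsv(common.RESULTS / "data", "cohort_a")
    labels = pd.read_csv(common.RESULTS / "modules" / "modules.tsv",
                         sep="\t", index_col=0)["module"]
    background = list(labels.index)
    modules = [m for m in labels.unique() if m != coexpr.UNASSIGNED]
    outdir = common.RESULTS / "enrich"
    outdir.mkdir(parents=True, exist_ok=True)

    rows = []
    for case in ("intoxication", "withdrawal", "abstinence"):
        de = io.read_de_tsv(common.RESULTS / "de" / f"de_human_{case}_pooled.tsv")
        query = set(de.index[de["class"].isin(["up", "down"])]) & set(background)
        for mod in modules:
            row = enrich.fisher_enrichment(
                query, set(labels.index[labels == mod]), background,
                name=f"{case}:{mod}")
            rows.append(vars(row))
    fisher = pd.DataFrame(rows).set_index("name")
    fisher["q"] = demod.adjust_bh(fisher["p"].to_numpy())
    fisher.to_csv(outdir / "de_in_modules.tsv", sep="\t")
    print("DE-in-module enrichment (top rows):")
    print(fisher.sort_values("p").head(6).to_string())

    # cell-profile scoring of the largest detected module
    top_module = labels[labels != coexpr.UNASSIGNED].value_counts().index[0]
    module_genes = list(labels.index[labels == top_module])
    cells = synthgen.generate_cell_profiles(
        n_cells=600,
        cell_types=["MSN_D1", "MSN_D2", "astrocyte", "oligodendrocyte"],
        module_genes=module_genes,
        enriched_types=["MSN_D1", "MSN_D2"],
        seed=stage_seed(args.seed, "cells"),
        universe=background,
    )
    auc = enrich.aucell_score(cells.rankings(), module_genes, top_fraction=0.1)
    comparison = enrich.compare_module_scores(
        auc,
        groups=pd.Series(
            ["neuron" if t.startswith("MSN") else "glia" for t in cells.cell_types],
            index=auc.index,
        ),
    )
    per_type = auc.groupby(cells.cell_types).median().rename("median_auc")
    per_type.to_csv(outdir / "aucell_by_cell_type.tsv", sep="\t")
    print(f"\nmodule {top_module!r} AUCell medians by cell type:")
    print(per_type.to_string())
    print("\nneuron vs glia rank-sum:")
    print(comparison.to_string())


if __name__ == "__main__":
    main()
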
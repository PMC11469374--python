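"""Module differential connectivity per exposure stage.

For every detected module and every stage-vs-control comparison, computes
the MDC ratio and the two-scheme permutation p-values.  The module with a
planted correlation rise in withdrawal should be called "gain" there, the
planted fall in abstinence "loss", and the stable module "none".
"""

import argparse
import importlib

import pandas as pd

from crossconcord import coexpr, io, mdc
from crossconcord.pipeline import stage_seed

common = importlib.import_module("00_common")


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--seed", type=int, default=7)
    parser.add_argument("--nperm", type=int, default=200)
    parser.add_argument("--beta", type=float, default=6.0)
    args = parser.parse_args()

    matrix = io.read_expression_tsv(common.RESULTS / "data", "cohort_a")
    labels = pd.read_csv(common.RESULTS / "modules" / "modules.tsv",
                         sep="\t", index_col=0)["module"]
    labels = labels[labels != coexpr.UNASSIGNED]
    outdir = common.RESULTS / "mdc"
    outdir.mkdir(parents=True, exist_ok=True)

    frames = []
    for case in ("intoxication", "withdrawal", "abstinence"):
        result = mdc.mdc_test(
            matrix, case, "control", labels, beta=args.beta,
            n_perm=args.nperm, seed=stage_seed(args.seed, f"mdc:{case}"),
            universe_genes=list(matrix.gene_ids),
        )
        result.insert(0, "contrast", case)
        result.to_csv(outdir / f"mdc_{case}.tsv", sep="\t")
        frames.append(result.reset_index())
    combined = pd.concat(frames, ignore_index=True)
    print(combined.to_string(index=False))
    calls = combined[combined["call"] != "none"]
    print(f"\n{len(calls)} significant connectivity changes (q < 0.05)")


if __name__ == "__main__":
    main()
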
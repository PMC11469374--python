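"""Simulate the paired human/rodent study and write it to results/data.

Generates two cohorts with shared planted concordance structure, three
planted modules (one connectivity gain, one loss, one stable), and a 90%
ortholog map with species-style symbol casing.  Prints the planted class
counts so later steps can be read against the truth.
"""

import argparse
import importlib
import json

from crossconcord import io, synthgen

common = importlib.import_module("00_common")


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--seed", type=int, default=7)
    args = parser.parse_args()

    design = common.study_design()
    mat_a, mat_b, orthologs, truth = synthgen.generate_pair(
        design, design, seed=args.seed, label_a="human", label_b="rodent"
    )
    outdir = common.RESULTS / "data"
    io.write_expression_tsv(mat_a, outdir, "cohort_a")
    io.write_expression_tsv(mat_b, outdir, "cohort_b")
    io.write_ortholog_tsv(orthologs, outdir / "orthologs.tsv")
    io.write_truth_json(truth, outdir / "truth.json")

    counts = truth.classes.value_counts().to_dict()
    print(f"simulated {design.n_genes} genes x {design.n_samples} samples per cohort")
    print("planted DE classes:", json.dumps(counts))
    print("planted modules:", truth.module_changes.to_dict(orient="index"))
    print(f"wrote {outdir}")


if __name__ == "__main__":
    main()
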
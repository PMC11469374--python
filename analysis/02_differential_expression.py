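"""Moderated DE for every contrast and sex stratum in both cohorts.

Each exposure stage is compared against control (pooled, female-only,
male-only) with empirical-Bayes moderated t statistics; tables land in
results/de and a count summary (down/up per stratum, biotype split of the
DE set) is printed and saved.
"""

import argparse
import importlib

import pandas as pd

from crossconcord import demod, io

common = importlib.import_module("00_common")


def main() -> None:
    argparse.ArgumentParser().parse_args()
    data = common.RESULTS / "data"
    outdir = common.RESULTS / "de"
    outdir.mkdir(parents=True, exist_ok=True)

    rows = []
    for label, prefix in (("human", "cohort_a"), ("rodent", "cohort_b")):
        matrix = io.read_expression_tsv(data, prefix)
        groups = list(dict.fromkeys(matrix.sample_annotations["group"]))
        for case in groups[1:]:
            for sex in (None, "F", "M"):
                de = demod.run_de(matrix, (groups[0], case), sex=sex)
                tag = f"{label}_{case}_{sex or 'pooled'}"
                io.write_de_tsv(de, outdir / f"de_{tag}.tsv")
                counts = de["class"].value_counts()
                bios = demod.summarize_biotypes(de, matrix.gene_annotations)
                pc = bios["proportion"].get("protein_coding", float("nan"))
                rows.append({
                    "cohort": label, "contrast": f"control_vs_{case}",
                    "sex": sex or "pooled",
                    "down": int(counts.get("down", 0)),
                    "up": int(counts.get("up", 0)),
                    "protein_coding_frac": round(float(pc), 3),
                })
    summary = pd.DataFrame(rows)
    summary.to_csv(outdir / "de_counts.tsv", sep="\t", index=False)
    print(summary.to_string(index=False))
    print("\nDE tables in", outdir)


if __name__ == "__main__":
    main()
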
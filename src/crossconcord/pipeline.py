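"""End-to-end cross-cohort workflow.

One YAML config drives: simulate (or load) a paired two-cohort dataset,
moderated DE per sex stratum and exposure contrast in both cohorts,
signed RRHO between the cohorts' signatures per stratum/contrast,
co-expression module detection on the reference cohort, module
differential connectivity per contrast, DE-in-module enrichment, optional
ORA against a GMT collection, biotype summaries, and MI-network hubs.
All intermediates are written as TSV/JSON under the output directory and
the run report cross-references every file it summarizes.

Stage seeds derive from one master seed by stable hashing of the stage
name, so stages can be rerun independently yet reproducibly.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import coexpr, demod, enrich, io, mdc as mdc_mod, rrho, synthgen

logger = logging.getLogger(__name__)


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31."""
    digest = hashlib.sha256(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass
class PipelineConfig:
    """Validated run configuration (see from_yaml for the file layout)."""

    seed: int = 0
    outdir: str = "out"
    design_a: dict = field(default_factory=dict)
    design_b: dict = field(default_factory=dict)
    input_dir: str | None = None  # load instead of simulate
    contrasts: list[str] | None = None  # case groups, control is groups[0]
    sexes: list[str] | None = None  # strata; None = pooled only
    de: dict = field(default_factory=dict)
    rrho: dict = field(default_factory=dict)
    network: dict = field(default_factory=dict)
    mdc: dict = field(default_factory=dict)
    enrichment: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def validate(self) -> None:
        gmt = self.enrichment.get("gmt")
        if gmt and not Path(gmt).exists():
            raise FileNotFoundError(f"GMT path does not exist: {gmt}")
        if self.input_dir and not Path(self.input_dir).exists():
            raise FileNotFoundError(f"input directory does not exist: {self.input_dir}")
        for key in ("p_thresh", "lfc_thresh"):
            if key in self.de and self.de[key] <= 0:
                raise ValueError(f"DE threshold {key} must be positive")

    def config_hash(self) -> str:
        payload = json.dumps(
            {k: getattr(self, k) for k in self.__dataclass_fields__}, sort_keys=True, default=str
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _stage(report: dict, name: str):
    class _Ctx:
        def __enter__(self):
            logger.info("stage %s: start", name)
            self.t0 = time.time()
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None:
                logger.error("stage %s failed: %s", name, exc)
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
            report.setdefault("stages", []).append(
                {"stage": name, "seconds": round(time.time() - self.t0, 3)}
            )
            logger.info("stage %s: done", name)
            return False

    return _Ctx()


def run_crossspecies(config: PipelineConfig) -> dict:
    """Execute the full workflow; returns (and writes) the run report."""
    config.validate()
    out = Path(config.outdir)
    for sub in ("data", "de", "rrho", "modules", "mdc", "enrich"):
        (out / sub).mkdir(parents=True, exist_ok=True)
    report: dict = {
        "provenance": {
            "seed": config.seed,
            "config_hash": config.config_hash(),
            "package_version": __import__("crossconcord").__version__,
        },
        "files": {},
    }

    # ---- data -------------------------------------------------------------
    with _stage(report, "data"):
        if config.input_dir:
            mat_a = io.read_expression_tsv(config.input_dir, "cohort_a")
            mat_b = io.read_expression_tsv(config.input_dir, "cohort_b")
            orthologs = io.read_ortholog_tsv(Path(config.input_dir) / "orthologs.tsv")
            truth = None
        else:
            design_a = synthgen.SyntheticDesign(**config.design_a)
            design_b = synthgen.SyntheticDesign(**{**config.design_a, **config.design_b})
            mat_a, mat_b, orthologs, truth = synthgen.generate_pair(
                design_a, design_b, seed=stage_seed(config.seed, "simulate")
            )
            report["files"]["truth"] = io.write_truth_json(truth, out / "data" / "truth.json")
        report["files"]["cohort_a"] = io.write_expression_tsv(mat_a, out / "data", "cohort_a")
        report["files"]["cohort_b"] = io.write_expression_tsv(mat_b, out / "data", "cohort_b")
        report["files"]["orthologs"] = io.write_ortholog_tsv(
            orthologs, out / "data" / "orthologs.tsv"
        )

    groups_a = list(dict.fromkeys(mat_a.sample_annotations["group"]))
    control = groups_a[0]
    contrasts = config.contrasts or [g for g in groups_a if g != control]
    strata: list[str | None] = [None] + list(config.sexes or [])

    # ---- differential expression -----------------------------------------
    de_tables: dict[tuple[str, str, str | None], pd.DataFrame] = {}
    with _stage(report, "de"):
        de_kwargs = dict(
            p_thresh=config.de.get("p_thresh", demod.P_THRESHOLD),
            lfc_thresh=config.de.get("lfc_thresh", demod.LFC_THRESHOLD),
            use_q_for_calls=config.de.get("use_q", False),
        )
        report["de_counts"] = []
        for label, mat in (("a", mat_a), ("b", mat_b)):
            for case in contrasts:
                for sex in strata:
                    table = demod.run_de(mat, (control, case), sex=sex, **de_kwargs)
                    de_tables[(label, case, sex)] = table
                    tag = f"{label}_{case}" + (f"_{sex}" if sex else "_pooled")
                    path = io.write_de_tsv(table, out / "de" / f"de_{tag}.tsv")
                    report["files"][f"de_{tag}"] = path
                    counts = table["class"].value_counts()
                    entry = {
                        "cohort": label, "contrast": f"{control}_vs_{case}",
                        "sex": sex or "pooled",
                        "up": int(counts.get("up", 0)), "down": int(counts.get("down", 0)),
                        "file": path,
                    }
                    bios = demod.summarize_biotypes(table, mat.gene_annotations)
                    entry["biotypes"] = {
                        b: {"count": int(r["count"]), "proportion": round(float(r["proportion"]), 4)}
                        for b, r in bios.iterrows()
                    }
                    report["de_counts"].append(entry)

    # ---- RRHO -------------------------------------------------------------
    with _stage(report, "rrho"):
        report["rrho"] = []
        step = config.rrho.get("step")
        for case in contrasts:
            for sex in strata:
                sig_a, sig_b = rrho.align_signatures(
                    de_tables[("a", case, sex)], de_tables[("b", case, sex)], orthologs
                )
                rmap = rrho.compute_rrho_map(sig_a, sig_b, step=step)
                tag = f"{case}" + (f"_{sex}" if sex else "_pooled")
                frames = rmap.signed_frames()
                for quad, frame in frames.items():
                    path = out / "rrho" / f"rrho_{tag}_{quad}.tsv"
                    frame.to_csv(path, sep="\t")
                    report["files"][f"rrho_{tag}_{quad}"] = str(path)
                genes_path = out / "rrho" / f"rrho_{tag}_concordant_genes.txt"
                genes_path.write_text(
                    "\n".join(sorted(set(rmap.gene_sets["down-down"])
                                     | set(rmap.gene_sets["up-up"]))) + "\n"
                )
                report["files"][f"rrho_{tag}_genes"] = str(genes_path)
                report["rrho"].append({
                    "contrast": f"{control}_vs_{case}", "sex": sex or "pooled",
                    "quadrant_max": {q: rmap.summaries[q]["max"] for q in rrho.QUADRANTS},
                })

    # ---- modules ----------------------------------------------------------
    with _stage(report, "modules"):
        n_net = min(config.network.get("n_genes", 5000), len(mat_a.gene_ids))
        selected = coexpr.select_variable_genes(mat_a, n=n_net)
        sub = mat_a.subset_genes(selected)
        beta = config.network.get("beta") or coexpr.pick_soft_threshold(sub)
        A = coexpr.adjacency(sub, beta)
        T = coexpr.tom(A)
        labels = coexpr.detect_modules(
            T,
            min_size=config.network.get("min_size", 30),
            merge_height=config.network.get("merge_height", 0.15),
            matrix=sub.values,
        )
        eigengenes, kme = coexpr.module_eigengene(sub.values, labels)
        labels.rename("module").to_frame().to_csv(out / "modules" / "modules.tsv", sep="\t")
        eigengenes.to_csv(out / "modules" / "eigengenes.tsv", sep="\t")
        kme.to_csv(out / "modules" / "kme.tsv", sep="\t")
        report["files"]["modules"] = str(out / "modules" / "modules.tsv")
        report["network"] = {
            "n_genes": n_net, "beta": beta,
            "module_sizes": {m: int(c) for m, c in labels.value_counts().items()},
        }

    modules_present = [m for m in labels.unique() if m != coexpr.UNASSIGNED]

    # ---- MDC --------------------------------------------------------------
    with _stage(report, "mdc"):
        report["mdc"] = []
        if modules_present:
            module_labels = labels[labels != coexpr.UNASSIGNED]
            n_perm = config.mdc.get("n_perm", 1000)
            for case in contrasts:
                result = mdc_mod.mdc_test(
                    sub, case, control, module_labels, beta,
                    n_perm=n_perm, seed=stage_seed(config.seed, f"mdc:{case}"),
                    universe_genes=selected,
                )
                path = out / "mdc" / f"mdc_{case}.tsv"
                result.to_csv(path, sep="\t")
                report["files"][f"mdc_{case}"] = str(path)
                report["mdc"].append({
                    "contrast": f"{control}_vs_{case}",
                    "calls": {m: row["call"] for m, row in result.iterrows()},
                    "file": str(path),
                })

    # ---- enrichment -------------------------------------------------------
    with _stage(report, "enrich"):
        report["enrichment"] = {}
        background = set(selected)
        rows = []
        for case in contrasts:
            de_a = de_tables[("a", case, None)]
            de_genes = set(de_a.index[de_a["class"].isin(["up", "down"])]) & background
            if not de_genes:
                continue
            for mod in modules_present:
                target = set(labels.index[labels == mod])
                row = enrich.fisher_enrichment(de_genes, target, background,
                                               name=f"{case}:{mod}")
                rows.append(vars(row))
        if rows:
            fisher_df = pd.DataFrame(rows).set_index("name")
            fisher_df["q"] = demod.adjust_bh(fisher_df["p"].to_numpy())
            path = out / "enrich" / "de_in_modules.tsv"
            fisher_df.to_csv(path, sep="\t")
            report["files"]["de_in_modules"] = str(path)
            report["enrichment"]["de_in_modules"] = str(path)
        gmt_path = config.enrichment.get("gmt")
        if gmt_path:
            collection = io.read_gmt(gmt_path)
            for case in contrasts:
                de_a = de_tables[("a", case, None)]
                query = set(de_a.index[de_a["class"].isin(["up", "down"])]) & background
                if not query:
                    continue
                table = enrich.ora(collection, query, background)
                path = out / "enrich" / f"ora_{case}.tsv"
                table.to_csv(path, sep="\t")
                report["files"][f"ora_{case}"] = str(path)

    # ---- hubs -------------------------------------------------------------
    with _stage(report, "hubs"):
        report["hubs"] = {}
        if modules_present:
            case = contrasts[0]
            case_samples = sub.samples_where(group=case)
            ctrl_samples = sub.samples_where(group=control)
            hub_rows = []
            for mod in modules_present:
                genes = list(labels.index[labels == mod])
                pooled_edges = coexpr.mi_network_dpi(sub.values, genes)
                nets = {
                    "case": coexpr.mi_network_dpi(sub.values[case_samples], genes),
                    "control": coexpr.mi_network_dpi(sub.values[ctrl_samples], genes),
                }
                hubset = coexpr.identify_hubs(
                    kme, labels[labels == mod],
                    de_table=de_tables[("a", case, None)],
                    condition_networks=nets, mi_edges=pooled_edges,
                )
                df = hubset.hubs[mod].reset_index()
                df.insert(0, "module", mod)
                hub_rows.append(df)
            hubs_df = pd.concat(hub_rows, ignore_index=True)
            path = out / "enrich" / "hubs.tsv"
            hubs_df.to_csv(path, sep="\t", index=False)
            report["files"]["hubs"] = str(path)
            report["hubs"] = {
                mod: hubs_df.loc[hubs_df["module"] == mod, "gene"].tolist()
                for mod in modules_present
            }

    # ---- report -----------------------------------------------------------
    with _stage(report, "report"):
        io.write_json(report, out / "report.json")
        summary = [
            f"crossconcord run (seed={config.seed}, config={report['provenance']['config_hash']})",
            f"contrasts: {', '.join(contrasts)} vs {control}",
        ]
        for entry in report["de_counts"]:
            summary.append(
                f"DE {entry['cohort']} {entry['contrast']} [{entry['sex']}]: "
                f"{entry['down']} down / {entry['up']} up"
            )
        for entry in report["rrho"]:
            qm = entry["quadrant_max"]
            summary.append(
                f"RRHO {entry['contrast']} [{entry['sex']}]: "
                f"dd={qm['down-down']:.1f} uu={qm['up-up']:.1f} "
                f"du={qm['down-up']:.1f} ud={qm['up-down']:.1f}"
            )
        (out / "summary.txt").write_text("\n".join(summary) + "\n")
        report["files"]["summary"] = str(out / "summary.txt")
    return report
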
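"""Shared study design for the analysis drivers.

Two cohorts ("human", "rodent"), control plus three opioid-exposure
stages, both sexes, 10 samples per group per sex.  Concordant effects
dominate the planted DE structure, one module gains connectivity in
withdrawal and one loses it in abstinence.
"""

from pathlib import Path

from crossconcord.synthgen import ModuleSpec, SyntheticDesign

RESULTS = Path(__file__).resolve().parent.parent / "results"


def study_design(n_genes: int = 1200) -> SyntheticDesign:
    return SyntheticDesign(
        n_genes=n_genes,
        groups=("control", "intoxication", "withdrawal", "abstinence"),
        n_per_group=10,
        sexes=("F", "M"),
        frac_concordant_up=0.05,
        frac_concordant_down=0.08,
        frac_discordant=0.02,
        frac_unique_a=0.02,
        frac_unique_b=0.02,
        modules=(
            ModuleSpec(size=60, r_control=0.2, r_treatment=0.6, group="withdrawal"),
            ModuleSpec(size=50, r_control=0.6, r_treatment=0.2, group="abstinence"),
            ModuleSpec(size=40, r_control=0.5, r_treatment=0.5, group="withdrawal"),
        ),
        ortholog_coverage=0.9,
    )
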
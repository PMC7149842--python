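"""Domain types, file I/O and the packaged reference cohort."""

from importlib import resources

from .fixture import CONTROL_CARRIER_COUNTS, build_reference_cohort
from .models import (
    CODING_CONSEQUENCES,
    CohortDataset,
    Consequence,
    GenePanel,
    Group,
    IndividualRecord,
    VariantRecord,
)
from .readers import (
    AnnotatedVariant,
    build_cohort,
    read_annotated_variants,
    read_cohort_tsv,
    read_gene_panel,
    read_roster,
    read_vcf,
)
from .writers import write_burden_table, write_cohort_tsv, write_oligogenic_table

__all__ = [
    "AnnotatedVariant",
    "CODING_CONSEQUENCES",
    "CONTROL_CARRIER_COUNTS",
    "CohortDataset",
    "Consequence",
    "GenePanel",
    "Group",
    "IndividualRecord",
    "VariantRecord",
    "build_cohort",
    "build_reference_cohort",
    "candidate_panel",
    "known_panel",
    "read_annotated_variants",
    "read_cohort_tsv",
    "read_gene_panel",
    "read_roster",
    "read_vcf",
    "write_burden_table",
    "write_cohort_tsv",
    "write_oligogenic_table",
]


def _packaged_panel(filename: str, name: str) -> GenePanel:
    ref = resources.files("geneburden").joinpath("data", filename)
    symbols = [
        line.split("#", 1)[0].strip()
        for line in ref.read_text(encoding="utf-8").splitlines()
    ]
    return GenePanel(name=name, genes=[s for s in symbols if s])


def candidate_panel() -> GenePanel:
    """The packaged 96-gene candidate panel (vertebral segmentation defects)."""
    return _packaged_panel("candidate_panel_96.txt", "candidate_96")


def known_panel() -> GenePanel:
    """The packaged 5-gene panel of previously reported causal genes."""
    return _packaged_panel("known_panel.txt", "known_genes")
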
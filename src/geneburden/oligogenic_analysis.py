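"""Multi-gene (oligogenic) carrier identification and enrichment.

An individual is a *multi-gene carrier* when their qualifying variants
span at least ``min_genes`` (default 2) distinct panel genes — distinct
genes, not distinct variants: two qualifying variants in one gene do not
qualify an individual. Enrichment of multi-gene carriers in cases versus
controls is tested with the same 2x2 kernel as the burden scan, with the
chi-square p reported headline-style and Fisher values alongside.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import FrozenSet, List, Optional, Tuple

import numpy as np

from .burden_stats import TwoByTwo, fisher_exact, pearson_chi2
from .cohort_model_io.models import CohortDataset, GenePanel, Group
from .qualifying_filter import QualifyingVariantSet

__all__ = [
    "IndividualGeneHits",
    "OligogenicResult",
    "genes_hit_per_individual",
    "multigene_carriers",
    "oligogenic_enrichment",
    "combination_report",
]


@dataclass(frozen=True)
class IndividualGeneHits:
    """Qualifying (gene, variant-key) pairs for one individual."""

    individual_id: str
    group: Group
    hits: FrozenSet[tuple]  # (gene_symbol, (chrom,pos,ref,alt))

    @property
    def genes(self) -> FrozenSet[str]:
        return frozenset(g for g, _ in self.hits)

    @property
    def distinct_gene_count(self) -> int:
        return len(self.genes)


@dataclass(frozen=True)
class OligogenicResult:
    min_genes: int
    table: TwoByTwo  # a = case multi-gene carriers, c = control multi-gene carriers
    case_percent: float  # case proportion as a percentage (1 decimal)
    chi2_statistic: float
    p_chi2: float
    p_fisher_one_sided: float
    p_fisher_two_sided: float
    case_carrier_ids: Tuple[str, ...]
    control_carrier_ids: Tuple[str, ...]
    combination_rows: Tuple[tuple, ...]  # (individual_id, gene, variant_type, hgvs_c)


def genes_hit_per_individual(
    cohort: CohortDataset,
    qualifying: QualifyingVariantSet,
    panel: Optional[GenePanel] = None,
) -> List[IndividualGeneHits]:
    """One entry per individual (both groups), ordered by individual id."""
    hit_sets: List[set] = [set() for _ in range(cohort.n_individuals)]
    for j in qualifying.indices:
        variant = cohort.variants[j]
        gene = variant.gene_symbol.upper()
        if panel is not None and gene not in panel:
            continue
        for i in np.flatnonzero(cohort.dosages[:, j] >= 1):
            hit_sets[i].add((gene, variant.key))
    out = [
        IndividualGeneHits(
            individual_id=ind.individual_id, group=ind.group, hits=frozenset(hit_sets[i])
        )
        for i, ind in enumerate(cohort.individuals)
    ]
    out.sort(key=lambda h: h.individual_id)
    return out


def multigene_carriers(
    hits: List[IndividualGeneHits],
    group: Group,
    min_genes: int = 2,
) -> List[str]:
    """Sorted ids of group members hitting >= min_genes distinct genes."""
    if min_genes < 2:
        raise ValueError("min_genes must be >= 2")
    return sorted(
        h.individual_id
        for h in hits
        if h.group is group and h.distinct_gene_count >= min_genes
    )


def combination_report(
    hits: List[IndividualGeneHits],
    cohort: CohortDataset,
    min_genes: int = 2,
) -> List[tuple]:
    """(individual, gene, variant type, nomenclature) rows for every
    qualifying variant of every multi-gene *case* carrier, ordered by
    individual id then gene."""
    carrier_ids = set(multigene_carriers(hits, Group.CASE, min_genes))
    variant_by_key = {v.key: v for v in cohort.variants}
    rows = []
    for h in hits:
        if h.individual_id not in carrier_ids:
            continue
        for gene, key in sorted(h.hits):
            variant = variant_by_key[key]
            rows.append((h.individual_id, gene, variant.consequence.value, variant.hgvs_c))
    rows.sort(key=lambda r: (r[0], r[1]))
    return rows


def oligogenic_enrichment(
    cohort: CohortDataset,
    hits: List[IndividualGeneHits],
    min_genes: int = 2,
) -> OligogenicResult:
    """Test enrichment of multi-gene carriers in cases versus controls."""
    cohort.require_both_groups()
    case_ids = multigene_carriers(hits, Group.CASE, min_genes)
    control_ids = multigene_carriers(hits, Group.CONTROL, min_genes)
    n_cases = cohort.group_size(Group.CASE)
    n_controls = cohort.group_size(Group.CONTROL)
    table = TwoByTwo(
        len(case_ids), n_cases - len(case_ids),
        len(control_ids), n_controls - len(control_ids),
    )
    statistic, p_chi2 = pearson_chi2(table)
    return OligogenicResult(
        min_genes=min_genes,
        table=table,
        case_percent=round(100.0 * table.a / n_cases, 1),
        chi2_statistic=statistic,
        p_chi2=p_chi2,
        p_fisher_one_sided=fisher_exact(table, "one_sided_enrichment"),
        p_fisher_two_sided=fisher_exact(table, "two_sided"),
        case_carrier_ids=tuple(case_ids),
        control_carrier_ids=tuple(control_ids),
        combination_rows=tuple(combination_report(hits, cohort, min_genes)),
    )
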
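"""Qualifying-variant selection.

A variant *qualifies* when it is rare both internally (folded minor-allele
frequency in the combined case+control cohort) and externally (maximum
allele frequency over the configured reference populations), has an
allowed consequence class, and — when a panel restriction is active —
falls in a panel gene. Criteria are evaluated in the fixed order
``internal, external, consequence, panel`` so the audit trail is
reproducible; the conjunction itself is order-free.

Synonymous variants are allowed by default (the default consequence set is
every class except ``other``); turn them off via
``FilterConfig.allowed_consequences``. Pathogenicity scores are carried
through but never gate qualification by default: optional ``min_gerp`` /
``min_cadd`` hooks exist for users who want score thresholds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .cohort_model_io.models import (
    CODING_CONSEQUENCES,
    CohortDataset,
    Consequence,
    GenePanel,
    Group,
    VariantRecord,
)

logger = logging.getLogger(__name__)

__all__ = [
    "FilterConfig",
    "QualifyingVariantSet",
    "compute_internal_af",
    "external_af_max",
    "is_qualifying",
    "select_qualifying",
    "known_gene_screen",
    "flag_inhouse_inconsistencies",
]

#: audit order in which criteria are checked
CRITERIA = ("internal", "external", "consequence", "panel")


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds and toggles for qualifying-variant selection."""

    maf_internal_max: float = 0.001
    maf_external_max: float = 0.001
    external_sources: Tuple[str, ...] = ("ExAC", "gnomAD")
    allowed_consequences: frozenset = field(default_factory=lambda: CODING_CONSEQUENCES)
    restrict_to_panel: bool = True
    min_gerp: Optional[float] = None  # optional score gates, off by default
    min_cadd: Optional[float] = None

    def __post_init__(self) -> None:
        for name in ("maf_internal_max", "maf_external_max"):
            value = getattr(self, name)
            if not (0.0 < value <= 1.0):
                raise ValueError(f"{name} must be in (0,1], got {value}")
        if not self.allowed_consequences:
            raise ValueError("allowed_consequences must be non-empty")
        object.__setattr__(self, "allowed_consequences", frozenset(self.allowed_consequences))


@dataclass(frozen=True)
class QualifyingVariantSet:
    """Result of applying the filter to every variant of a cohort."""

    indices: Tuple[int, ...]  # retained variant indices, ascending
    internal_afs: Tuple[float, ...]  # internal folded MAF per cohort variant (all of them)
    reasons: Tuple[Optional[str], ...]  # per cohort variant: None if retained, else failed criterion
    removed_by_criterion: Dict[str, int]

    def __contains__(self, variant_index: int) -> bool:
        return self.reasons[variant_index] is None

    def __len__(self) -> int:
        return len(self.indices)


def compute_internal_af(cohort: CohortDataset, variant_index: int) -> float:
    """Folded minor-allele frequency in the combined case+control cohort."""
    if not (0 <= variant_index < cohort.n_variants):
        raise IndexError(f"variant index {variant_index} out of range")
    n = cohort.n_individuals
    if n < 1:
        raise ValueError("cohort has no individuals")
    freq = float(cohort.dosages[:, variant_index].sum()) / (2 * n)
    return min(freq, 1.0 - freq)


def external_af_max(variant: VariantRecord, sources: Sequence[str]) -> float:
    """Maximum allele frequency over the present sources; 0 if none present."""
    return max((variant.external_afs[s] for s in sources if s in variant.external_afs), default=0.0)


def is_qualifying(
    variant: VariantRecord,
    internal_af: float,
    config: FilterConfig,
    panel: Optional[GenePanel] = None,
) -> Tuple[bool, Optional[str]]:
    """Check all criteria; on failure return the first failed criterion name."""
    if internal_af >= config.maf_internal_max:
        return False, "internal"
    if external_af_max(variant, config.external_sources) >= config.maf_external_max:
        return False, "external"
    if variant.consequence not in config.allowed_consequences:
        return False, "consequence"
    if config.restrict_to_panel and panel is not None and variant.gene_symbol not in panel:
        return False, "panel"
    if config.min_gerp is not None and variant.scores.get("gerp", np.inf) < config.min_gerp:
        return False, "score"
    if config.min_cadd is not None and variant.scores.get("cadd", np.inf) < config.min_cadd:
        return False, "score"
    return True, None


def select_qualifying(
    cohort: CohortDataset,
    config: FilterConfig,
    panel: Optional[GenePanel] = None,
) -> QualifyingVariantSet:
    """Apply :func:`is_qualifying` to every variant of the cohort."""
    if cohort.n_individuals == 0:
        raise ValueError("cohort is empty")
    # vectorized internal AF for all variants at once
    n = cohort.n_individuals
    freqs = cohort.dosages.sum(axis=0, dtype=np.int64) / (2.0 * n)
    internal_afs = np.minimum(freqs, 1.0 - freqs)

    indices: List[int] = []
    reasons: List[Optional[str]] = []
    removed: Dict[str, int] = {}
    for j, variant in enumerate(cohort.variants):
        ok, reason = is_qualifying(variant, float(internal_afs[j]), config, panel)
        reasons.append(reason)
        if ok:
            indices.append(j)
        else:
            removed[reason] = removed.get(reason, 0) + 1
    for criterion, count in sorted(removed.items()):
        logger.info("filter: removed %d variant(s) by %s criterion", count, criterion)
    logger.info("filter: retained %d of %d variants", len(indices), cohort.n_variants)
    return QualifyingVariantSet(
        indices=tuple(indices),
        internal_afs=tuple(float(f) for f in internal_afs),
        reasons=tuple(reasons),
        removed_by_criterion=removed,
    )


def known_gene_screen(
    qualifying: QualifyingVariantSet,
    cohort: CohortDataset,
    known: GenePanel,
) -> List[dict]:
    """Report every (case, qualifying variant) pair in the known genes.

    Rows are sorted by gene symbol, then patient id.
    """
    case_mask = cohort.group_mask(Group.CASE)
    rows = []
    for j in qualifying.indices:
        variant = cohort.variants[j]
        if variant.gene_symbol not in known:
            continue
        for i in np.flatnonzero(cohort.dosages[:, j] >= 1):
            if not case_mask[i]:
                continue
            rows.append(
                {
                    "gene": variant.gene_symbol,
                    "patient": cohort.individuals[i].individual_id,
                    "variant": f"{variant.chrom}:{variant.pos}:{variant.ref}>{variant.alt}",
                    "hgvs_c": variant.hgvs_c,
                    "zygosity": "hom" if cohort.dosages[i, j] == 2 else "het",
                    "external_afs": dict(variant.external_afs),
                    "internal_af": qualifying.internal_afs[j],
                }
            )
    rows.sort(key=lambda r: (r["gene"], r["patient"]))
    return rows


def flag_inhouse_inconsistencies(
    cohort: CohortDataset,
    qualifying: QualifyingVariantSet,
    threshold: float = 0.001,
    source: str = "in_house",
) -> List[int]:
    """Flag retained variants whose in-house database AF exceeds the threshold.

    Such variants are reported, not dropped: an annotation-supplied in-house
    AF can disagree with the internal AF of the cohort actually presented.
    """
    flagged = []
    for j in qualifying.indices:
        af = cohort.variants[j].external_afs.get(source)
        if af is not None and af >= threshold:
            flagged.append(j)
            logger.warning(
                "variant %s (%s) retained but %s AF %g >= %g",
                cohort.variants[j].key, cohort.variants[j].gene_symbol, source, af, threshold,
            )
    return flagged
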
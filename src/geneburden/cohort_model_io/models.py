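"""Core domain types: variants, individuals, cohorts, gene panels.

Conventions
-----------
* Coordinates are 1-based (VCF style); a variant is identified by the
  4-tuple ``(chrom, pos, ref, alt)``.
* Genotypes are stored as an individuals x variants dosage matrix with
  entries in {0, 1, 2}; a *carrier* is an individual with dosage >= 1.
* An external allele frequency that is absent (e.g. a "novel" variant
  never seen in the reference population) is simply missing from
  ``external_afs`` and is treated as frequency 0 downstream.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

__all__ = [
    "Consequence",
    "Group",
    "VariantRecord",
    "IndividualRecord",
    "CohortDataset",
    "GenePanel",
    "CODING_CONSEQUENCES",
]


class Consequence(str, enum.Enum):
    """Functional consequence class of a variant."""

    MISSENSE = "missense"
    SYNONYMOUS = "synonymous"
    NONSENSE = "nonsense"
    FRAMESHIFT = "frameshift"
    INFRAME_INSERTION = "inframe_insertion"
    INFRAME_DELETION = "inframe_deletion"
    SPLICE_REGION = "splice_region"
    SPLICE_ACCEPTOR = "splice_acceptor"
    SPLICE_DONOR = "splice_donor"
    OTHER = "other"

    @classmethod
    def parse(cls, label: str) -> "Consequence":
        try:
            return cls(label.strip().lower().replace(" ", "_").replace("-", "_"))
        except ValueError:
            valid = ", ".join(c.value for c in cls)
            raise ValueError(
                f"unknown consequence label {label!r}; expected one of: {valid}"
            ) from None


#: Consequence classes counted as coding/splice for filtering purposes.
CODING_CONSEQUENCES = frozenset(c for c in Consequence if c is not Consequence.OTHER)


class Group(str, enum.Enum):
    CASE = "case"
    CONTROL = "control"


@dataclass(frozen=True)
class VariantRecord:
    """One annotated variant.

    ``external_afs`` maps a reference-population source name (e.g.
    ``"ExAC"``, ``"gnomAD"``) to an allele frequency; absent sources mean
    the variant was not observed there. ``scores`` carries precomputed
    conservation/pathogenicity annotations (gerp, cadd, sift, polyphen2,
    mutationtaster); they are reported but never computed here.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    gene_symbol: str
    consequence: Consequence
    transcript: Optional[str] = None
    hgvs_c: Optional[str] = None
    hgvs_p: Optional[str] = None
    external_afs: Mapping[str, float] = field(default_factory=dict)
    scores: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise ValueError(f"ref and alt are identical ({self.ref!r})")
        if not isinstance(self.consequence, Consequence):
            object.__setattr__(self, "consequence", Consequence.parse(str(self.consequence)))
        for source, af in self.external_afs.items():
            if not (0.0 <= af <= 1.0):
                raise ValueError(f"allele frequency for {source!r} out of [0,1]: {af}")

    @property
    def key(self) -> tuple:
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass(frozen=True)
class IndividualRecord:
    individual_id: str
    group: Group
    sex: Optional[str] = None
    age: Optional[float] = None

    def __post_init__(self) -> None:
        if not self.individual_id:
            raise ValueError("individual_id must be non-empty")
        if not isinstance(self.group, Group):
            object.__setattr__(self, "group", Group(str(self.group)))


class CohortDataset:
    """Ordered individuals x ordered variants with a dosage matrix.

    Parameters
    ----------
    individuals : sequence of IndividualRecord
    variants : sequence of VariantRecord
    dosages : array-like of shape (n_individuals, n_variants), entries in {0,1,2}
    """

    def __init__(
        self,
        individuals: Sequence[IndividualRecord],
        variants: Sequence[VariantRecord],
        dosages,
    ) -> None:
        self.individuals = list(individuals)
        self.variants = list(variants)
        dosages = np.asarray(dosages, dtype=np.int8)
        if dosages.ndim != 2 or dosages.shape != (len(self.individuals), len(self.variants)):
            raise ValueError(
                f"dosage matrix shape {dosages.shape} does not match "
                f"{len(self.individuals)} individuals x {len(self.variants)} variants"
            )
        if dosages.size and (dosages.min() < 0 or dosages.max() > 2):
            raise ValueError("dosages must be in {0, 1, 2}")
        self.dosages = dosages

        ids = [ind.individual_id for ind in self.individuals]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate individual ids in cohort")
        keys = [v.key for v in self.variants]
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate (chrom,pos,ref,alt) variant keys in cohort")

        self._id_index = {iid: i for i, iid in enumerate(ids)}

    # -- convenience accessors -------------------------------------------------

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def individual_index(self, individual_id: str) -> int:
        return self._id_index[individual_id]

    def group_mask(self, group: Group) -> np.ndarray:
        return np.array([ind.group is group for ind in self.individuals], dtype=bool)

    def group_size(self, group: Group) -> int:
        return int(self.group_mask(group).sum())

    def variant_indices_for_gene(self, gene_symbol: str) -> list:
        g = gene_symbol.upper()
        return [i for i, v in enumerate(self.variants) if v.gene_symbol.upper() == g]

    def require_both_groups(self) -> None:
        if self.group_size(Group.CASE) < 1 or self.group_size(Group.CONTROL) < 1:
            raise ValueError("operation requires at least one case and one control")

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CohortDataset):
            return NotImplemented
        return (
            self.individuals == other.individuals
            and self.variants == other.variants
            and np.array_equal(self.dosages, other.dosages)
        )

    def __repr__(self) -> str:
        return (
            f"CohortDataset({self.group_size(Group.CASE)} cases, "
            f"{self.group_size(Group.CONTROL)} controls, {self.n_variants} variants)"
        )


class GenePanel:
    """A named set of gene symbols, upper-cased and de-duplicated."""

    def __init__(self, name: str, genes: Iterable[str]) -> None:
        normalized = {g.strip().upper() for g in genes if g.strip()}
        if not normalized:
            raise ValueError(f"gene panel {name!r} is empty")
        self.name = name
        self.genes = frozenset(normalized)

    def __contains__(self, gene_symbol: str) -> bool:
        return gene_symbol.strip().upper() in self.genes

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self):
        return iter(sorted(self.genes))

    def __repr__(self) -> str:
        return f"GenePanel({self.name!r}, {len(self.genes)} genes)"
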
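"""Readers for the supported input formats.

Formats
-------
* Annotated-variant TSV: one row per variant, tab-separated, UTF-8.
  Mandatory columns: ``chrom, pos, ref, alt, gene, consequence``.
  Optional: ``transcript, hgvs_c, hgvs_p``, any number of ``<source>_af``
  allele-frequency columns, score columns (``gerp, cadd, sift, polyphen2,
  mutationtaster``) and a ``carriers`` column listing individual ids
  separated by ``;`` with an optional ``:hom`` suffix.
  Empty cells, ``.`` and the literal ``Novel`` all mean "missing".
* Individual roster TSV: columns ``individual_id, group`` (+ optional
  ``sex, age``).
* Gene panel: plain text, one symbol per line, ``#`` comments.
* VCF v4.x with GT genotypes, annotations supplied as a sidecar TSV.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np

from ..errors import (
    EmptyPanelError,
    InputValidationError,
    RosterError,
    SchemaError,
)
from .models import (
    CohortDataset,
    Consequence,
    GenePanel,
    Group,
    IndividualRecord,
    VariantRecord,
)

logger = logging.getLogger(__name__)

MISSING_CELLS = {"", ".", "novel", "na", "nan"}

#: canonical display names for allele-frequency sources
_AF_SOURCE_NAMES = {"exac": "ExAC", "gnomad": "gnomAD", "in_house": "in_house", "inhouse": "in_house"}

_SCORE_COLUMNS = ("gerp", "cadd", "sift", "polyphen2", "mutationtaster")

MANDATORY_COLUMNS = ("chrom", "pos", "ref", "alt", "gene", "consequence")


def _is_missing(cell: Optional[str]) -> bool:
    return cell is None or cell.strip().lower() in MISSING_CELLS


@dataclass(frozen=True)
class AnnotatedVariant:
    """A variant record together with its carrier assignments."""

    record: VariantRecord
    carriers: Dict[str, int]  # individual_id -> dosage (1 het, 2 hom)


def _parse_carriers(cell: str, row_num: int) -> Dict[str, int]:
    carriers: Dict[str, int] = {}
    for token in cell.split(";"):
        token = token.strip()
        if not token:
            continue
        if token.endswith(":hom"):
            iid, dosage = token[: -len(":hom")], 2
        elif token.endswith(":het"):
            iid, dosage = token[: -len(":het")], 1
        else:
            iid, dosage = token, 1
        if not iid:
            raise InputValidationError(f"row {row_num}: empty carrier id in {cell!r}")
        carriers[iid] = dosage
    return carriers


def read_annotated_variants(path) -> List[AnnotatedVariant]:
    """Parse an annotated-variant TSV into records plus carrier maps."""
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as handle:
        reader = csv.DictReader(handle, delimiter="\t")
        if reader.fieldnames is None:
            raise SchemaError(f"{path}: file is empty (no header row)")
        header = [h.strip() for h in reader.fieldnames]
        for col in MANDATORY_COLUMNS:
            if col not in header:
                raise SchemaError(f"{path}: missing mandatory column {col!r}")
        af_columns = [h for h in header if h.lower().endswith("_af")]

        out: List[AnnotatedVariant] = []
        for row_num, row in enumerate(reader, start=2):
            try:
                pos = int(row["pos"])
            except (TypeError, ValueError):
                raise InputValidationError(
                    f"{path} row {row_num}: pos {row.get('pos')!r} is not an integer"
                ) from None
            try:
                consequence = Consequence.parse(row["consequence"])
            except ValueError as exc:
                raise InputValidationError(f"{path} row {row_num}: {exc}") from None

            external_afs: Dict[str, float] = {}
            for col in af_columns:
                cell = row.get(col)
                if _is_missing(cell):
                    continue
                try:
                    af = float(cell)
                except ValueError:
                    raise InputValidationError(
                        f"{path} row {row_num}: {col} value {cell!r} is not a number"
                    ) from None
                if not (0.0 <= af <= 1.0):
                    raise InputValidationError(
                        f"{path} row {row_num}: {col} value {af} outside [0,1]"
                    )
                base = col[: -len("_af")].lower()
                external_afs[_AF_SOURCE_NAMES.get(base, base)] = af

            scores: Dict[str, object] = {}
            for col in _SCORE_COLUMNS:
                cell = row.get(col)
                if _is_missing(cell):
                    continue
                if col in ("gerp", "cadd"):
                    scores[col] = float(cell)
                else:
                    scores[col] = cell.strip()

            record = VariantRecord(
                chrom=row["chrom"].strip(),
                pos=pos,
                ref=row["ref"].strip(),
                alt=row["alt"].strip(),
                gene_symbol=row["gene"].strip(),
                consequence=consequence,
                transcript=None if _is_missing(row.get("transcript")) else row["transcript"].strip(),
                hgvs_c=None if _is_missing(row.get("hgvs_c")) else row["hgvs_c"].strip(),
                hgvs_p=None if _is_missing(row.get("hgvs_p")) else row["hgvs_p"].strip(),
                external_afs=external_afs,
                scores=scores,
            )
            carriers_cell = row.get("carriers") or ""
            carriers = {} if _is_missing(carriers_cell) else _parse_carriers(carriers_cell, row_num)
            out.append(AnnotatedVariant(record=record, carriers=carriers))
    return out


def read_roster(path) -> List[IndividualRecord]:
    """Parse an individual roster TSV (individual_id, group[, sex, age])."""
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as handle:
        reader = csv.DictReader(handle, delimiter="\t")
        if reader.fieldnames is None or "individual_id" not in reader.fieldnames:
            raise SchemaError(f"{path}: missing mandatory column 'individual_id'")
        if "group" not in reader.fieldnames:
            raise SchemaError(f"{path}: missing mandatory column 'group'")
        out = []
        for row_num, row in enumerate(reader, start=2):
            try:
                group = Group(row["group"].strip().lower())
            except ValueError:
                raise InputValidationError(
                    f"{path} row {row_num}: group {row['group']!r} is not case/control"
                ) from None
            age_cell = row.get("age")
            out.append(
                IndividualRecord(
                    individual_id=row["individual_id"].strip(),
                    group=group,
                    sex=None if _is_missing(row.get("sex")) else row["sex"].strip(),
                    age=None if _is_missing(age_cell) else float(age_cell),
                )
            )
    return out


def build_cohort(
    individuals: Sequence[IndividualRecord],
    annotated: Sequence[AnnotatedVariant],
) -> CohortDataset:
    """Assemble a CohortDataset from a roster and annotated variants."""
    known_ids = {ind.individual_id for ind in individuals}
    dosages = np.zeros((len(individuals), len(annotated)), dtype=np.int8)
    index = {ind.individual_id: i for i, ind in enumerate(individuals)}
    for j, av in enumerate(annotated):
        for iid, dosage in av.carriers.items():
            if iid not in known_ids:
                raise RosterError(
                    f"carrier {iid!r} of variant {av.record.key} is not in the roster"
                )
            dosages[index[iid], j] = dosage
    return CohortDataset(individuals, [av.record for av in annotated], dosages)


def read_cohort_tsv(variants_path, roster_path) -> CohortDataset:
    """Read the (variant TSV, roster TSV) pair written by :mod:`writers`."""
    individuals = read_roster(roster_path)
    annotated = read_annotated_variants(variants_path)
    return build_cohort(individuals, annotated)


def read_gene_panel(path, name: Optional[str] = None) -> GenePanel:
    """Read a plain-text gene panel (one symbol per line, '#' comments)."""
    path = Path(path)
    symbols = []
    for line in path.read_text(encoding="utf-8").splitlines():
        line = line.split("#", 1)[0].strip()
        if line:
            symbols.append(line)
    if not symbols:
        raise EmptyPanelError(f"{path}: no gene symbols after removing comments")
    return GenePanel(name=name or path.stem, genes=symbols)


def read_vcf(path, annotations, individuals: Sequence[IndividualRecord]) -> CohortDataset:
    """Read genotypes from a VCF plus a sidecar annotation TSV.

    Multiallelic sites are split into one biallelic record per ALT allele.
    Missing genotypes count as dosage 0 (logged). Sites without a matching
    annotation row get consequence ``other`` and no external AFs.
    """
    from cyvcf2 import VCF  # deferred: htslib import is comparatively heavy

    annotation_map = {}
    for av in read_annotated_variants(annotations):
        annotation_map[av.record.key] = av.record

    roster_index = {ind.individual_id: i for i, ind in enumerate(individuals)}
    vcf = VCF(str(path))
    for sample in vcf.samples:
        if sample not in roster_index:
            raise RosterError(f"VCF sample {sample!r} is not in the individual roster")
    sample_rows = [roster_index[s] for s in vcf.samples]

    variants: List[VariantRecord] = []
    columns: List[np.ndarray] = []
    n_missing = 0
    for site in vcf:
        genotypes = site.genotype.array()  # (n_samples, ploidy+1); -1 = missing
        alleles = genotypes[:, :-1]
        n_missing += int((alleles < 0).sum())
        for alt_index, alt in enumerate(site.ALT, start=1):
            key = (site.CHROM, site.POS, site.REF, alt)
            record = annotation_map.get(key)
            if record is None:
                record = VariantRecord(
                    chrom=site.CHROM,
                    pos=site.POS,
                    ref=site.REF,
                    alt=alt,
                    gene_symbol=(site.INFO.get("GENE") or "unknown"),
                    consequence=Consequence.OTHER,
                )
            dosage_by_sample = (alleles == alt_index).sum(axis=1).astype(np.int8)
            column = np.zeros(len(individuals), dtype=np.int8)
            column[sample_rows] = np.minimum(dosage_by_sample, 2)
            variants.append(record)
            columns.append(column)
    if n_missing:
        logger.warning("read_vcf: %d missing genotype alleles treated as reference", n_missing)

    dosages = (
        np.stack(columns, axis=1)
        if columns
        else np.zeros((len(individuals), 0), dtype=np.int8)
    )
    return CohortDataset(individuals, variants, dosages)
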
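"""Writers for cohort, burden-scan and oligogenic result TSVs.

All output is pure data (no timestamps), tab-separated, UTF-8, with a
deterministic column and row order so that re-runs are byte-identical.
Allele frequencies are printed with 10 significant digits, which the
round-trip tests rely on.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Sequence

from .models import CohortDataset

_VARIANT_COLUMNS = [
    "chrom",
    "pos",
    "ref",
    "alt",
    "gene",
    "consequence",
    "transcript",
    "hgvs_c",
    "hgvs_p",
    "exac_af",
    "gnomad_af",
    "in_house_af",
    "gerp",
    "cadd",
    "sift",
    "polyphen2",
    "mutationtaster",
    "carriers",
]

_AF_COLUMN_SOURCE = {"exac_af": "ExAC", "gnomad_af": "gnomAD", "in_house_af": "in_house"}


def _fmt(value) -> str:
    if value is None:
        return "."
    if isinstance(value, float):
        return format(value, ".10g")
    return str(value)


def write_cohort_tsv(cohort: CohortDataset, variants_path, roster_path) -> None:
    """Write a cohort as an annotated-variant TSV plus a roster TSV."""
    variants_path, roster_path = Path(variants_path), Path(roster_path)
    with roster_path.open("w", newline="", encoding="utf-8") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(["individual_id", "group", "sex", "age"])
        for ind in cohort.individuals:
            writer.writerow([ind.individual_id, ind.group.value, _fmt(ind.sex), _fmt(ind.age)])

    with variants_path.open("w", newline="", encoding="utf-8") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(_VARIANT_COLUMNS)
        for j, variant in enumerate(cohort.variants):
            column = cohort.dosages[:, j]
            carriers = ";".join(
                ind.individual_id + (":hom" if column[i] == 2 else "")
                for i, ind in enumerate(cohort.individuals)
                if column[i] >= 1
            )
            afs = dict(variant.external_afs)
            row = [
                variant.chrom,
                variant.pos,
                variant.ref,
                variant.alt,
                variant.gene_symbol,
                variant.consequence.value,
                _fmt(variant.transcript),
                _fmt(variant.hgvs_c),
                _fmt(variant.hgvs_p),
                _fmt(afs.get("ExAC")),
                _fmt(afs.get("gnomAD")),
                _fmt(afs.get("in_house")),
                _fmt(variant.scores.get("gerp")),
                _fmt(variant.scores.get("cadd")),
                _fmt(variant.scores.get("sift")),
                _fmt(variant.scores.get("polyphen2")),
                _fmt(variant.scores.get("mutationtaster")),
                carriers or ".",
            ]
            writer.writerow(row)


def write_burden_table(results: Sequence, path, allow_empty: bool = False) -> None:
    """Write gene burden scan results (one row per gene, ranked)."""
    if not results and not allow_empty:
        raise ValueError("no burden results to write (pass allow_empty=True to override)")
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(
            [
                "gene",
                "case_n",
                "case_carriers",
                "control_n",
                "control_carriers",
                "chi2",
                "p_chi2",
                "p_fisher_one_sided",
                "p_fisher_two_sided",
                "rank",
            ]
        )
        for rank, res in enumerate(results, start=1):
            table = res.table
            writer.writerow(
                [
                    res.gene_symbol,
                    table.a + table.b,
                    table.a,
                    table.c + table.d,
                    table.c,
                    format(res.chi2_statistic, ".6e"),
                    format(res.p_chi2, ".6e"),
                    format(res.p_fisher_one_sided, ".6e"),
                    format(res.p_fisher_two_sided, ".6e"),
                    rank,
                ]
            )


def write_oligogenic_table(result, path) -> None:
    """Write an oligogenic enrichment summary plus per-individual rows."""
    path = Path(path)
    table = result.table
    with path.open("w", newline="", encoding="utf-8") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(
            [
                "min_genes",
                "case_multigene_carriers",
                "case_n",
                "case_percent",
                "control_multigene_carriers",
                "control_n",
                "chi2",
                "p_chi2",
                "p_fisher_one_sided",
                "p_fisher_two_sided",
            ]
        )
        writer.writerow(
            [
                result.min_genes,
                table.a,
                table.a + table.b,
                format(result.case_percent, ".1f"),
                table.c,
                table.c + table.d,
                format(result.chi2_statistic, ".6e"),
                format(result.p_chi2, ".6e"),
                format(result.p_fisher_one_sided, ".6e"),
                format(result.p_fisher_two_sided, ".6e"),
            ]
        )
        writer.writerow([])
        writer.writerow(["individual_id", "gene", "variant_type", "hgvs_c"])
        for row in result.combination_rows:
            writer.writerow(list(row))
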
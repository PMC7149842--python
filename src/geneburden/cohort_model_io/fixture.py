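"""Packaged reference cohort with known, externally published marginals.

The fixture encodes a 37-case / 534-control exome study whose per-gene
qualifying-carrier counts, per-patient variant combinations and known-gene
screen results are fixed by published summary tables, so every pipeline
stage has exact expected output:

* case carriers per gene: BAZ1B 3, FREM2 3, SUFU 2, VANGL1 2, KMT2D 3,
  MYO18B 3 (each case variant is a distinct heterozygous site);
* control carriers per gene: BAZ1B 1, FREM2 5, SUFU 2, VANGL1 4, KMT2D 11;
* exactly 7 cases and exactly 30 controls carry qualifying variants in
  >= 2 distinct candidate-panel genes.

Control carrier identities are not published; they are drawn
deterministically from the seed, which cannot affect any count-based
statistic. Every planted variant carries exactly one heterozygous carrier
(internal AF 1/1142 < 0.001) and a sub-0.001 external AF, so all planted
variants pass the default qualifying filter. A handful of distractor
variants are planted that each fail exactly one filter criterion.
"""

from __future__ import annotations

import re
from typing import Dict, List, Tuple

import numpy as np

from .models import (
    CohortDataset,
    Consequence,
    Group,
    IndividualRecord,
    VariantRecord,
)

# (patient, gene, consequence, chrom, pos, transcript, hgvs_c, hgvs_p, gerp, cadd, exac, gnomad, in_house)
_CASE_VARIANTS: List[tuple] = [
    # --- novel associated genes (per-patient variant table) ---
    ("CS63", "BAZ1B", "inframe_insertion", "7", 72861616, "NM_032408.3",
     "c.3804_3821dupGGAGGAGGAGGAAGAAGA", "p.Glu1268_Glu1273dup", None, None, 0.000016, None, None),
    ("CS216", "BAZ1B", "missense", "7", 72912871, "NM_032408.3",
     "c.527A>G", "p.Lys176Arg", 5.26, 17.03, 0.0000082, None, None),
    ("CS519", "BAZ1B", "missense", "7", 72892427, "NM_032408.3",
     "c.1364G>A", "p.Arg455Gln", 5.56, 11.17, 0.000016, None, None),
    ("CS193", "FREM2", "missense", "13", 39452441, "NM_207361.4",
     "c.8842T>C", "p.Tyr2948His", 0.57, 25.468, 0.000033, None, None),
    ("CS1049", "FREM2", "missense", "13", 39450454, "NM_207361.4",
     "c.8479C>T", "p.Arg2827Cys", 3.79, 18.07, 0.000016, None, None),
    ("OS1056", "FREM2", "missense", "13", 39424205, "NM_207361.4",
     "c.6410A>T", "p.Tyr2137Phe", 5.79, 17.11, 0.0000083, None, None),
    ("CS488", "KMT2D", "missense", "12", 49425124, "NM_003482.3",
     "c.13364G>A", "p.Arg4455His", 5.57, 13.45, 0.000058, None, None),
    ("CS1162", "KMT2D", "missense", "12", 49444297, "NM_003482.3",
     "c.3074C>T", "p.Ser1025Leu", 3.4, 6.896, 0.000059, None, None),
    ("CS1210", "KMT2D", "missense", "12", 49432200, "NM_003482.3",
     "c.8939C>T", "p.Ala2980Val", 2.77, 11.24, 0.000017, None, None),
    ("CS63", "SUFU", "missense", "10", 104375107, "NM_016169.3",
     "c.1105G>A", "p.Val369Ile", 5.21, 12.54, 0.000091, None, None),
    ("CS132", "SUFU", "splice_region", "10", 104375165, "NM_016169.3",
     "c.1157+6C>T", None, None, None, 0.000033, None, None),
    ("CS1130", "VANGL1", "synonymous", "1", 116206326, "NM_138959.2",
     "c.249G>A", "p.Ser83=", None, None, 0.00012, None, None),
    ("CS927", "VANGL1", "missense", "1", 116227985, "NM_138959.2",
     "c.1151C>G", "p.Pro384Arg", 5.44, 25.8, 0.0000083, None, None),
    # --- known-gene screen hits (all MYO18B, heterozygous) ---
    ("CS132", "MYO18B", "splice_region", "22", 26219648, "NM_032608.5",
     "c.2695+3A>G", None, None, None, 0.000017, None, 0.0029),
    ("CS1015", "MYO18B", "missense", "22", 26164545, "NM_032608.5",
     "c.662T>C", "p.Leu221Pro", None, None, 0.000034, 0.0000324, None),
    ("CS1049", "MYO18B", "missense", "22", 26299670, "NM_032608.5",
     "c.5020G>A", "p.Gly1674Arg", None, None, 0.000013, 0.00003232, None),
    # --- remaining multi-gene combination variants (positions synthesized) ---
    ("CS63", "GRIP1", "splice_acceptor", "12", 66741000, None,
     "c.1043-1G>A", None, None, None, 0.00001, None, None),
    ("CS63", "TBX6", "missense", "16", 30100500, None,
     "c.499C>T", "p.Arg167Cys", None, None, 0.000012, None, None),
    ("CS132", "WNT7A", "missense", "3", 13896100, None,
     "c.83C>T", "p.Ser28Leu", None, None, 0.000014, None, None),
    ("CS587", "FUZ", "missense", "19", 50310200, None,
     "c.819C>A", "p.Asp273Glu", None, None, 0.000016, None, None),
    ("CS587", "MAP3K7", "missense", "6", 91240300, None,
     "c.1115G>A", "p.Arg372His", None, None, 0.000018, None, None),
    ("CS587", "POR", "missense", "7", 75614400, None,
     "c.1798C>T", "p.Arg600Trp", None, None, 0.00002, None, None),
    ("CS676", "CHD7", "synonymous", "8", 61757500, None,
     "c.4008C>T", "p.Ile1336=", None, None, 0.000022, None, None),
    ("CS676", "FRAS1", "missense", "4", 79280600, None,
     "c.7423G>A", "p.Glu2475Lys", None, None, 0.000024, None, None),
    ("CS519", "COG1", "missense", "17", 71189700, None,
     "c.739C>T", "p.His247Tyr", None, None, 0.000026, None, None),
    ("CS1015", "ANKRD11", "missense", "16", 89350800, None,
     "c.6067G>T", "p.Ala2023Ser", None, None, 0.000028, None, None),
    ("CS1015", "HOXD13", "missense", "2", 176957900, None,
     "c.814G>A", "p.Val272Ile", None, None, 0.00003, None, None),
]

#: published control carrier counts for the five top-ranked genes
CONTROL_CARRIER_COUNTS: Dict[str, int] = {
    "BAZ1B": 1,
    "FREM2": 5,
    "SUFU": 2,
    "VANGL1": 4,
    "KMT2D": 11,
}

#: gene -> (chrom, base position) for synthesizing unique control variant sites
_GENE_LOCI: Dict[str, Tuple[str, int]] = {
    "BAZ1B": ("7", 72870000), "FREM2": ("13", 39430000), "SUFU": ("10", 104380000),
    "VANGL1": ("1", 116210000), "KMT2D": ("12", 49430000), "MYO18B": ("22", 26200000),
    "GRIP1": ("12", 66750000), "TBX6": ("16", 30101000), "WNT7A": ("3", 13897000),
    "FUZ": ("19", 50311000), "MAP3K7": ("6", 91241000), "POR": ("7", 75615000),
    "CHD7": ("8", 61758000), "FRAS1": ("4", 79281000), "COG1": ("17", 71190000),
    "ANKRD11": ("16", 89351000), "HOXD13": ("2", 176958000),
    "PAX1": ("20", 21686000), "PAX9": ("14", 37126000), "DLL3": ("19", 39989000),
}

#: per-gene slot counts for the 30 multi-gene controls (60 slots total).
#: Counts are tuned so every gene here keeps a burden-scan p-value above
#: the fifth-ranked published gene (3 case vs 14 control carriers -> p≈0.058;
#: 1 case vs >=4 controls -> p>0.2), preserving the published top-5 ordering.
_MULTIGENE_CONTROL_SLOTS: Dict[str, int] = {
    "MYO18B": 14,
    "GRIP1": 5, "TBX6": 5,
    "WNT7A": 4, "FUZ": 4, "MAP3K7": 4, "POR": 4, "CHD7": 4,
    "FRAS1": 4, "COG1": 4, "ANKRD11": 4, "HOXD13": 4,
}

_NAMED_CASES = [
    "CS63", "CS132", "CS193", "CS216", "CS488", "CS519", "CS587", "CS676",
    "CS927", "CS1015", "CS1049", "CS1130", "CS1162", "CS1210", "OS1056",
]

_CASE_DEMOGRAPHICS = {  # the few published sex/age annotations
    "CS63": ("F", 6.0), "CS132": ("F", 12.0), "CS1015": ("M", 5.0), "CS1049": ("F", 7.0),
}

_SUBSTITUTION = re.compile(r"(?:^|[^ACGT])([ACGT])>([ACGT])$")


def _alleles_from_hgvs(hgvs_c: str) -> Tuple[str, str]:
    """Derive simplified ref/alt alleles from a cDNA substitution or dup."""
    match = _SUBSTITUTION.search(hgvs_c)
    if match:
        return match.group(1), match.group(2)
    dup = re.search(r"dup([ACGT]+)$", hgvs_c)
    if dup:
        return "G", "G" + dup.group(1)
    return "N", "NA"  # fallback, never hit by the packaged table


def build_reference_cohort(seed: int = 0) -> CohortDataset:
    """Build the packaged 37-case / 534-control reference cohort.

    Pure function of ``seed``: equal seeds give identical datasets.
    """
    rng = np.random.default_rng(seed)

    case_ids = _NAMED_CASES + [f"CS9{i:03d}" for i in range(1, 23)]
    control_ids = [f"C{i:04d}" for i in range(1, 535)]
    individuals = [
        IndividualRecord(iid, Group.CASE,
                         sex=_CASE_DEMOGRAPHICS.get(iid, (None, None))[0],
                         age=_CASE_DEMOGRAPHICS.get(iid, (None, None))[1])
        for iid in case_ids
    ] + [IndividualRecord(iid, Group.CONTROL) for iid in control_ids]

    variants: List[VariantRecord] = []
    carriers: List[Dict[str, int]] = []

    for (patient, gene, consequence, chrom, pos, transcript,
         hgvs_c, hgvs_p, gerp, cadd, exac, gnomad, in_house) in _CASE_VARIANTS:
        ref, alt = _alleles_from_hgvs(hgvs_c)
        external_afs = {}
        if exac is not None:
            external_afs["ExAC"] = exac
        if gnomad is not None:
            external_afs["gnomAD"] = gnomad
        if in_house is not None:
            external_afs["in_house"] = in_house
        scores = {}
        if gerp is not None:
            scores["gerp"] = gerp
        if cadd is not None:
            scores["cadd"] = cadd
        variants.append(
            VariantRecord(
                chrom=chrom, pos=pos, ref=ref, alt=alt, gene_symbol=gene,
                consequence=Consequence(consequence), transcript=transcript,
                hgvs_c=hgvs_c, hgvs_p=hgvs_p, external_afs=external_afs, scores=scores,
            )
        )
        carriers.append({patient: 1})

    # -- seeded control carrier assignment ------------------------------------
    # 23 single-gene carriers for the published per-gene control counts,
    # 30 disjoint multi-gene carriers, then a few distractor carriers.
    shuffled = list(control_ids)
    rng.shuffle(shuffled)
    cursor = 0

    def take(n: int) -> List[str]:
        nonlocal cursor
        chunk = shuffled[cursor:cursor + n]
        cursor += n
        return chunk

    site_counter: Dict[str, int] = {}

    def plant(gene: str, individual_id: str, consequence=Consequence.MISSENSE,
              external_af=None, dosage: int = 1) -> None:
        chrom, base = _GENE_LOCI[gene]
        site_counter[gene] = site_counter.get(gene, 0) + 1
        af = float(rng.uniform(1e-6, 5e-5)) if external_af is None else external_af
        variants.append(
            VariantRecord(
                chrom=chrom, pos=base + site_counter[gene], ref="C", alt="T",
                gene_symbol=gene, consequence=consequence,
                external_afs={"ExAC": af} if af > 0 else {},
            )
        )
        carriers.append({individual_id: dosage})

    for gene, count in CONTROL_CARRIER_COUNTS.items():
        for iid in take(count):
            plant(gene, iid)

    # 30 multi-gene controls: each gets variants in exactly 2 distinct genes,
    # paired greedily from the per-gene slot budget (largest remainder first).
    remaining = dict(_MULTIGENE_CONTROL_SLOTS)
    multigene_controls = take(30)
    for iid in multigene_controls:
        first, second = sorted(remaining, key=lambda g: (-remaining[g], g))[:2]
        for gene in (first, second):
            plant(gene, iid)
            remaining[gene] -= 1
            if remaining[gene] == 0:
                del remaining[gene]
    assert not remaining, "multi-gene slot budget must divide into 30 pairs"

    # -- distractors: each fails exactly one filter criterion -----------------
    # internal MAF (3 carriers of one site -> 3/1142 > 0.001)
    internal_failers = take(3)
    chrom, base = _GENE_LOCI["PAX9"]
    site_counter["PAX9"] = site_counter.get("PAX9", 0) + 1
    variants.append(
        VariantRecord(chrom=chrom, pos=base + site_counter["PAX9"], ref="C", alt="T",
                      gene_symbol="PAX9", consequence=Consequence.MISSENSE,
                      external_afs={"ExAC": 0.00001}))
    carriers.append({iid: 1 for iid in internal_failers})
    # external MAF (common in the reference population)
    plant("PAX1", take(1)[0], external_af=0.05)
    # consequence class
    plant("DLL3", take(1)[0], consequence=Consequence.OTHER, external_af=0.00001)
    # panel membership (gene outside the candidate panel)
    off_panel = take(1)[0]
    variants.append(
        VariantRecord(chrom="21", pos=10000001, ref="C", alt="T",
                      gene_symbol="OFFPANEL1", consequence=Consequence.MISSENSE,
                      external_afs={"ExAC": 0.00001}))
    carriers.append({off_panel: 1})

    index = {ind.individual_id: i for i, ind in enumerate(individuals)}
    dosages = np.zeros((len(individuals), len(variants)), dtype=np.int8)
    for j, carrier_map in enumerate(carriers):
        for iid, dosage in carrier_map.items():
            dosages[index[iid], j] = dosage
    return CohortDataset(individuals, variants, dosages)
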
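"""Readers and writers for plink-style text PED/MAP, annotation TSV and GMT.

Only the white-space separated *text* dialects are supported (missing allele
``"0"``); binary BED/BIM/FAM and VCF are out of scope.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .model import (
    FUNC_CLASSES,
    MISSING,
    FormatError,
    GeneSet,
    GeneSetDB,
    SnpMeta,
    TrioStudy,
)

__all__ = [
    "read_ped_map",
    "write_ped_map",
    "read_annotation",
    "write_annotation",
    "read_gmt",
    "write_gmt",
]


def _read_map(map_path: Path) -> list[SnpMeta]:
    snps: list[SnpMeta] = []
    seen: set[str] = set()
    with open(map_path) as fh:
        for lineno, line in enumerate(fh, 1):
            fields = line.split()
            if not fields:
                continue
            if len(fields) != 4:
                raise FormatError(
                    f"{map_path}:{lineno}: expected 4 columns "
                    f"(chrom, snp_id, genetic distance, position), "
                    f"got {len(fields)}"
                )
            chrom, snp_id, gdist, pos = fields
            if snp_id in seen:
                raise FormatError(f"{map_path}:{lineno}: duplicate SNP id {snp_id!r}")
            seen.add(snp_id)
            snps.append(
                SnpMeta(
                    snp_id=snp_id,
                    chrom=chrom,
                    pos=int(pos),
                    gdist=float(gdist),
                    allele_a="A",
                    allele_b=None,
                )
            )
    return snps


def read_ped_map(ped_path: str | Path, map_path: str | Path) -> TrioStudy:
    """Read a plink text PED/MAP pair into a :class:`TrioStudy`.

    Each PED row carries 6 pedigree columns followed by two allele columns
    per MAP SNP; ``0`` marks a missing allele (a half-called genotype is
    treated as fully missing).  Alleles are arbitrary single characters;
    ``allele_a`` is the first allele observed at each SNP, ``allele_b`` the
    second.  Trios are derived from the pedigree (affected offspring with
    both parents present in the same family).
    """
    ped_path, map_path = Path(ped_path), Path(map_path)
    snps = _read_map(map_path)
    n_snps = len(snps)

    rows = []
    geno_rows = []
    # first/second allele observed per SNP
    allele_a: list[str | None] = [None] * n_snps
    allele_b: list[str | None] = [None] * n_snps

    with open(ped_path) as fh:
        for lineno, line in enumerate(fh, 1):
            fields = line.split()
            if not fields:
                continue
            if len(fields) != 6 + 2 * n_snps:
                raise FormatError(
                    f"{ped_path}:{lineno}: expected {6 + 2 * n_snps} columns "
                    f"(6 pedigree + 2 alleles x {n_snps} MAP SNPs), "
                    f"got {len(fields)}"
                )
            rows.append(fields[:6])
            geno_rows.append(fields[6:])

    codes = np.full((len(rows), n_snps), MISSING, dtype=np.int8)
    for i, alleles in enumerate(geno_rows):
        for j in range(n_snps):
            a1, a2 = alleles[2 * j], alleles[2 * j + 1]
            if a1 == "0" or a2 == "0":
                continue
            count = 0
            for a in (a1, a2):
                if allele_a[j] is None:
                    allele_a[j] = a
                if a != allele_a[j]:
                    if allele_b[j] is None:
                        allele_b[j] = a
                    elif a != allele_b[j]:
                        raise FormatError(
                            f"{ped_path}: SNP {snps[j].snp_id} has more than "
                            f"two alleles ({allele_a[j]}, {allele_b[j]}, {a})"
                        )
                    count += 1
            codes[i, j] = count

    for j, snp in enumerate(snps):
        snp.allele_a = allele_a[j] if allele_a[j] is not None else "A"
        snp.allele_b = allele_b[j]

    samples = pd.DataFrame(
        rows,
        columns=[
            "family_id",
            "individual_id",
            "father_id",
            "mother_id",
            "sex",
            "affection",
        ],
    )
    samples["sex"] = samples["sex"].astype(int)
    samples["affection"] = samples["affection"].astype(int)
    return TrioStudy(samples=samples, genotypes=codes, snps=snps)


def write_ped_map(
    study: TrioStudy, ped_path: str | Path, map_path: str | Path
) -> None:
    """Write a study back to plink text PED/MAP.

    Heterozygotes are written in canonical order (``allele_a`` first);
    missing genotypes as ``0 0``.
    """
    with open(map_path, "w") as fh:
        for s in study.snps:
            gd = int(s.gdist) if float(s.gdist).is_integer() else s.gdist
            fh.write(f"{s.chrom} {s.snp_id} {gd} {s.pos}\n")
    with open(ped_path, "w") as fh:
        for i, row in enumerate(study.samples.itertuples(index=False)):
            fields = [
                str(row.family_id),
                str(row.individual_id),
                str(row.father_id),
                str(row.mother_id),
                str(row.sex),
                str(row.affection),
            ]
            for j, snp in enumerate(study.snps):
                g = study.genotypes[i, j]
                b = snp.allele_b if snp.allele_b is not None else "0"
                if g == MISSING:
                    fields += ["0", "0"]
                elif g == 0:
                    fields += [snp.allele_a, snp.allele_a]
                elif g == 1:
                    fields += [snp.allele_a, b]
                else:
                    fields += [b, b]
            fh.write(" ".join(fields) + "\n")


def read_annotation(tsv_path: str | Path) -> dict[str, tuple[str | None, str]]:
    """Read the SNP annotation TSV into ``{snp_id: (gene, func_class)}``.

    Expected header columns: ``snp_id``, ``gene``, ``func_class``
    (func_class tokens case-insensitive, one of missense/splice/none; an
    empty or ``-`` gene means unmapped).  Duplicate ``snp_id`` rows with
    conflicting content are an error.
    """
    tsv_path = Path(tsv_path)
    mapping: dict[str, tuple[str | None, str]] = {}
    with open(tsv_path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        required = {"snp_id", "gene", "func_class"}
        if reader.fieldnames is None or not required.issubset(reader.fieldnames):
            raise FormatError(
                f"{tsv_path}: header must contain columns {sorted(required)}"
            )
        for lineno, row in enumerate(reader, 2):
            snp_id = row["snp_id"].strip()
            gene: str | None = row["gene"].strip()
            if gene in ("", "-", "none", "NA"):
                gene = None
            func = row["func_class"].strip().lower()
            if func not in FUNC_CLASSES:
                raise FormatError(
                    f"{tsv_path}:{lineno}: unknown func_class "
                    f"{row['func_class']!r}; accepted tokens: "
                    f"{', '.join(FUNC_CLASSES)}"
                )
            if snp_id in mapping and mapping[snp_id] != (gene, func):
                raise FormatError(
                    f"{tsv_path}:{lineno}: conflicting duplicate annotation "
                    f"for {snp_id!r}"
                )
            mapping[snp_id] = (gene, func)
    return mapping


def write_annotation(
    mapping: Mapping[str, tuple[str | None, str]], tsv_path: str | Path
) -> None:
    with open(tsv_path, "w") as fh:
        fh.write("snp_id\tgene\tfunc_class\n")
        for snp_id, (gene, func) in mapping.items():
            fh.write(f"{snp_id}\t{gene if gene is not None else '-'}\t{func}\n")


def read_gmt(gmt_path: str | Path) -> GeneSetDB:
    """Read gene sets from a GMT file (set_id TAB description TAB genes...).

    Genes within a set are de-duplicated preserving order; a repeated
    ``set_id`` is an error.
    """
    gmt_path = Path(gmt_path)
    sets: dict[str, GeneSet] = {}
    with open(gmt_path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{gmt_path}:{lineno}: expected at least 3 tab-separated "
                    f"fields (set_id, description, genes...), got {len(fields)}"
                )
            set_id, description = fields[0], fields[1]
            if set_id in sets:
                raise FormatError(
                    f"{gmt_path}:{lineno}: duplicate set id {set_id!r}"
                )
            genes: list[str] = []
            for g in fields[2:]:
                g = g.strip()
                if g and g not in genes:
                    genes.append(g)
            sets[set_id] = GeneSet(set_id, description, tuple(genes))
    return GeneSetDB(sets=sets)


def write_gmt(db: GeneSetDB, gmt_path: str | Path) -> None:
    with open(gmt_path, "w") as fh:
        for gs in db:
            fh.write("\t".join([gs.set_id, gs.description, *gs.genes]) + "\n")
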
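"""Core data model for trio GWAS studies.

A :class:`TrioStudy` holds a pedigree sample table, a numerically coded
genotype matrix and per-SNP metadata.  Genotypes are stored as counts of
``allele_b`` (0, 1 or 2), with ``-1`` for missing; which of the two alleles
is "minor" is decided later from founder allele frequencies, never from
file order.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

#: Functional annotation classes used for permutation matching.
FUNC_CLASSES = ("missense", "splice", "none")

#: Missing-genotype code in :attr:`TrioStudy.genotypes`.
MISSING = -1

SAMPLE_COLUMNS = [
    "family_id",
    "individual_id",
    "father_id",
    "mother_id",
    "sex",
    "affection",
]


@dataclass
class SnpMeta:
    """Identity, position, alleles and annotation of one SNP.

    ``allele_b`` is the allele counted by the genotype code; it may be
    ``None`` for a monomorphic SNP where only one allele was ever observed.
    ``func_class`` is one of :data:`FUNC_CLASSES`.
    """

    snp_id: str
    chrom: str = "1"
    pos: int = 1
    allele_a: str = "A"
    allele_b: str | None = "B"
    gdist: float = 0.0
    gene: str | None = None
    func_class: str = "none"

    def __post_init__(self) -> None:
        if self.allele_b is not None and self.allele_a == self.allele_b:
            raise ValueError(
                f"SNP {self.snp_id}: allele_a and allele_b must differ"
            )
        if self.func_class not in FUNC_CLASSES:
            raise ValueError(
                f"SNP {self.snp_id}: func_class {self.func_class!r} not in "
                f"{FUNC_CLASSES}"
            )


@dataclass
class GeneSet:
    set_id: str
    description: str
    genes: tuple[str, ...]


@dataclass
class GeneSetDB:
    """A collection of flat gene sets (e.g. GO terms read from a GMT file)."""

    sets: dict[str, GeneSet]
    universe: list[str] | None = None

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, set_id: str) -> GeneSet:
        return self.sets[set_id]

    def __iter__(self):
        return iter(self.sets.values())


class FormatError(ValueError):
    """Malformed input file (PED/MAP/TSV/GMT)."""


def derive_trios(samples: pd.DataFrame) -> np.ndarray:
    """Return (n_trios, 3) row indices (father, mother, offspring).

    A trio is an *affected* offspring whose ``father_id`` and ``mother_id``
    both resolve to individuals of the same family.  Offspring with one or
    both parents absent are kept in the study but form no trio.  Siblings
    each form their own trio.
    """
    index: dict[tuple[str, str], int] = {}
    for i, (fam, iid) in enumerate(
        zip(samples["family_id"], samples["individual_id"])
    ):
        key = (str(fam), str(iid))
        if key in index:
            raise FormatError(
                f"duplicate individual ID {iid!r} in family {fam!r}"
            )
        index[key] = i
    trios = []
    for i, row in enumerate(samples.itertuples(index=False)):
        if int(row.affection) != 2:
            continue
        fkey = (str(row.family_id), str(row.father_id))
        mkey = (str(row.family_id), str(row.mother_id))
        if str(row.father_id) in ("0", "") or str(row.mother_id) in ("0", ""):
            continue
        if fkey in index and mkey in index:
            trios.append((index[fkey], index[mkey], i))
    if not trios:
        return np.empty((0, 3), dtype=np.intp)
    return np.asarray(trios, dtype=np.intp)


@dataclass
class TrioStudy:
    """Genotyped sample with derived affected-offspring trios.

    Attributes
    ----------
    samples
        One row per individual with columns :data:`SAMPLE_COLUMNS`.
        ``affection`` uses PED coding: 1 unaffected, 2 affected, 0/-9 missing.
    genotypes
        ``(n_individuals, n_snps)`` int8 array of ``allele_b`` counts,
        :data:`MISSING` where no call.
    snps
        Ordered SNP metadata matching the genotype columns.
    trios
        ``(n_trios, 3)`` array of (father, mother, offspring) row indices,
        derived from the pedigree.
    """

    samples: pd.DataFrame
    genotypes: np.ndarray
    snps: list[SnpMeta]
    trios: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.samples = self.samples.reset_index(drop=True)
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        if self.genotypes.shape != (len(self.samples), len(self.snps)):
            raise ValueError(
                f"genotype matrix shape {self.genotypes.shape} does not match "
                f"({len(self.samples)} individuals, {len(self.snps)} SNPs)"
            )
        if self.trios is None:
            self.trios = derive_trios(self.samples)

    # -- basic geometry -------------------------------------------------
    @property
    def n_individuals(self) -> int:
        return len(self.samples)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    @property
    def n_trios(self) -> int:
        return len(self.trios)

    @property
    def snp_ids(self) -> list[str]:
        return [s.snp_id for s in self.snps]

    # -- pedigree helpers -----------------------------------------------
    def founder_mask(self) -> np.ndarray:
        """Boolean mask of founders: individuals with no parent present."""
        present = {
            (str(f), str(i))
            for f, i in zip(
                self.samples["family_id"], self.samples["individual_id"]
            )
        }
        mask = np.ones(self.n_individuals, dtype=bool)
        for i, row in enumerate(self.samples.itertuples(index=False)):
            fam = str(row.family_id)
            if (fam, str(row.father_id)) in present or (
                fam,
                str(row.mother_id),
            ) in present:
                mask[i] = False
        return mask

    # -- subsetting ------------------------------------------------------
    def select_snps(self, which: Iterable[int] | np.ndarray) -> "TrioStudy":
        """New study restricted to the given SNP column indices (order kept)."""
        idx = np.asarray(list(which), dtype=np.intp)
        return TrioStudy(
            samples=self.samples.copy(),
            genotypes=self.genotypes[:, idx].copy(),
            snps=[replace(self.snps[i]) for i in idx],
            trios=self.trios.copy(),
        )

    def annotate(self, mapping: Mapping[str, tuple[str | None, str]]) -> None:
        """Attach gene / functional class from an annotation map in place.

        SNPs absent from the map get ``gene=None, func_class='none'``.
        """
        for snp in self.snps:
            gene, func = mapping.get(snp.snp_id, (None, "none"))
            snp.gene = gene
            snp.func_class = func

    def snp_table(self) -> pd.DataFrame:
        """Per-SNP metadata as a DataFrame (snp_id, chrom, pos, gene, func_class)."""
        return pd.DataFrame(
            {
                "snp_id": [s.snp_id for s in self.snps],
                "chrom": [s.chrom for s in self.snps],
                "pos": [s.pos for s in self.snps],
                "gene": [s.gene for s in self.snps],
                "func_class": [s.func_class for s in self.snps],
            }
        )
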
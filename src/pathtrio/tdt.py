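"""Transmission Disequilibrium Test over affected-offspring trios.

For each SNP, every heterozygous parent of an affected offspring
contributes one transmission observation of the minor allele: transmitted
(T) or untransmitted (U).  Under no association T and U are exchangeable
and (T-U)^2/(T+U) is chi-square with 1 df (McNemar form).  Homozygous
parents are uninformative; trios with a missing or Mendelian-inconsistent
genotype at a SNP are skipped at that SNP.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2 as chi2_dist

from .model import MISSING, TrioStudy
from .qc import allele_frequencies

AllelePair = tuple[str, str] | None


@dataclass
class TdtResult:
    """Per-SNP TDT summary for the minor allele.

    ``or_value`` = T/U: > 1 means the minor allele is over-transmitted
    (risk direction); ``inf`` when U = 0 < T and ``nan`` when T = U = 0.
    ``n_informative`` counts heterozygous-parent transmissions (T + U).
    """

    snp_id: str
    t_count: int
    u_count: int
    chi2: float
    p: float
    or_value: float
    n_informative: int


def _from_counts(snp_id: str, t: int, u: int) -> TdtResult:
    n = t + u
    if n == 0:
        return TdtResult(snp_id, 0, 0, 0.0, 1.0, math.nan, 0)
    chi2 = (t - u) ** 2 / n
    p = float(chi2_dist.sf(chi2, df=1))
    if u == 0:
        orv = math.inf
    else:
        orv = t / u
    return TdtResult(snp_id, int(t), int(u), float(chi2), p, orv, int(n))


def tdt_single(
    trio_genotypes: Sequence[tuple[AllelePair, AllelePair, AllelePair]],
    minor_allele: str,
    snp_id: str = "snp",
) -> TdtResult:
    """TDT at one SNP from explicit (father, mother, offspring) allele pairs.

    Each genotype is an unordered pair of allele characters or ``None`` for
    missing.  Trios with any missing member, or that are Mendelian
    inconsistent, are skipped.
    """
    alleles: set[str] = set()
    for trio in trio_genotypes:
        for g in trio:
            if g is not None:
                alleles.update(g)
    if trio_genotypes and alleles and minor_allele not in alleles:
        raise ValueError(
            f"minor allele {minor_allele!r} not among observed alleles "
            f"{sorted(alleles)}"
        )
    t = u = 0
    for father, mother, child in trio_genotypes:
        if father is None or mother is None or child is None:
            continue
        gf = sum(a == minor_allele for a in father)
        gm = sum(a == minor_allele for a in mother)
        go = sum(a == minor_allele for a in child)
        k_het = (gf == 1) + (gm == 1)
        t_het = go - (gf == 2) - (gm == 2)
        if t_het < 0 or t_het > k_het:  # Mendelian inconsistency
            continue
        t += t_het
        u += k_het - t_het
    return _from_counts(snp_id, t, u)


def transmission_counts(study: TrioStudy) -> pd.DataFrame:
    """Vectorised minor-allele T/U counts for every SNP of a study.

    Returns a frame with snp_id, minor_allele, t, u.  The minor allele is
    determined from founder allele frequencies (ties go to ``allele_b``).
    """
    if study.n_trios == 0:
        raise ValueError("study has no complete affected-offspring trios")
    G = study.genotypes
    f = G[study.trios[:, 0]].astype(np.int16)
    m = G[study.trios[:, 1]].astype(np.int16)
    o = G[study.trios[:, 2]].astype(np.int16)
    complete = (f != MISSING) & (m != MISSING) & (o != MISSING)
    k_het = (f == 1).astype(np.int16) + (m == 1)
    t_het = o - (f == 2) - (m == 2)
    ok = complete & (t_het >= 0) & (t_het <= k_het)
    t_b = np.where(ok, t_het, 0).sum(axis=0)
    u_b = np.where(ok, k_het - t_het, 0).sum(axis=0)

    freqs = allele_frequencies(study, founders_only=True)
    b_is_minor = freqs["freq_b"].to_numpy() <= 0.5
    t = np.where(b_is_minor, t_b, u_b)
    u = np.where(b_is_minor, u_b, t_b)
    return pd.DataFrame(
        {
            "snp_id": study.snp_ids,
            "minor_allele": freqs["minor_allele"],
            "t": t,
            "u": u,
        }
    )


def tdt_scan(study: TrioStudy) -> list[TdtResult]:
    """Run the TDT at every SNP; one result per SNP in study order."""
    counts = transmission_counts(study)
    return [
        _from_counts(s, int(t), int(u))
        for s, t, u in zip(counts["snp_id"], counts["t"], counts["u"])
    ]


def tdt_frame(study: TrioStudy, results: list[TdtResult]) -> pd.DataFrame:
    """Join TDT results with SNP metadata into the results table.

    Columns: snp_id, chrom, pos, gene, func_class, t, u, or_value, chi2, p,
    n_informative — the layout written to the results TSV.
    """
    meta = study.snp_table()
    res = pd.DataFrame(
        {
            "snp_id": [r.snp_id for r in results],
            "t": [r.t_count for r in results],
            "u": [r.u_count for r in results],
            "or_value": [r.or_value for r in results],
            "chi2": [r.chi2 for r in results],
            "p": [r.p for r in results],
            "n_informative": [r.n_informative for r in results],
        }
    )
    return meta.merge(res, on="snp_id", how="right")
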
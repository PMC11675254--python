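"""Pre-analysis SNP quality control.

Filters are applied in a fixed order: genotype call rate, minor allele
frequency (founders), Hardy-Weinberg exact test (founders), then VIF-based
LD pruning in a sliding window (plink's ``indep`` style).  Trio genotypes
that are Mendelian-inconsistent at a SNP are masked to missing before any
filter, preserving the rest of the trio's information.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .model import MISSING, TrioStudy


@dataclass
class QcConfig:
    """Thresholds for SNP-level QC.

    Defaults follow standard GWAS practice for trio data: MAF >= 0.05,
    per-SNP call rate >= 0.95, Hardy-Weinberg exact p >= 1e-5 in founders,
    and ``indep 50 5 2`` pruning (window 50 SNPs, step 5, VIF threshold 2,
    VIF = 1/(1-R^2) against the other SNPs in the window).
    """

    maf_min: float = 0.05
    geno_min: float = 0.95
    hwe_p_min: float = 1e-5
    vif_window: int = 50
    vif_step: int = 5
    vif_threshold: float = 2.0

    def __post_init__(self) -> None:
        if not 0 <= self.maf_min <= 0.5:
            raise ValueError("maf_min must be in [0, 0.5]")
        if not 0 < self.geno_min <= 1:
            raise ValueError("geno_min must be in (0, 1]")
        if self.vif_threshold < 1:
            raise ValueError("vif_threshold must be >= 1")


# ---------------------------------------------------------------------------
# allele frequencies


def allele_frequencies(
    study: TrioStudy, founders_only: bool = True
) -> pd.DataFrame:
    """Per-SNP minor allele, MAF and call rate.

    With ``founders_only`` the tallies run over founders (no parent in the
    dataset); otherwise over all individuals.  A SNP with every genotype
    missing gets ``maf = NaN`` and is flagged for removal downstream.
    On a 0.5/0.5 tie the ``allele_b`` of the SNP is reported as minor.
    """
    if study.n_snps == 0 or study.n_individuals == 0:
        raise ValueError("empty study")
    G = study.genotypes
    if founders_only:
        G = G[study.founder_mask()]
    observed = G != MISSING
    n_obs = observed.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        freq_b = np.where(observed, G, 0).sum(axis=0) / (2.0 * n_obs)
    call_rate = n_obs / max(G.shape[0], 1)
    maf = np.minimum(freq_b, 1.0 - freq_b)
    minor = [
        (s.allele_b if fb <= 0.5 else s.allele_a) if n > 0 else None
        for s, fb, n in zip(study.snps, freq_b, n_obs)
    ]
    return pd.DataFrame(
        {
            "snp_id": study.snp_ids,
            "minor_allele": minor,
            "maf": maf,
            "call_rate": call_rate,
            "freq_b": freq_b,
        }
    )


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test


def hwe_exact_p(n_aa: int, n_ab: int, n_bb: int) -> float:
    """Exact Hardy-Weinberg test p-value from genotype counts.

    Conditions on the allele counts and sums the probabilities of all
    heterozygote counts that are no more probable than the observed one
    (two-sided "no more probable" definition).  Returns 1.0 for a
    monomorphic sample.
    """
    if min(n_aa, n_ab, n_bb) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_aa + n_ab + n_bb
    if n == 0:
        raise ValueError("at least one genotype count must be positive")
    n_a = 2 * n_aa + n_ab
    n_b = 2 * n_bb + n_ab
    if n_a == 0 or n_b == 0:
        return 1.0
    rare = min(n_a, n_b)
    # possible heterozygote counts share the parity of the rare allele count
    hets = np.arange(rare % 2, rare + 1, 2)
    hom_rare = (rare - hets) // 2
    hom_common = n - hets - hom_rare
    logp = (
        hets * np.log(2.0)
        + gammaln(n + 1)
        - gammaln(hom_rare + 1)
        - gammaln(hets + 1)
        - gammaln(hom_common + 1)
        + gammaln(n_a + 1)
        + gammaln(n_b + 1)
        - gammaln(2 * n + 1)
    )
    probs = np.exp(logp - logp.max())
    probs /= probs.sum()
    p_obs = probs[hets == n_ab][0]
    return float(min(1.0, probs[probs <= p_obs * (1 + 1e-12)].sum()))


# ---------------------------------------------------------------------------
# Mendelian masking


def mask_mendelian_errors(study: TrioStudy) -> tuple[TrioStudy, int]:
    """Mask trio genotypes that are Mendelian-inconsistent at a SNP.

    All three members of an offending trio are set missing at that SNP
    (genotype-level masking; the trio keeps contributing at other SNPs).
    Returns the masked study (a copy) and the number of trio x SNP cells
    masked.
    """
    G = study.genotypes.copy()
    if study.n_trios == 0:
        return (
            TrioStudy(study.samples.copy(), G, [s for s in study.snps],
                      study.trios.copy()),
            0,
        )
    f = G[study.trios[:, 0]]
    m = G[study.trios[:, 1]]
    o = G[study.trios[:, 2]]
    complete = (f != MISSING) & (m != MISSING) & (o != MISSING)
    k_het = (f == 1).astype(np.int16) + (m == 1)
    t_het = o.astype(np.int16) - (f == 2) - (m == 2)
    bad = complete & ((t_het < 0) | (t_het > k_het))
    n_bad = int(bad.sum())
    if n_bad:
        trio_rows, snp_cols = np.nonzero(bad)
        for col in range(3):
            G[study.trios[trio_rows, col], snp_cols] = MISSING
    from dataclasses import replace as _replace

    masked = TrioStudy(
        samples=study.samples.copy(),
        genotypes=G,
        snps=[_replace(s) for s in study.snps],
        trios=study.trios.copy(),
    )
    return masked, n_bad


# ---------------------------------------------------------------------------
# VIF pruning


def _pairwise_corr(X: np.ndarray) -> np.ndarray:
    """Correlation matrix with pairwise-complete deletion (NaN = missing)."""
    M = np.isfinite(X).astype(float)
    X0 = np.where(np.isfinite(X), X, 0.0)
    n = M.T @ M
    s1 = X0.T @ M  # s1[j, k] = sum of x_j over rows complete in (j, k)
    s2 = (X0**2).T @ M
    prod = X0.T @ X0
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = s1 / n
        cov = prod / n - mean * mean.T
        var = s2 / n - mean**2
        denom = np.sqrt(var * var.T)
        corr = cov / denom
    corr[~np.isfinite(corr)] = 0.0
    np.clip(corr, -1.0, 1.0, out=corr)
    np.fill_diagonal(corr, 1.0)
    return corr


def _window_vifs(corr: np.ndarray) -> np.ndarray:
    """VIF_i = 1/(1 - R^2_i) of each SNP regressed on the rest of the window."""
    k = corr.shape[0]
    try:
        inv = np.linalg.inv(corr)
        diag = np.diag(inv)
        if np.all(diag >= 1.0 - 1e-8):
            return np.maximum(diag, 1.0)
    except np.linalg.LinAlgError:
        pass
    # singular / indefinite pairwise-complete matrix: per-SNP fallback
    vifs = np.empty(k)
    for i in range(k):
        others = np.delete(np.arange(k), i)
        r = corr[np.ix_(others, [i])].ravel()
        sub = corr[np.ix_(others, others)]
        beta = np.linalg.pinv(sub) @ r
        r2 = float(np.clip(r @ beta, 0.0, 1.0))
        vifs[i] = np.inf if r2 >= 1.0 - 1e-8 else 1.0 / (1.0 - r2)
    return vifs


def vif_prune(study: TrioStudy, cfg: QcConfig) -> list[str]:
    """LD-prune SNPs by sliding-window VIF; returns kept snp_ids.

    Windows of ``vif_window`` SNPs advance by ``vif_step`` along each
    chromosome separately, over the SNPs still kept.  Within a window the
    SNP with the largest VIF is removed (ties: lowest index first) until
    all VIFs are <= ``vif_threshold``; removals are permanent.  Windows
    with fewer than two polymorphic SNPs pass unchanged.  Correlations are
    computed over founders with pairwise-complete deletion.
    """
    G = study.genotypes[study.founder_mask()].astype(float)
    G[G == MISSING] = np.nan
    removed: set[int] = set()
    # polymorphic = has at least two distinct observed genotype codes
    poly = np.zeros(study.n_snps, dtype=bool)
    for j in range(study.n_snps):
        col = G[:, j]
        obs = col[np.isfinite(col)]
        poly[j] = obs.size >= 2 and np.nanstd(obs) > 0

    chroms: dict[str, list[int]] = {}
    for j, s in enumerate(study.snps):
        chroms.setdefault(s.chrom, []).append(j)

    for chrom_idx in chroms.values():
        start = 0
        while True:
            current = [j for j in chrom_idx if j not in removed]
            if start >= len(current):
                break
            window = current[start : start + cfg.vif_window]
            cand = [j for j in window if poly[j]]
            while len(cand) >= 2:
                corr = _pairwise_corr(G[:, cand])
                vifs = _window_vifs(corr)
                worst = int(np.argmax(vifs))
                if vifs[worst] <= cfg.vif_threshold:
                    break
                removed.add(cand[worst])
                cand.pop(worst)
            if start + cfg.vif_window >= len(current):
                break
            start += cfg.vif_step
    return [s.snp_id for j, s in enumerate(study.snps) if j not in removed]


# ---------------------------------------------------------------------------
# pipeline


def apply_qc(study: TrioStudy, cfg: QcConfig) -> tuple[TrioStudy, pd.DataFrame]:
    """Run the full SNP QC and return (filtered study, report).

    Order: Mendelian masking, then call rate -> MAF -> HWE (founders) ->
    VIF pruning.  The report lists the number of SNPs removed by each
    filter and the running remainder.
    """
    study, n_mendel = mask_mendelian_errors(study)
    report_rows = [("mendelian_masked_genotypes", n_mendel, study.n_snps)]

    freqs_all = allele_frequencies(study, founders_only=False)
    keep = freqs_all["call_rate"].to_numpy() >= cfg.geno_min
    report_rows.append(("call_rate", int((~keep).sum()), int(keep.sum())))
    study = study.select_snps(np.nonzero(keep)[0])
    if study.n_snps == 0:
        raise ValueError("all SNPs removed by QC (call-rate filter)")

    freqs = allele_frequencies(study, founders_only=True)
    maf = freqs["maf"].to_numpy()
    keep = np.isfinite(maf) & (maf >= cfg.maf_min)
    report_rows.append(("maf", int((~keep).sum()), int(keep.sum())))
    study = study.select_snps(np.nonzero(keep)[0])
    if study.n_snps == 0:
        raise ValueError("all SNPs removed by QC (MAF filter)")

    founders = study.genotypes[study.founder_mask()]
    hwe_p = np.empty(study.n_snps)
    for j in range(study.n_snps):
        col = founders[:, j]
        col = col[col != MISSING]
        hwe_p[j] = hwe_exact_p(
            int((col == 0).sum()), int((col == 1).sum()), int((col == 2).sum())
        )
    keep = hwe_p >= cfg.hwe_p_min
    report_rows.append(("hwe", int((~keep).sum()), int(keep.sum())))
    study = study.select_snps(np.nonzero(keep)[0])
    if study.n_snps == 0:
        raise ValueError("all SNPs removed by QC (HWE filter)")

    kept_ids = set(vif_prune(study, cfg))
    keep = np.array([s.snp_id in kept_ids for s in study.snps])
    report_rows.append(("vif_prune", int((~keep).sum()), int(keep.sum())))
    study = study.select_snps(np.nonzero(keep)[0])
    if study.n_snps == 0:
        raise ValueError("all SNPs removed by QC (VIF pruning)")

    report = pd.DataFrame(
        report_rows, columns=["filter", "snps_removed", "snps_remaining"]
    )
    return study, report
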
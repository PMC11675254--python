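"""Allele frequencies, Hardy-Weinberg exact test, Mendelian masking and
VIF pruning."""

import math
from fractions import Fraction

import numpy as np
import pytest

from pathtrio.model import MISSING
from pathtrio.qc import (
    QcConfig,
    allele_frequencies,
    apply_qc,
    hwe_exact_p,
    mask_mendelian_errors,
    vif_prune,
)
from pathtrio.simulate import SimConfig, simulate_study

from conftest import fill_children, make_study


# -- allele frequencies --------------------------------------------------


def test_founder_frequencies_direct_count():
    # founders AA and AB at one SNP: freq(B) = 1/4
    study = make_study([[0], [1], [1]])
    f = allele_frequencies(study, founders_only=True)
    assert f.loc[0, "maf"] == pytest.approx(0.25)
    assert f.loc[0, "minor_allele"] == "B"


def test_all_heterozygous_gives_maf_half_tie_to_allele_b():
    study = make_study([[1], [1], [1]])
    f = allele_frequencies(study, founders_only=True)
    assert f.loc[0, "maf"] == pytest.approx(0.5)
    assert f.loc[0, "minor_allele"] == "B"


def test_frequencies_match_brute_force_tally():
    sim = simulate_study(
        SimConfig(n_trios=50, n_snps=40, n_genes=8, n_sets=2,
                  missing_rate=0.1, seed=11)
    )
    study = sim.study
    f = allele_frequencies(study, founders_only=True)
    founders = study.genotypes[study.founder_mask()]
    for j in range(study.n_snps):
        col = founders[:, j]
        col = col[col != MISSING]
        nb = int(col.sum())
        n = 2 * len(col)
        expect = min(nb / n, 1 - nb / n)
        assert f.loc[j, "maf"] == pytest.approx(expect, abs=1e-12)


def test_all_missing_snp_flagged():
    study = make_study([[0, MISSING], [1, MISSING], [1, MISSING]])
    f = allele_frequencies(study, founders_only=True)
    assert math.isnan(f.loc[1, "maf"])
    assert f.loc[1, "call_rate"] == 0


# -- HWE exact test ------------------------------------------------------


def hwe_oracle(n_aa, n_ab, n_bb):
    """Exact-rational enumeration of the conditional het distribution."""
    n = n_aa + n_ab + n_bb
    na = 2 * n_aa + n_ab
    nb = 2 * n_bb + n_ab
    if na == 0 or nb == 0:
        return 1.0
    rare = min(na, nb)

    def prob(het):
        hom_r = (rare - het) // 2
        hom_c = n - het - hom_r
        ways = (
            Fraction(math.factorial(n))
            / math.factorial(hom_r)
            / math.factorial(het)
            / math.factorial(hom_c)
            * 2**het
        )
        total = Fraction(math.factorial(2 * n)) / (
            math.factorial(na) * math.factorial(nb)
        )
        return ways / total

    probs = {h: prob(h) for h in range(rare % 2, rare + 1, 2)}
    p_obs = probs[n_ab]
    return float(sum(p for p in probs.values() if p <= p_obs))


@pytest.mark.parametrize(
    "counts",
    [(57, 14, 50), (5, 10, 5), (0, 3, 100), (68, 28, 4), (1, 1, 1),
     (100, 5, 95), (40, 100, 60)],
)
def test_hwe_matches_enumeration_oracle(counts):
    assert hwe_exact_p(*counts) == pytest.approx(
        hwe_oracle(*counts), rel=1e-12
    )


def test_hwe_random_counts_match_oracle_up_to_200_founders():
    rng = np.random.default_rng(0)
    for _ in range(25):
        n = int(rng.integers(2, 201))
        maf = rng.uniform(0.05, 0.5)
        g = rng.binomial(2, maf, n)
        counts = (int((g == 0).sum()), int((g == 1).sum()), int((g == 2).sum()))
        assert hwe_exact_p(*counts) == pytest.approx(
            hwe_oracle(*counts), rel=1e-12
        )


def test_hwe_monomorphic_and_symmetry_and_errors():
    assert hwe_exact_p(10, 0, 0) == 1.0
    assert hwe_exact_p(57, 14, 50) == pytest.approx(
        hwe_exact_p(50, 14, 57), rel=1e-12
    )
    with pytest.raises(ValueError):
        hwe_exact_p(0, 0, 0)


# -- Mendelian masking ---------------------------------------------------


def test_mendelian_inconsistency_masks_whole_trio_at_snp():
    # parents AA x AA cannot produce an AB child at SNP 1
    study = make_study([[0, 0], [0, 0], [1, 0]])
    masked, n_bad = mask_mendelian_errors(study)
    assert n_bad == 1
    assert (masked.genotypes[:, 0] == MISSING).all()
    assert (masked.genotypes[:, 1] != MISSING).all()


# -- VIF pruning ---------------------------------------------------------


def test_identical_columns_prunes_exactly_one():
    rng = np.random.default_rng(2)
    n = 60
    col = rng.binomial(2, 0.3, n)
    other = rng.binomial(2, 0.3, n)
    G = np.column_stack([col, col, other])
    # make rows multiples of 3 (all founders by pedigree construction)
    study = make_study(G)
    kept = vif_prune(study, QcConfig())
    assert len(kept) == 2
    assert "rs3" in kept


def test_independent_snps_rarely_pruned():
    sim = simulate_study(
        SimConfig(n_trios=250, n_snps=200, n_genes=20, n_sets=2,
                  missing_rate=0.0, tau=0.5, seed=5)
    )
    kept = vif_prune(sim.study, QcConfig())
    assert len(kept) >= 0.95 * sim.study.n_snps


def test_vif_matches_least_squares_oracle():
    """VIF of a noisy copy equals 1/(1-R^2) from an explicit regression."""
    rng = np.random.default_rng(9)
    n = 300
    s1 = rng.binomial(2, 0.4, n).astype(float)
    s2 = rng.binomial(2, 0.3, n).astype(float)
    s3 = np.clip(np.round(s1 + rng.normal(0, 0.6, n)), 0, 2)
    X = np.column_stack([s1, s2, s3])
    # oracle: R^2 of s3 on s1, s2 with intercept
    A = np.column_stack([np.ones(n), s1, s2])
    beta, *_ = np.linalg.lstsq(A, s3, rcond=None)
    resid = s3 - A @ beta
    r2 = 1 - resid.var() / s3.var()
    vif_oracle = 1 / (1 - r2)

    from pathtrio.qc import _pairwise_corr, _window_vifs

    vifs = _window_vifs(_pairwise_corr(X))
    assert vifs[2] == pytest.approx(vif_oracle, rel=1e-6)


def test_window_with_single_polymorphic_snp_passes():
    G = np.zeros((6, 2), dtype=np.int8)
    G[:, 1] = [0, 1, 2, 1, 0, 1]
    study = make_study(G)
    assert vif_prune(study, QcConfig()) == ["rs1", "rs2"]


# -- apply_qc ------------------------------------------------------------


def qc_fixture_study():
    """180 founder-trios study with SNPs engineered to fail one filter each."""
    rng = np.random.default_rng(4)
    n_tr = 120
    n = 3 * n_tr
    cols, names = [], []

    def add(col, name):
        cols.append(col)
        names.append(name)

    good = rng.binomial(2, 0.3, (n, 3))
    for k in range(3):
        add(good[:, k], f"good{k}")
    add(rng.binomial(2, 0.01, n), "low_maf")  # maf ~0.01
    low_call = rng.binomial(2, 0.3, n)
    low_call = np.where(rng.random(n) < 0.1, MISSING, low_call)
    add(low_call, "low_call")
    hwe_bad = np.tile([0, 2], n // 2)  # no heterozygotes at 50/50 freq
    add(hwe_bad, "hwe_fail")
    G = fill_children(np.column_stack(cols).astype(np.int8), seed=44)
    from pathtrio.model import SnpMeta

    snps = [SnpMeta(snp_id=nm, pos=1000 * (j + 1)) for j, nm in enumerate(names)]
    return make_study(G, snps=snps)


def test_apply_qc_report_matches_hand_tally():
    study = qc_fixture_study()
    filtered, report = apply_qc(study, QcConfig())
    rows = report.set_index("filter")
    assert rows.loc["call_rate", "snps_removed"] == 1
    assert rows.loc["maf", "snps_removed"] == 1
    assert rows.loc["hwe", "snps_removed"] == 1
    kept = {s.snp_id for s in filtered.snps}
    assert kept == {"good0", "good1", "good2"}


def test_filter_order_call_rate_before_maf():
    """A SNP failing both call rate and MAF is attributed to call rate."""
    rng = np.random.default_rng(8)
    n = 300
    bad = rng.binomial(2, 0.01, n)
    bad = np.where(rng.random(n) < 0.2, MISSING, bad)
    G = fill_children(
        np.column_stack([bad, rng.binomial(2, 0.3, n)]).astype(np.int8), seed=8
    )
    study = make_study(G)
    _, report = apply_qc(study, QcConfig())
    rows = report.set_index("filter")
    assert rows.loc["call_rate", "snps_removed"] == 1
    assert rows.loc["maf", "snps_removed"] == 0


def test_lowering_maf_min_never_removes_more():
    study = qc_fixture_study()
    removed = []
    for maf_min in (0.2, 0.1, 0.05, 0.01):
        _, report = apply_qc(study, QcConfig(maf_min=maf_min))
        removed.append(
            report.set_index("filter").loc["maf", "snps_removed"]
        )
    assert removed == sorted(removed, reverse=True)


def test_all_snps_removed_is_explicit_error():
    study = make_study(np.full((3, 2), MISSING, dtype=np.int8))
    with pytest.raises(ValueError, match="all SNPs removed"):
        apply_qc(study, QcConfig())


def test_qc_config_validation():
    with pytest.raises(ValueError):
        QcConfig(maf_min=0.7)
    with pytest.raises(ValueError):
        QcConfig(vif_threshold=0.5)
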
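"""Synthetic affected-offspring trio studies with a causal pathway.

The generator emulates the statistical structure the analysis assumes:
founders in Hardy-Weinberg equilibrium at per-SNP minor allele
frequencies, independent SNPs partitioned contiguously into genes and
genes into gene sets, and excess transmission of the risk allele
concentrated in a designated "causal" set.  Ascertainment is modelled
purely as transmission distortion — every offspring is labelled affected
and each heterozygous parent transmits the risk allele with probability
``tau`` (0.5 = null) at causal SNPs — because the TDT's noncentrality
depends only on the transmission probability.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .model import FUNC_CLASSES, MISSING, GeneSet, GeneSetDB, SnpMeta, TrioStudy


@dataclass
class SimConfig:
    """Study-generation parameters.

    ``tau`` is the probability a heterozygous parent transmits the risk
    (allele_b) allele at a causal SNP; ``causal_fraction`` is the share of
    the causal set's SNPs given that distortion.  SNPs are split evenly
    and contiguously over ``n_genes`` genes and genes over ``n_sets``
    sets; ``causal_set_id=None`` designates the middle set.
    """

    n_trios: int = 500
    n_snps: int = 1000
    n_genes: int = 100
    n_sets: int = 10
    causal_set_id: str | None = None
    causal_fraction: float = 0.5
    tau: float = 0.6
    maf_range: tuple[float, float] = (0.05, 0.5)
    missing_rate: float = 0.02
    class_probs: tuple[float, float, float] = (0.10, 0.05, 0.85)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.5 <= self.tau < 1:
            raise ValueError("tau must be in [0.5, 1)")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must be in [0, 1)")
        if not math.isclose(sum(self.class_probs), 1.0, abs_tol=1e-9):
            raise ValueError("class_probs must sum to 1")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5]")
        if not 0 <= self.causal_fraction <= 1:
            raise ValueError("causal_fraction must be in [0, 1]")


@dataclass
class SimulatedStudy:
    """A generated study with its annotation, gene sets and ground truth."""

    study: TrioStudy
    annotation: dict[str, tuple[str | None, str]]
    gene_sets: GeneSetDB
    truth: pd.DataFrame  # snp_id, gene, set_id, func_class, maf, is_causal, tau


def _partition(cfg: SimConfig) -> tuple[list[str], list[str], list[str]]:
    """Map SNP index -> (snp_id, gene, set_id) by contiguous blocks."""
    snp_ids = [f"rs{i + 1:06d}" for i in range(cfg.n_snps)]
    per_gene = math.ceil(cfg.n_snps / cfg.n_genes)
    genes = [f"GENE{(i // per_gene) + 1:04d}" for i in range(cfg.n_snps)]
    per_set = math.ceil(cfg.n_genes / cfg.n_sets)
    gene_set = {
        f"GENE{g + 1:04d}": f"GO:SIM{(g // per_set) + 1:04d}"
        for g in range(cfg.n_genes)
    }
    sets = [gene_set[g] for g in genes]
    return snp_ids, genes, sets


def _default_causal_set(cfg: SimConfig) -> str:
    return f"GO:SIM{cfg.n_sets // 2 + 1:04d}"


def _transmit(
    parent: np.ndarray, tau_snp: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Allele transmitted by each parent: 1 risk copy iff hom-risk, or het
    parent passing the risk allele with probability tau."""
    het_pass = rng.random(parent.shape) < tau_snp
    return (parent == 2).astype(np.int8) + (
        (parent == 1) & het_pass
    ).astype(np.int8)


def simulate_study(cfg: SimConfig) -> SimulatedStudy:
    """Generate one trio study plus annotation, gene sets and truth record."""
    rng = np.random.default_rng(cfg.seed)
    snp_ids, genes, sets = _partition(cfg)
    causal_set = (
        cfg.causal_set_id
        if cfg.causal_set_id is not None
        else _default_causal_set(cfg)
    )
    all_sets = sorted(set(sets))
    if causal_set not in all_sets:
        raise ValueError(
            f"causal_set_id {causal_set!r} not among generated sets "
            f"{all_sets[:5]}..."
        )

    maf = rng.uniform(*cfg.maf_range, cfg.n_snps)
    func_class = rng.choice(FUNC_CLASSES, size=cfg.n_snps, p=cfg.class_probs)

    in_causal_set = np.array([s == causal_set for s in sets])
    candidates = np.nonzero(in_causal_set)[0]
    n_causal = int(round(cfg.causal_fraction * len(candidates)))
    causal_idx = (
        rng.choice(candidates, size=n_causal, replace=False)
        if n_causal
        else np.array([], dtype=np.intp)
    )
    is_causal = np.zeros(cfg.n_snps, dtype=bool)
    is_causal[causal_idx] = True
    tau_snp = np.where(is_causal, cfg.tau, 0.5)

    n = cfg.n_trios
    father = rng.binomial(2, maf, (n, cfg.n_snps)).astype(np.int8)
    mother = rng.binomial(2, maf, (n, cfg.n_snps)).astype(np.int8)
    child = _transmit(father, tau_snp, rng) + _transmit(mother, tau_snp, rng)

    geno = np.empty((3 * n, cfg.n_snps), dtype=np.int8)
    geno[0::3] = father
    geno[1::3] = mother
    geno[2::3] = child
    if cfg.missing_rate > 0:
        geno[rng.random(geno.shape) < cfg.missing_rate] = MISSING

    fam = np.repeat([f"F{i + 1:05d}" for i in range(n)], 3)
    roles = np.tile(["F", "M", "C"], n)
    iid = np.char.add(np.char.add(fam.astype(str), "_"), roles)
    child_sex = rng.choice([1, 2], size=n)
    samples = pd.DataFrame(
        {
            "family_id": fam,
            "individual_id": iid,
            "father_id": np.where(roles == "C", np.char.add(fam, "_F"), "0"),
            "mother_id": np.where(roles == "C", np.char.add(fam, "_M"), "0"),
            "sex": np.where(
                roles == "F", 1, np.where(roles == "M", 2, 0)
            ).astype(int),
            "affection": np.where(roles == "C", 2, 1).astype(int),
        }
    )
    samples.loc[2::3, "sex"] = child_sex

    snps = [
        SnpMeta(
            snp_id=snp_ids[j],
            chrom="1",
            pos=10_000 * (j + 1),
            allele_a="A",
            allele_b="B",
            gene=genes[j],
            func_class=str(func_class[j]),
        )
        for j in range(cfg.n_snps)
    ]
    study = TrioStudy(samples=samples, genotypes=geno, snps=snps)

    annotation = {
        snp_ids[j]: (genes[j], str(func_class[j])) for j in range(cfg.n_snps)
    }
    set_to_genes: dict[str, list[str]] = {}
    for g, s in sorted(set(zip(genes, sets))):
        set_to_genes.setdefault(s, []).append(g)
    db = GeneSetDB(
        sets={
            s: GeneSet(s, f"synthetic gene set {s}", tuple(gs))
            for s, gs in sorted(set_to_genes.items())
        }
    )
    truth = pd.DataFrame(
        {
            "snp_id": snp_ids,
            "gene": genes,
            "set_id": sets,
            "func_class": func_class,
            "maf": maf,
            "is_causal": is_causal,
            "tau": tau_snp,
        }
    )
    truth.attrs["causal_set_id"] = causal_set
    return SimulatedStudy(study, annotation, db, truth)


def simulate_pair(
    cfg_inv: SimConfig,
    cfg_rep: SimConfig,
    panel_fraction: float = 1.0,
) -> tuple[SimulatedStudy, SimulatedStudy]:
    """Investigation + replication studies sharing one causal architecture.

    The replication study has independent families (its own seed) but the
    same per-SNP MAFs, functional classes and causal/tau assignments on a
    random ``panel_fraction`` subset of the investigation panel — the way
    a second genotyping array covers only part of the first one.
    """
    if not 0 < panel_fraction <= 1:
        raise ValueError("panel_fraction must be in (0, 1]")
    inv = simulate_study(cfg_inv)
    truth = inv.truth
    rng = np.random.default_rng(cfg_rep.seed)
    n_panel = int(round(panel_fraction * cfg_inv.n_snps))
    panel = np.sort(rng.choice(cfg_inv.n_snps, size=n_panel, replace=False))

    maf = truth["maf"].to_numpy()[panel]
    tau_snp = truth["tau"].to_numpy()[panel]
    n = cfg_rep.n_trios
    father = rng.binomial(2, maf, (n, n_panel)).astype(np.int8)
    mother = rng.binomial(2, maf, (n, n_panel)).astype(np.int8)
    child = _transmit(father, tau_snp, rng) + _transmit(mother, tau_snp, rng)
    geno = np.empty((3 * n, n_panel), dtype=np.int8)
    geno[0::3] = father
    geno[1::3] = mother
    geno[2::3] = child
    if cfg_rep.missing_rate > 0:
        geno[rng.random(geno.shape) < cfg_rep.missing_rate] = MISSING

    template = inv.study.select_snps(panel)
    fam = np.repeat([f"R{i + 1:05d}" for i in range(n)], 3)
    roles = np.tile(["F", "M", "C"], n)
    iid = np.char.add(np.char.add(fam.astype(str), "_"), roles)
    samples = pd.DataFrame(
        {
            "family_id": fam,
            "individual_id": iid,
            "father_id": np.where(roles == "C", np.char.add(fam, "_F"), "0"),
            "mother_id": np.where(roles == "C", np.char.add(fam, "_M"), "0"),
            "sex": np.where(roles == "F", 1, 2).astype(int),
            "affection": np.where(roles == "C", 2, 1).astype(int),
        }
    )
    rep_study = TrioStudy(
        samples=samples,
        genotypes=geno,
        snps=[replace(s) for s in template.snps],
    )
    rep = SimulatedStudy(
        study=rep_study,
        annotation=inv.annotation,
        gene_sets=inv.gene_sets,
        truth=truth,
    )
    return inv, rep
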
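"""Repeated-run experiments: null calibration and power of the pipeline.

These helpers run the simulator, the TDT and the matched-permutation test
many times to measure operating characteristics — the type-I rate of the
one-sided exceedance rule under a fully null generator, and the H1 /
replication rate as transmission distortion grows.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from .permutation import PermutationConfig, pathway_verdict
from .pipeline import run_two_phase
from .qc import QcConfig
from .simulate import SimConfig, simulate_pair, simulate_study
from .tdt import tdt_frame, tdt_scan


def _study_seeds(base_seed: int, n: int) -> np.ndarray:
    return np.random.default_rng(base_seed).integers(0, 2**31 - 1, size=n)


def pathway_exceedance_for_study(
    sim_cfg: SimConfig, perm_cfg: PermutationConfig
) -> tuple[float, float, str]:
    """Simulate one study, TDT it, and permutation-test its causal set.

    Returns (exceed_frac_05, exceed_frac_01, decision) for the designated
    pathway (QC is not applied: the generator already satisfies it up to
    sampling noise, and calibration concerns only the permutation rule).
    """
    sim = simulate_study(sim_cfg)
    results = tdt_scan(sim.study)
    table = tdt_frame(sim.study, results)
    causal_set = sim.truth.attrs["causal_set_id"]
    pathway_ids = sim.truth.loc[
        sim.truth["set_id"] == causal_set, "snp_id"
    ].tolist()
    v = pathway_verdict(pathway_ids, table, perm_cfg)
    return v.exceed_frac_05, v.exceed_frac_01, v.decision


def null_calibration(
    n_studies: int = 1000,
    sim_cfg: SimConfig | None = None,
    perm_cfg: PermutationConfig | None = None,
    base_seed: int = 0,
) -> dict:
    """Type-I rate of the exceedance rule over fully null studies.

    Each study is generated with tau = 0.5 (no distortion anywhere) and a
    designated pathway; the fraction of studies whose 0.05-level
    exceedance falls below ``alpha_05`` estimates the one-sided type-I
    rate, nominally 2.5%.
    """
    sim_cfg = sim_cfg or SimConfig(
        n_trios=200, n_snps=2000, n_genes=200, n_sets=20, tau=0.5
    )
    if sim_cfg.tau != 0.5:
        raise ValueError("null calibration requires tau = 0.5")
    perm_cfg = perm_cfg or PermutationConfig(n_perm=2000)
    seeds = _study_seeds(base_seed, n_studies)
    frac05 = np.empty(n_studies)
    frac01 = np.empty(n_studies)
    h1 = 0
    for i, s in enumerate(seeds):
        cfg_i = replace(sim_cfg, seed=int(s))
        pcfg_i = replace(perm_cfg, seed=int(s) + 1)
        f05, f01, decision = pathway_exceedance_for_study(cfg_i, pcfg_i)
        frac05[i] = f05
        frac01[i] = f01
        h1 += decision == "H1"
    below_05 = frac05 < perm_cfg.alpha_05
    rate = float(below_05.mean())
    return {
        "n_studies": n_studies,
        "rate_below_alpha_05": rate,
        "rate_below_alpha_05_pct": 100.0 * rate,
        "h1_rate": h1 / n_studies,
        "binomial_se": float(
            np.sqrt(perm_cfg.alpha_05 * (1 - perm_cfg.alpha_05) / n_studies)
        ),
        "exceed_frac_05": frac05,
        "exceed_frac_01": frac01,
    }


def h1_rate_vs_tau(
    taus: tuple[float, ...] = (0.50, 0.55, 0.60),
    n_reps: int = 200,
    sim_cfg: SimConfig | None = None,
    perm_cfg: PermutationConfig | None = None,
    base_seed: int = 0,
) -> dict[float, float]:
    """Single-sample H1 acceptance rate at each transmission distortion.

    The same per-replicate seeds are reused across tau values so the
    comparison is paired.
    """
    sim_cfg = sim_cfg or SimConfig(
        n_trios=200, n_snps=1000, n_genes=100, n_sets=10, causal_fraction=0.5
    )
    perm_cfg = perm_cfg or PermutationConfig(n_perm=1000)
    seeds = _study_seeds(base_seed, n_reps)
    rates: dict[float, float] = {}
    for tau in taus:
        h1 = 0
        for s in seeds:
            cfg_i = replace(sim_cfg, tau=tau, seed=int(s))
            pcfg_i = replace(perm_cfg, seed=int(s) + 1)
            _, _, decision = pathway_exceedance_for_study(cfg_i, pcfg_i)
            h1 += decision == "H1"
        rates[tau] = h1 / n_reps
    return rates


def replication_rate(
    n_seeds: int = 50,
    sim_cfg: SimConfig | None = None,
    panel_fraction: float = 0.6,
    perm_cfg: PermutationConfig | None = None,
    qc_cfg: QcConfig | None = None,
    base_seed: int = 0,
) -> dict:
    """Fraction of full two-phase runs ending in "replicated".

    Each seed simulates an investigation/replication pair with a shared
    causal architecture and runs the complete pipeline (QC included).
    Runs that find no index pathway count as not replicated.
    """
    sim_cfg = sim_cfg or SimConfig(
        n_trios=500, n_snps=600, n_genes=60, n_sets=6,
        tau=0.6, causal_fraction=0.5,
    )
    perm_cfg = perm_cfg or PermutationConfig(n_perm=1000)
    qc_cfg = qc_cfg or QcConfig()
    seeds = _study_seeds(base_seed, n_seeds)
    outcomes = []
    from .enrichment import NoIndexPathwayError

    for s in seeds:
        cfg_inv = replace(sim_cfg, seed=int(s))
        cfg_rep = replace(sim_cfg, seed=int(s) + 10**6)
        inv, rep = simulate_pair(cfg_inv, cfg_rep, panel_fraction)
        try:
            result = run_two_phase(
                inv.study,
                rep.study,
                inv.gene_sets,
                qc_cfg=qc_cfg,
                perm_cfg=replace(perm_cfg, seed=int(s) + 1),
            )
        except NoIndexPathwayError:
            outcomes.append(("no_index_pathway", None))
            continue
        outcomes.append((result.decision, result.index_pathway.set_id))
    n_replicated = sum(1 for d, _ in outcomes if d == "replicated")
    causal_set = simulate_study(sim_cfg).truth.attrs["causal_set_id"]
    n_correct_index = sum(1 for _, sid in outcomes if sid == causal_set)
    return {
        "n_seeds": n_seeds,
        "replicated_fraction": n_replicated / n_seeds,
        "correct_index_fraction": n_correct_index / n_seeds,
        "outcomes": outcomes,
    }
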
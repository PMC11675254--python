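"""Matched-permutation significance test for pathway enrichment.

Random SNP sets are drawn from the non-pathway universe with the same
size and functional-class composition (missense / splice / unannotated)
as the tested pathway.  For each draw the number of SNPs significant at
the nominal 0.05 and 0.01 levels is counted; the *exceedance fraction* at
a level is the share of draws whose count is greater than or equal to the
observed pathway count.  H1 (true enrichment) is accepted only when both
exceedance fractions fall below their one-sided thresholds (defaults
0.025 and 0.005 — the two-sided 0.05/0.01 levels halved, since only an
excess of significant SNPs counts as evidence).

``exceedance`` samples the per-draw counts directly: within each
functional class, the number of significant SNPs in a uniform
without-replacement draw is multivariate-hypergeometric, and classes are
drawn independently, so sampling class-wise category counts and summing
is distributionally identical to materialising each SNP set.  This keeps
a million permutations to a few array operations.
:func:`draw_matched_set` still materialises explicit SNP-id sets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .model import FUNC_CLASSES

#: Nominal significance levels counted within each drawn set.
LEVELS = (0.05, 0.01)


@dataclass
class PermutationConfig:
    n_perm: int = 10**6
    match_classes: bool = True
    seed: int = 0
    alpha_05: float = 0.025
    alpha_01: float = 0.005
    relax_matching: bool = False

    def __post_init__(self) -> None:
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")
        for a in (self.alpha_05, self.alpha_01):
            if not 0 < a < 0.5:
                raise ValueError("one-sided thresholds must be in (0, 0.5)")


@dataclass
class PermutationVerdict:
    observed_count_05: int
    observed_count_01: int
    exceed_frac_05: float
    exceed_frac_01: float
    decision: str  # "H0" | "H1"
    n_perm: int = 0
    mc_se_05: float = float("nan")
    mc_se_01: float = float("nan")


def draw_matched_set(
    universe: pd.DataFrame | Sequence,
    target_class_counts: Mapping[str, int],
    rng: np.random.Generator,
) -> list[str]:
    """One uniform draw of SNP ids matched per functional class.

    ``universe`` is a frame with snp_id and func_class columns (or a
    sequence of objects with those attributes) that must already exclude
    the tested pathway's own SNPs.  Raises when a class has fewer SNPs
    than requested, naming the class.
    """
    if not isinstance(universe, pd.DataFrame):
        universe = pd.DataFrame(
            {
                "snp_id": [s.snp_id for s in universe],
                "func_class": [s.func_class for s in universe],
            }
        )
    drawn: list[str] = []
    for cls in FUNC_CLASSES:
        need = int(target_class_counts.get(cls, 0))
        if need == 0:
            continue
        pool = universe.loc[universe["func_class"] == cls, "snp_id"].to_numpy()
        if len(pool) < need:
            raise ValueError(
                f"cannot draw {need} {cls!r} SNPs: only {len(pool)} in the "
                f"universe"
            )
        drawn.extend(rng.choice(pool, size=need, replace=False))
    return drawn


def _class_pools(
    universe_p: np.ndarray, universe_class: np.ndarray, match_classes: bool
) -> dict[str, np.ndarray]:
    if match_classes:
        return {
            cls: universe_p[universe_class == cls] for cls in FUNC_CLASSES
        }
    return {"all": universe_p}


def exceedance(
    tested_counts: tuple[int, int],
    universe_results: Mapping[str, float] | pd.Series,
    cfg: PermutationConfig,
    target_class_counts: Mapping[str, int],
    universe_classes: Mapping[str, str] | None = None,
) -> PermutationVerdict:
    """Exceedance fractions and H0/H1 verdict for observed (count_05, count_01).

    ``universe_results`` maps candidate snp_id -> p-value (pathway SNPs
    excluded); ``universe_classes`` maps snp_id -> functional class and is
    required when ``cfg.match_classes``.  Draw counts at the two levels
    are sampled jointly per class (multivariate hypergeometric), ``>=``
    defines exceedance, and H1 needs both fractions under their
    thresholds.
    """
    obs_05, obs_01 = int(tested_counts[0]), int(tested_counts[1])
    if isinstance(universe_results, pd.Series):
        ids = universe_results.index.to_numpy()
        pvals = universe_results.to_numpy(dtype=float)
    else:
        ids = np.array(list(universe_results.keys()))
        pvals = np.array([universe_results[i] for i in ids], dtype=float)

    match = cfg.match_classes
    if match:
        if universe_classes is None:
            raise ValueError("universe_classes required when matching classes")
        classes = np.array([universe_classes[i] for i in ids])
        targets = {c: int(target_class_counts.get(c, 0)) for c in FUNC_CLASSES}
    else:
        classes = np.full(len(ids), "all")
        targets = {"all": int(sum(target_class_counts.values()))}

    for cls, need in targets.items():
        have = int((classes == cls).sum())
        if need > have:
            if cfg.relax_matching:
                warnings.warn(
                    f"class {cls!r} exhausted ({need} needed, {have} "
                    f"available); falling back to size-only matching"
                )
                classes = np.full(len(ids), "all")
                targets = {"all": int(sum(target_class_counts.values()))}
                match = False
                break
            raise ValueError(
                f"cannot match class {cls!r}: {need} needed, {have} in universe"
            )

    rng = np.random.default_rng(cfg.seed)
    count_05 = np.zeros(cfg.n_perm, dtype=np.int64)
    count_01 = np.zeros(cfg.n_perm, dtype=np.int64)
    for cls, need in targets.items():
        if need == 0:
            continue
        p_cls = pvals[classes == cls]
        n_sig01 = int((p_cls < LEVELS[1]).sum())
        n_sig05only = int(((p_cls < LEVELS[0]) & (p_cls >= LEVELS[1])).sum())
        n_rest = len(p_cls) - n_sig01 - n_sig05only
        draws = rng.multivariate_hypergeometric(
            [n_sig01, n_sig05only, n_rest], need, size=cfg.n_perm
        )
        count_01 += draws[:, 0]
        count_05 += draws[:, 0] + draws[:, 1]

    frac_05 = float((count_05 >= obs_05).mean())
    frac_01 = float((count_01 >= obs_01).mean())
    decision = (
        "H1" if (frac_05 < cfg.alpha_05 and frac_01 < cfg.alpha_01) else "H0"
    )
    se = lambda f: float(np.sqrt(f * (1 - f) / cfg.n_perm))
    return PermutationVerdict(
        observed_count_05=obs_05,
        observed_count_01=obs_01,
        exceed_frac_05=frac_05,
        exceed_frac_01=frac_01,
        decision=decision,
        n_perm=cfg.n_perm,
        mc_se_05=se(frac_05),
        mc_se_01=se(frac_01),
    )


def pathway_verdict(
    pathway_snp_ids: Sequence[str],
    results_table: pd.DataFrame,
    cfg: PermutationConfig,
) -> PermutationVerdict:
    """Full permutation test of a SNP set against the rest of a results table.

    ``results_table`` needs snp_id, p and func_class columns covering both
    the pathway and the candidate universe; the pathway's own SNPs are
    excluded from the null draws.  Observed counts are the pathway SNPs
    significant at 0.05 and 0.01; target class counts mirror the
    pathway's composition.
    """
    path = set(pathway_snp_ids)
    in_path = results_table["snp_id"].isin(path)
    obs = results_table.loc[in_path]
    rest = results_table.loc[~in_path]
    observed = (
        int((obs["p"] < LEVELS[0]).sum()),
        int((obs["p"] < LEVELS[1]).sum()),
    )
    targets = obs["func_class"].value_counts().to_dict()
    return exceedance(
        observed,
        pd.Series(rest["p"].to_numpy(), index=rest["snp_id"].to_numpy()),
        cfg,
        targets,
        universe_classes=dict(zip(rest["snp_id"], rest["func_class"])),
    )


def decide(
    investigation: PermutationVerdict, replication: PermutationVerdict
) -> str:
    """Two-phase outcome: "replicated" iff both samples accept H1."""
    both = investigation.decision == "H1" and replication.decision == "H1"
    return "replicated" if both else "not_replicated"
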
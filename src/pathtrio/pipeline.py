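"""End-to-end two-phase driver.

Phase 1 (investigation sample): QC -> TDT -> inflation check -> genelist1
-> gene-set enrichment -> index pathway -> matched-permutation verdict.
Phase 2 (replication sample): QC -> TDT -> availability/direction
selection -> prevalence at 0.05 and 0.01 -> matched-permutation verdict
-> final replicated / not-replicated decision.

A single YAML/JSON config governs a run; every intermediate table is
written as TSV next to a human-readable summary so the decision can be
audited number by number.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any, Mapping

import pandas as pd
import yaml

from . import io as ptio
from .enrichment import (
    EnrichmentRow,
    IndexPathway,
    NoIndexPathwayError,
    build_genelist1,
    enrich,
    enrichment_frame,
    select_index_pathway,
)
from .inflation import genomic_lambda, qq_coordinates
from .model import GeneSetDB, TrioStudy
from .permutation import (
    PermutationConfig,
    PermutationVerdict,
    decide,
    pathway_verdict,
)
from .qc import QcConfig, apply_qc
from .replication import (
    PrevalenceResult,
    ReplicationSelection,
    prevalence,
    select_replication_snps,
)
from .simulate import SimConfig, simulate_pair
from .tdt import tdt_frame, tdt_scan


class ConfigError(ValueError):
    """Missing or invalid pipeline configuration key."""


@dataclass
class PipelineResult:
    qc_report_inv: pd.DataFrame
    qc_report_rep: pd.DataFrame
    lambda_inv: float
    lambda_rep: float
    tdt_inv: pd.DataFrame
    tdt_rep: pd.DataFrame
    genelist1: list[str]
    enrichment: list[EnrichmentRow]
    index_pathway: IndexPathway
    inv_verdict: PermutationVerdict
    selection: ReplicationSelection
    prevalences: dict[float, PrevalenceResult]
    rep_verdict: PermutationVerdict
    decision: str
    seeds: dict[str, int] = field(default_factory=dict)


def _require(cfg: Mapping[str, Any], key: str, where: str = "config"):
    if key not in cfg:
        raise ConfigError(f"missing {where} key: {key!r}")
    return cfg[key]


def run_two_phase(
    inv_study: TrioStudy,
    rep_study: TrioStudy,
    gene_sets: GeneSetDB,
    qc_cfg: QcConfig | None = None,
    perm_cfg: PermutationConfig | None = None,
    p_threshold: float = 0.001,
    alpha: float = 0.05,
    levels: tuple[float, ...] = (0.05, 0.01),
    require_inv_p: float | None = None,
) -> PipelineResult:
    """Run the full two-phase analysis on annotated studies.

    Both studies must carry gene / functional-class annotation on their
    SNP metadata.  Raises :class:`~pathtrio.enrichment.NoIndexPathwayError`
    when Phase 1 finds no over-represented set.
    """
    qc_cfg = qc_cfg or QcConfig()
    perm_cfg = perm_cfg or PermutationConfig(n_perm=2000)

    # ---- Phase 1: investigation ---------------------------------------
    inv_qc, report_inv = apply_qc(inv_study, qc_cfg)
    inv_results = tdt_scan(inv_qc)
    lambda_inv = genomic_lambda(inv_results)
    inv_table = tdt_frame(inv_qc, inv_results)

    annotation = {
        s.snp_id: (s.gene, s.func_class) for s in inv_qc.snps
    }
    genelist1 = build_genelist1(inv_results, annotation, p_threshold)
    if not genelist1:
        raise NoIndexPathwayError(
            f"genelist1 is empty at p < {p_threshold}: no gene to test"
        )
    universe = sorted(
        {s.gene for s in inv_qc.snps if s.gene is not None}
    )
    rows = enrich(genelist1, gene_sets, universe)
    index = select_index_pathway(rows, gene_sets, inv_qc.snp_table(), alpha)
    inv_verdict = pathway_verdict(index.snp_ids, inv_table, perm_cfg)

    # ---- Phase 2: replication -----------------------------------------
    rep_qc, report_rep = apply_qc(rep_study, qc_cfg)
    rep_results = tdt_scan(rep_qc)
    lambda_rep = genomic_lambda(rep_results)
    rep_table = tdt_frame(rep_qc, rep_results)

    selection = select_replication_snps(
        index, inv_results, rep_results, require_inv_p=require_inv_p
    )
    prevalences = {
        level: prevalence(selection, rep_results, level) for level in levels
    }
    rep_verdict = pathway_verdict(selection.snp_ids, rep_table, perm_cfg)

    return PipelineResult(
        qc_report_inv=report_inv,
        qc_report_rep=report_rep,
        lambda_inv=lambda_inv,
        lambda_rep=lambda_rep,
        tdt_inv=inv_table,
        tdt_rep=rep_table,
        genelist1=genelist1,
        enrichment=rows,
        index_pathway=index,
        inv_verdict=inv_verdict,
        selection=selection,
        prevalences=prevalences,
        rep_verdict=rep_verdict,
        decision=decide(inv_verdict, rep_verdict),
        seeds={"permutation": perm_cfg.seed},
    )


def load_config(config_path: str | Path) -> dict:
    with open(config_path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ConfigError("config must be a mapping")
    return cfg


def _studies_from_config(cfg: Mapping[str, Any]):
    if "synthetic" in cfg:
        syn = cfg["synthetic"]
        inv_cfg = SimConfig(**_require(syn, "investigation", "synthetic"))
        rep_cfg = SimConfig(**_require(syn, "replication", "synthetic"))
        inv, rep = simulate_pair(
            inv_cfg, rep_cfg, panel_fraction=syn.get("panel_fraction", 1.0)
        )
        return inv.study, rep.study, inv.gene_sets, {
            "simulate_investigation": inv_cfg.seed,
            "simulate_replication": rep_cfg.seed,
        }
    inputs = _require(cfg, "inputs")
    inv_paths = _require(inputs, "investigation", "inputs")
    rep_paths = _require(inputs, "replication", "inputs")
    inv = ptio.read_ped_map(
        _require(inv_paths, "ped", "inputs.investigation"),
        _require(inv_paths, "map", "inputs.investigation"),
    )
    rep = ptio.read_ped_map(
        _require(rep_paths, "ped", "inputs.replication"),
        _require(rep_paths, "map", "inputs.replication"),
    )
    annotation = ptio.read_annotation(_require(inputs, "annotation", "inputs"))
    inv.annotate(annotation)
    rep.annotate(annotation)
    gene_sets = ptio.read_gmt(_require(inputs, "gene_sets", "inputs"))
    return inv, rep, gene_sets, {}


def write_outputs(result: PipelineResult, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result.qc_report_inv.to_csv(out / "qc_investigation.tsv", sep="\t", index=False)
    result.qc_report_rep.to_csv(out / "qc_replication.tsv", sep="\t", index=False)
    result.tdt_inv.to_csv(out / "tdt_investigation.tsv", sep="\t", index=False)
    result.tdt_rep.to_csv(out / "tdt_replication.tsv", sep="\t", index=False)
    enrichment_frame(result.enrichment).to_csv(
        out / "enrichment.tsv", sep="\t", index=False
    )
    (out / "genelist1.txt").write_text("\n".join(result.genelist1) + "\n")
    (out / "genelist2.txt").write_text(
        "\n".join(result.index_pathway.genes) + "\n"
    )
    pd.DataFrame(
        {
            "snp_id": result.index_pathway.snp_ids,
            "func_class": [
                result.index_pathway.snp_classes[s]
                for s in result.index_pathway.snp_ids
            ],
        }
    ).to_csv(out / "index_pathway_snps.tsv", sep="\t", index=False)

    prev_rows = [
        {
            "level": p.level,
            "n_selected": p.n_selected,
            "n_significant": p.n_significant,
            "prevalence": p.prevalence,
            "expected": p.expected,
            "relative_excess_pct": p.relative_excess_pct,
        }
        for p in result.prevalences.values()
    ]
    pd.DataFrame(prev_rows).to_csv(out / "prevalence.tsv", sep="\t", index=False)

    perm_rows = []
    for sample, v in (
        ("investigation", result.inv_verdict),
        ("replication", result.rep_verdict),
    ):
        for level, obs, frac in (
            (0.05, v.observed_count_05, v.exceed_frac_05),
            (0.01, v.observed_count_01, v.exceed_frac_01),
        ):
            perm_rows.append(
                {
                    "sample": sample,
                    "level": level,
                    "observed_count": obs,
                    "exceed_frac": frac,
                    "decision": v.decision,
                    "n_perm": v.n_perm,
                }
            )
    pd.DataFrame(perm_rows).to_csv(
        out / "permutation.tsv", sep="\t", index=False
    )

    report = {
        "lambda_investigation": result.lambda_inv,
        "lambda_replication": result.lambda_rep,
        "genelist1_size": len(result.genelist1),
        "index_pathway": result.index_pathway.set_id,
        "index_pathway_n_snps": len(result.index_pathway.snp_ids),
        "index_pathway_class_counts": result.index_pathway.class_counts,
        "replication_n_selected": result.selection.n_selected,
        "prevalences": {
            str(level): {
                "prevalence": p.prevalence,
                "expected": p.expected,
                "relative_excess_pct": p.relative_excess_pct,
            }
            for level, p in result.prevalences.items()
        },
        "investigation_verdict": asdict(result.inv_verdict),
        "replication_verdict": asdict(result.rep_verdict),
        "decision": result.decision,
        "seeds": result.seeds,
    }
    (out / "report.json").write_text(json.dumps(report, indent=2) + "\n")

    lines = [
        "pathtrio two-phase run summary",
        "=" * 32,
        f"lambda (investigation): {result.lambda_inv:.3f}",
        f"lambda (replication):   {result.lambda_rep:.3f}",
        f"genelist1: {len(result.genelist1)} genes",
        f"index pathway: {result.index_pathway.set_id} "
        f"({len(result.index_pathway.genes)} genes, "
        f"{len(result.index_pathway.snp_ids)} SNPs)",
        f"replication selection: {result.selection.n_selected} SNPs "
        f"(available + direction-concordant)",
    ]
    for level, p in result.prevalences.items():
        lines.append(
            f"prevalence @ p<{level}: {100 * p.prevalence:.1f}% "
            f"(expected {100 * p.expected:.1f}%, "
            f"{p.relative_excess_pct:+.0f}% excess)"
        )
    for sample, v in (
        ("investigation", result.inv_verdict),
        ("replication", result.rep_verdict),
    ):
        lines.append(
            f"{sample} permutation: exceed 0.05-level "
            f"{v.exceed_frac_05:.4f}, 0.01-level {v.exceed_frac_01:.4f} "
            f"-> {v.decision}"
        )
    lines.append(f"decision: {result.decision}")
    (out / "summary.txt").write_text("\n".join(lines) + "\n")


def run_pipeline(
    config: str | Path | Mapping[str, Any], out_dir: str | Path
) -> tuple[int, PipelineResult | None]:
    """Config-driven run; returns (exit status, result).

    Status 0 = completed, 2 = clean halt because no index pathway was
    over-represented.  Any other failure propagates as an exception.
    """
    if not isinstance(config, Mapping):
        config = load_config(config)
    inv, rep, gene_sets, seeds = _studies_from_config(config)

    qc_cfg = QcConfig(**config.get("qc", {}))
    perm_kwargs = dict(config.get("permutation", {}))
    perm_cfg = PermutationConfig(**{"n_perm": 2000, **perm_kwargs})
    enr = config.get("enrichment", {})

    try:
        result = run_two_phase(
            inv,
            rep,
            gene_sets,
            qc_cfg=qc_cfg,
            perm_cfg=perm_cfg,
            p_threshold=enr.get("p_threshold", 0.001),
            alpha=enr.get("alpha", 0.05),
            require_inv_p=config.get("replication", {}).get(
                "require_inv_p"
            ),
        )
    except NoIndexPathwayError:
        return 2, None
    result.seeds.update(seeds)
    write_outputs(result, out_dir)
    return 0, result
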
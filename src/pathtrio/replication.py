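"""Replication-sample prevalence test for the index pathway.

Phase 2: pathway SNPs that are (a) present on the replication array and
(b) associated in the same direction as in the investigation sample are
selected, and the fraction of them significant at a nominal level is
compared with the level itself — under no enrichment, a fraction ``alpha``
of independent SNPs is expected below ``p = alpha``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

from .enrichment import IndexPathway
from .model import FUNC_CLASSES
from .tdt import TdtResult


@dataclass
class ReplicationSelection:
    """Pathway SNPs surviving availability and direction-concordance filters."""

    snp_ids: list[str]
    class_counts: dict[str, int]

    @property
    def n_selected(self) -> int:
        return len(self.snp_ids)


@dataclass
class PrevalenceResult:
    """Observed vs expected fraction of significant pathway SNPs."""

    level: float
    n_significant: int
    n_selected: int
    prevalence: float
    expected: float
    relative_excess_pct: float


def or_direction(or_value: float) -> int:
    """+1 risk (OR > 1, including infinite), -1 protective, 0 non-directional.

    An undefined OR (T = U = 0) and OR exactly 1 carry no direction.
    """
    if math.isnan(or_value) or or_value == 1.0:
        return 0
    return 1 if or_value > 1.0 else -1


def select_replication_snps(
    index: IndexPathway,
    inv_results: Sequence[TdtResult],
    rep_results: Sequence[TdtResult],
    require_inv_p: float | None = None,
) -> ReplicationSelection:
    """Filter index-pathway SNPs for availability and direction concordance.

    Keeps SNPs present in the replication results whose odds ratio lies on
    the same side of 1 in both samples; non-directional SNPs (OR undefined
    or exactly 1 in either sample) are dropped.  ``require_inv_p`` adds an
    optional strict filter on the investigation-sample p-value.
    """
    inv_by_id = {r.snp_id: r for r in inv_results}
    rep_by_id = {r.snp_id: r for r in rep_results}
    kept: list[str] = []
    counts = {c: 0 for c in FUNC_CLASSES}
    for snp_id in index.snp_ids:
        inv = inv_by_id.get(snp_id)
        rep = rep_by_id.get(snp_id)
        if inv is None or rep is None:
            continue
        if require_inv_p is not None and not inv.p < require_inv_p:
            continue
        d_inv = or_direction(inv.or_value)
        d_rep = or_direction(rep.or_value)
        if d_inv == 0 or d_rep == 0 or d_inv != d_rep:
            continue
        kept.append(snp_id)
        counts[index.snp_classes.get(snp_id, "none")] += 1
    if not kept:
        warnings.warn(
            "no index-pathway SNP passed the replication filters; "
            "prevalence is undefined"
        )
    return ReplicationSelection(snp_ids=kept, class_counts=counts)


def relative_excess_pct(prevalence: float, expected: float) -> float:
    """100 * (prevalence - expected) / expected."""
    return 100.0 * (prevalence - expected) / expected


def prevalence(
    selection: ReplicationSelection,
    rep_results: Sequence[TdtResult],
    level: float,
) -> PrevalenceResult:
    """Within-pathway prevalence of significant replication associations.

    ``prevalence`` = fraction of selected SNPs with replication p below
    ``level``; the expected fraction under no enrichment is the level
    itself.
    """
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    if selection.n_selected == 0:
        raise ValueError("empty selection: prevalence is undefined")
    rep_p = {r.snp_id: r.p for r in rep_results}
    n_sig = sum(1 for s in selection.snp_ids if rep_p[s] < level)
    prev = n_sig / selection.n_selected
    return PrevalenceResult(
        level=level,
        n_significant=n_sig,
        n_selected=selection.n_selected,
        prevalence=prev,
        expected=level,
        relative_excess_pct=relative_excess_pct(prev, level),
    )
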
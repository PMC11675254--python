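"""Gene-set over-representation and index-pathway selection.

Phase 1 of the analysis: genes harboring SNPs below the association
threshold ("genelist1") are tested for over-representation in each gene
set with an upper-tail hypergeometric test against the array-bound gene
universe, adjusted with Benjamini-Hochberg.  The best set below alpha is
the *index pathway*; its genes are "genelist2" and every study SNP mapped
to those genes (not only the sub-threshold ones) forms the pathway SNP
universe carried into replication.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .model import FUNC_CLASSES, GeneSetDB
from .tdt import TdtResult


class NoIndexPathwayError(RuntimeError):
    """No gene set is significantly over-represented; the pipeline halts."""


@dataclass
class EnrichmentRow:
    set_id: str
    set_size_in_universe: int
    overlap: int
    query_size: int
    universe_size: int
    p_hyper: float
    p_adj: float = float("nan")


@dataclass
class IndexPathway:
    """The selected over-represented gene set and its study SNPs."""

    set_id: str
    genes: tuple[str, ...]  # genelist2
    snp_ids: list[str]
    snp_classes: dict[str, str] = field(default_factory=dict)

    @property
    def class_counts(self) -> dict[str, int]:
        counts = {c: 0 for c in FUNC_CLASSES}
        for c in self.snp_classes.values():
            counts[c] += 1
        return counts


def _gene_of(value) -> str | None:
    # annotation maps may carry gene strings or (gene, func_class) tuples
    if isinstance(value, tuple):
        return value[0]
    return value


def build_genelist1(
    results: Sequence[TdtResult],
    annotation: Mapping[str, object],
    p_threshold: float = 0.001,
) -> list[str]:
    """Genes harboring at least one SNP with p below the threshold.

    SNPs without a mapped gene are dropped.  Returns sorted unique gene
    symbols; an empty list triggers a warning but is not an error.
    """
    if not 0 < p_threshold < 1:
        raise ValueError("p_threshold must be in (0, 1)")
    genes = {
        g
        for r in results
        if r.p < p_threshold
        and (g := _gene_of(annotation.get(r.snp_id))) is not None
    }
    if not genes:
        warnings.warn(
            f"no gene has a SNP with p < {p_threshold}; genelist1 is empty"
        )
    return sorted(genes)


def enrich(
    query: Sequence[str], db: GeneSetDB, universe: Sequence[str]
) -> list[EnrichmentRow]:
    """Hypergeometric over-representation of each gene set in the query.

    ``universe`` is the background gene list (genes represented by at
    least one analysed SNP).  For each set with >= 1 gene in the universe,
    p = P(X >= overlap) for X hypergeometric(universe, set-in-universe,
    query) — the chance a random query of the same size overlaps the set
    at least as much.  Benjamini-Hochberg adjusted p-values are attached
    across the tested sets; rows come back sorted by raw p.
    """
    uni = set(universe)
    q = set(query)
    if not q or not uni:
        raise ValueError("query and universe must be non-empty")
    if not q <= uni:
        raise ValueError(
            f"query genes outside the universe: {sorted(q - uni)[:5]}"
        )
    rows = []
    for gs in db:
        set_in_uni = uni.intersection(gs.genes)
        if not set_in_uni:
            continue
        overlap = len(q & set_in_uni)
        p = float(
            hypergeom.sf(overlap - 1, len(uni), len(set_in_uni), len(q))
        )
        rows.append(
            EnrichmentRow(
                set_id=gs.set_id,
                set_size_in_universe=len(set_in_uni),
                overlap=overlap,
                query_size=len(q),
                universe_size=len(uni),
                p_hyper=min(p, 1.0),
            )
        )
    if rows:
        adj = multipletests([r.p_hyper for r in rows], method="fdr_bh")[1]
        for r, a in zip(rows, adj):
            r.p_adj = float(a)
    rows.sort(key=lambda r: (r.p_hyper, r.set_id))
    return rows


def enrichment_frame(rows: Sequence[EnrichmentRow]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "set_id": [r.set_id for r in rows],
            "set_size_in_universe": [r.set_size_in_universe for r in rows],
            "overlap": [r.overlap for r in rows],
            "query_size": [r.query_size for r in rows],
            "universe_size": [r.universe_size for r in rows],
            "p_hyper": [r.p_hyper for r in rows],
            "p_adj": [r.p_adj for r in rows],
        }
    )


def select_index_pathway(
    rows: Sequence[EnrichmentRow],
    db: GeneSetDB,
    snp_table: pd.DataFrame,
    alpha: float = 0.05,
) -> IndexPathway:
    """Pick the single most over-represented set below ``alpha``.

    Ties on adjusted p are broken by larger overlap, then lexicographic
    set id.  ``snp_table`` is the study SNP table (snp_id, gene,
    func_class); every study SNP mapped to a pathway gene joins the
    pathway SNP universe.  Raises :class:`NoIndexPathwayError` when no set
    clears alpha.
    """
    if not rows:
        raise ValueError("no enrichment rows")
    candidates = [r for r in rows if r.p_adj < alpha]
    if not candidates:
        raise NoIndexPathwayError(
            f"no gene set with adjusted p < {alpha}; best was "
            f"{min(rows, key=lambda r: r.p_adj).p_adj:.3g}"
        )
    best = min(candidates, key=lambda r: (r.p_adj, -r.overlap, r.set_id))
    genes = db[best.set_id].genes
    gene_set = set(genes)
    in_path = snp_table["gene"].isin(gene_set)
    sub = snp_table.loc[in_path]
    return IndexPathway(
        set_id=best.set_id,
        genes=genes,
        snp_ids=list(sub["snp_id"]),
        snp_classes=dict(zip(sub["snp_id"], sub["func_class"])),
    )
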
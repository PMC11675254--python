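"""Gene-list construction, hypergeometric over-representation and
index-pathway selection."""

import itertools
import math

import pandas as pd
import pytest

from pathtrio.enrichment import (
    EnrichmentRow,
    NoIndexPathwayError,
    build_genelist1,
    enrich,
    select_index_pathway,
)
from pathtrio.model import GeneSet, GeneSetDB
from pathtrio.tdt import TdtResult


def result(snp_id, p):
    return TdtResult(snp_id, 1, 1, 0.0, p, 1.0, 2)


def db_from(sets):
    return GeneSetDB(
        sets={
            sid: GeneSet(sid, sid, tuple(genes)) for sid, genes in sets.items()
        }
    )


# -- genelist1 ----------------------------------------------------------


def test_genelist1_filters_on_threshold():
    results = [result("rs1", 0.0005), result("rs2", 0.5)]
    ann = {"rs1": ("geneA", "none"), "rs2": ("geneB", "none")}
    assert build_genelist1(results, ann, 0.001) == ["geneA"]


def test_genelist1_deduplicates_and_drops_unmapped():
    results = [result("rs1", 1e-5), result("rs2", 1e-5), result("rs3", 1e-5)]
    ann = {"rs1": ("geneA", "none"), "rs2": ("geneA", "none"),
           "rs3": (None, "none")}
    assert build_genelist1(results, ann, 0.001) == ["geneA"]


def test_genelist1_matches_brute_force_filter_then_map():
    import numpy as np

    rng = np.random.default_rng(6)
    snps = [f"rs{i}" for i in range(100)]
    genes = [f"g{i % 20}" for i in range(100)]
    ps = rng.uniform(size=100) ** 3
    results = [result(s, p) for s, p in zip(snps, ps)]
    ann = {s: (g, "none") for s, g in zip(snps, genes)}
    expect = sorted(
        {g for s, g, p in zip(snps, genes, ps) if p < 0.01}
    )
    assert build_genelist1(results, ann, 0.01) == expect


def test_genelist1_empty_warns():
    with pytest.warns(UserWarning, match="genelist1 is empty"):
        out = build_genelist1([result("rs1", 0.5)], {"rs1": ("g", "none")}, 0.001)
    assert out == []


# -- hypergeometric enrichment ------------------------------------------


def enrichment_oracle(query, gene_set, universe):
    """P(overlap >= observed) by enumerating every same-size query draw."""
    q = len(query)
    observed = len(set(query) & set(gene_set))
    hits = total = 0
    for draw in itertools.combinations(universe, q):
        total += 1
        if len(set(draw) & set(gene_set)) >= observed:
            hits += 1
    return hits / total


def test_full_overlap_probability_is_one_over_choose():
    universe = [f"g{i}" for i in range(10)]
    db = db_from({"S": universe[:5]})
    rows = enrich(universe[:5], db, universe)
    assert rows[0].p_hyper == pytest.approx(1 / math.comb(10, 5), rel=1e-12)


def test_set_equal_to_universe_is_certain():
    universe = [f"g{i}" for i in range(8)]
    db = db_from({"S": universe})
    rows = enrich(universe[:3], db, universe)
    assert rows[0].p_hyper == pytest.approx(1.0)


def test_zero_overlap_is_certain():
    universe = [f"g{i}" for i in range(10)]
    db = db_from({"S": universe[5:]})
    rows = enrich(universe[:3], db, universe)
    assert rows[0].overlap == 0
    assert rows[0].p_hyper == pytest.approx(1.0)


def test_enrich_matches_exhaustive_enumeration_small_universes():
    import numpy as np

    rng = np.random.default_rng(3)
    for trial in range(6):
        n_uni = int(rng.integers(6, 16))
        universe = [f"g{i}" for i in range(n_uni)]
        set_size = int(rng.integers(1, n_uni + 1))
        gene_set = list(rng.choice(universe, set_size, replace=False))
        q = int(rng.integers(1, n_uni + 1))
        query = list(rng.choice(universe, q, replace=False))
        rows = enrich(query, db_from({"S": gene_set}), universe)
        oracle = enrichment_oracle(query, gene_set, universe)
        assert rows[0].p_hyper == pytest.approx(oracle, rel=1e-12), (
            f"trial {trial}"
        )


def test_enrich_validates_inputs():
    with pytest.raises(ValueError, match="non-empty"):
        enrich([], db_from({"S": ["a"]}), ["a"])
    with pytest.raises(ValueError, match="outside the universe"):
        enrich(["zzz"], db_from({"S": ["a"]}), ["a"])


def test_bh_adjustment_dominates_raw_p():
    import numpy as np

    rng = np.random.default_rng(4)
    universe = [f"g{i}" for i in range(30)]
    sets = {
        f"S{k}": list(rng.choice(universe, 8, replace=False)) for k in range(6)
    }
    query = list(rng.choice(universe, 10, replace=False))
    rows = enrich(query, db_from(sets), universe)
    for r in rows:
        assert r.p_adj >= r.p_hyper - 1e-15
    adj_sorted = [r.p_adj for r in rows]  # rows sorted by p_hyper
    assert adj_sorted == sorted(adj_sorted)


# -- index pathway selection --------------------------------------------


def snp_table(mapping):
    return pd.DataFrame(
        {
            "snp_id": list(mapping),
            "gene": [g for g, _ in mapping.values()],
            "func_class": [c for _, c in mapping.values()],
        }
    )


def test_single_significant_set_selected_with_all_its_snps():
    db = db_from({"S1": ["gA", "gB"], "S2": ["gC"]})
    rows = [
        EnrichmentRow("S1", 2, 2, 2, 10, 0.002, 0.004),
        EnrichmentRow("S2", 1, 0, 2, 10, 1.0, 1.0),
    ]
    table = snp_table(
        {
            "rs1": ("gA", "missense"),
            "rs2": ("gA", "none"),
            "rs3": ("gB", "splice"),
            "rs4": ("gC", "none"),
        }
    )
    index = select_index_pathway(rows, db, table, alpha=0.05)
    assert index.set_id == "S1"
    assert index.genes == ("gA", "gB")
    # all study SNPs in pathway genes, not only sub-threshold ones
    assert index.snp_ids == ["rs1", "rs2", "rs3"]
    assert index.class_counts == {"missense": 1, "splice": 1, "none": 1}


def test_tie_break_larger_overlap_then_set_id():
    db = db_from({"A": ["g1"], "B": ["g1", "g2"]})
    rows = [
        EnrichmentRow("A", 1, 1, 2, 10, 0.01, 0.02),
        EnrichmentRow("B", 2, 2, 2, 10, 0.01, 0.02),
    ]
    table = snp_table({"rs1": ("g1", "none")})
    assert select_index_pathway(rows, db, table).set_id == "B"
    rows[0] = EnrichmentRow("A", 2, 2, 2, 10, 0.01, 0.02)
    assert select_index_pathway(rows, db, table).set_id == "A"


def test_no_set_below_alpha_is_explicit_outcome():
    rows = [EnrichmentRow("S", 2, 1, 2, 10, 0.4, 0.4)]
    with pytest.raises(NoIndexPathwayError):
        select_index_pathway(rows, db_from({"S": ["g"]}), snp_table({}), 0.05)


def test_index_snps_equal_union_of_gene_preimages():
    """Set-logic oracle: snp_ids = union over genelist2 of SNP->gene preimages."""
    import numpy as np

    rng = np.random.default_rng(5)
    genes = [f"g{i}" for i in range(12)]
    mapping = {
        f"rs{i}": (genes[int(rng.integers(12))], "none") for i in range(60)
    }
    pathway_genes = genes[:4]
    db = db_from({"S": pathway_genes})
    rows = [EnrichmentRow("S", 4, 3, 5, 12, 1e-4, 1e-4)]
    index = select_index_pathway(rows, db, snp_table(mapping))
    expect = {s for s, (g, _) in mapping.items() if g in set(pathway_genes)}
    assert set(index.snp_ids) == expect
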
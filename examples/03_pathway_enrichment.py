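"""From TDT results to an index pathway.

Genes with a SNP below p = 0.001 form genelist1; each gene set is tested
for over-representation of genelist1 against the array-bound gene
universe (upper-tail hypergeometric, Benjamini-Hochberg adjusted).  The
best set below alpha = 0.05 becomes the index pathway and contributes all
of its study SNPs to the replication phase.
"""

from pathtrio import (
    SimConfig, build_genelist1, enrich, select_index_pathway,
    simulate_study, tdt_scan,
)
from pathtrio.enrichment import enrichment_frame

sim = simulate_study(
    SimConfig(n_trios=500, n_snps=1000, n_genes=100, n_sets=10,
              tau=0.6, causal_fraction=0.5, seed=1)
)
results = tdt_scan(sim.study)

genelist1 = build_genelist1(results, sim.annotation, p_threshold=0.001)
print(f"genelist1: {len(genelist1)} genes with a SNP at p < 0.001")

universe = sorted({g for g, _ in sim.annotation.values()})
rows = enrich(genelist1, sim.gene_sets, universe)
print(enrichment_frame(rows).head(3).to_string(index=False))

index = select_index_pathway(rows, sim.gene_sets, sim.study.snp_table())
print(f"index pathway: {index.set_id} with {len(index.snp_ids)} SNPs, "
      f"class counts {index.class_counts}")
print(f"injected causal set was {sim.truth.attrs['causal_set_id']}")
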
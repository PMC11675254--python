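import numpy as np
import pandas as pd
import pytest

from pathtrio.model import MISSING, SnpMeta, TrioStudy


def fill_children(G, seed=0):
    """Overwrite each third row with a Mendelian-consistent child genotype."""
    G = np.asarray(G, dtype=np.int8).copy()
    rng = np.random.default_rng(seed)

    def transmit(g):
        if g == 2:
            return 1
        if g == 1:
            return int(rng.integers(2))
        return 0

    for t in range(G.shape[0] // 3):
        f, m = G[3 * t], G[3 * t + 1]
        for j in range(G.shape[1]):
            if f[j] == MISSING or m[j] == MISSING:
                G[3 * t + 2, j] = MISSING
            else:
                G[3 * t + 2, j] = transmit(f[j]) + transmit(m[j])
    return G


def make_study(genotypes, n_snps=None, affected=None, snps=None):
    """Build a study from a genotype matrix whose rows come in F,M,C triples."""
    G = np.asarray(genotypes, dtype=np.int8)
    n_ind, m = G.shape
    assert n_ind % 3 == 0
    n_trios = n_ind // 3
    fam = np.repeat([f"F{i}" for i in range(n_trios)], 3)
    roles = np.tile(["F", "M", "C"], n_trios)
    iid = [f"{f}_{r}" for f, r in zip(fam, roles)]
    samples = pd.DataFrame(
        {
            "family_id": fam,
            "individual_id": iid,
            "father_id": [f + "_F" if r == "C" else "0" for f, r in zip(fam, roles)],
            "mother_id": [f + "_M" if r == "C" else "0" for f, r in zip(fam, roles)],
            "sex": [1 if r == "F" else 2 for r in roles],
            "affection": [2 if r == "C" else 1 for r in roles],
        }
    )
    if snps is None:
        snps = [
            SnpMeta(snp_id=f"rs{j + 1}", pos=1000 * (j + 1)) for j in range(m)
        ]
    return TrioStudy(samples=samples, genotypes=G, snps=snps)


@pytest.fixture
def tiny_trio_study():
    """One trio, two SNPs: father AB, mother AA; child gets B at SNP1 only."""
    return make_study(
        [
            [1, 1],  # father
            [0, 0],  # mother
            [1, 0],  # child
        ]
    )
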
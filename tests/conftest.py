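import numpy as np
import pandas as pd
import pytest

import strainscan as ss
from strainscan.genotypes import GenotypeMatrix, KinshipMatrix


@pytest.fixture(scope="session")
def structured_panel():
    """Default-structure panel: 22 strains, 6 clusters, block LD."""
    cfg = ss.SimConfig(n_snps=300, master_seed=7, traits=("t1", "t2"))
    G = ss.simulate_panel(cfg)
    Gf = ss.filter_informative(G)
    sdps = ss.collapse_sdps(Gf)
    K = ss.kinship_ibs(Gf)
    P = ss.simulate_phenotypes(G, cfg)
    return cfg, G, Gf, sdps, K, P


@pytest.fixture(scope="session")
def flat_panel():
    """No-LD panel: every SNP an independent random pattern."""
    cfg = ss.SimConfig(
        n_snps=500, n_clusters=22, block_len=1, flip_rate=0.0,
        master_seed=11, traits=("t1",),
    )
    G = ss.simulate_panel(cfg)
    Gf = ss.filter_informative(G)
    sdps = ss.collapse_sdps(Gf)
    K = ss.kinship_ibs(Gf)
    P = ss.simulate_phenotypes(G, cfg)
    return cfg, G, Gf, sdps, K, P


def make_genotypes(calls, strains=None, chrom=None, pos=None):
    """Build a GenotypeMatrix from an int array of {0,1,-1} calls."""
    calls = np.asarray(calls, dtype=np.int8)
    m, n = calls.shape
    strains = strains or [f"S{i + 1:02d}" for i in range(n)]
    return GenotypeMatrix(
        strains=strains,
        snp_id=np.array([f"rs{i + 1}" for i in range(m)], dtype=object),
        chrom=np.array(chrom if chrom is not None else ["chr1"] * m, dtype=object),
        pos=np.array(pos if pos is not None else (np.arange(m) + 1) * 1000, dtype=np.int64),
        calls=calls,
        alleles=np.array([["A", "G"]] * m),
    )


def identity_kinship(strains):
    return KinshipMatrix(list(strains), np.eye(len(strains)))


def one_animal_table(strains, y):
    return pd.DataFrame(
        {"animal_id": list(strains), "strain": list(strains),
         "treatment": "ctr", "t": np.asarray(y, float)}
    )
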
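import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
from anndata import AnnData

from dichoscreen import synth
from dichoscreen.screen import Bipartition, ProportionTable

GROUP8 = ["sphenopalatine", "stellate", "coeliac", "lumbar", "P1", "P2", "P3", "P4"]


def make_adata(counts, groups, genes=None, barcodes=None) -> AnnData:
    """Dense count array -> labeled AnnData (cells x genes)."""
    counts = np.asarray(counts)
    n, m = counts.shape
    genes = list(genes) if genes is not None else [f"g{j}" for j in range(m)]
    barcodes = list(barcodes) if barcodes is not None else [f"c{i}" for i in range(n)]
    obs = pd.DataFrame({"group": list(groups)}, index=pd.Index(barcodes, name="barcode"))
    var = pd.DataFrame(index=pd.Index(genes, name="gene"))
    var["mito"] = [g.startswith("mt-") for g in genes]
    return AnnData(X=sp.csr_matrix(counts), obs=obs, var=var)


def random_table(rng, n_genes=20, groups=GROUP8) -> ProportionTable:
    ncells = pd.Series(rng.integers(10, 300, size=len(groups)), index=list(groups))
    num = pd.DataFrame(
        {g: rng.integers(0, ncells[g] + 1, size=n_genes) for g in groups},
        index=[f"g{j}" for j in range(n_genes)],
    )
    return ProportionTable(num, ncells)


@pytest.fixture(scope="session")
def qc_sim():
    """Simulation with all artifact classes planted, shared across QC tests."""
    cfg = synth.default_sim_config(
        n_planted=10,
        n_background_genes=200,
        n_nonneuron_cells=80,
        n_lowquality_droplets=30,
        n_glial_doublets=30,
        seed=11,
        scale=0.05,
    )
    return cfg, synth.generate_counts(cfg)


def split_of(mask: int, groups=GROUP8) -> Bipartition:
    s1 = tuple(g for i, g in enumerate(groups) if mask >> i & 1)
    s2 = tuple(g for i, g in enumerate(groups) if not mask >> i & 1)
    return Bipartition(s1, s2)
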
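import numpy as np
import pandas as pd
import pytest

from seapop import synthgen
from seapop.geno_io import LOCUS_COLUMNS, MISSING, GenotypeMatrix


def make_gm(dosages, sites, chrom=None, depth=None, locus_ids=None):
    """Build a small GenotypeMatrix from a dosage array and site labels."""
    d = np.asarray(dosages, dtype=np.int8)
    n, m = d.shape
    loci = pd.DataFrame(
        {
            "chrom": chrom if chrom is not None else ["chr1"] * m,
            "pos": np.arange(1, m + 1) * 100,
            "locus_id": locus_ids if locus_ids is not None else [f"L{j}" for j in range(m)],
            "ref": "A",
            "alt": "T",
        }
    )[LOCUS_COLUMNS]
    ids = [f"ind{i}" for i in range(n)]
    return GenotypeMatrix(d, ids, np.asarray(sites, dtype=object), loci,
                          None if depth is None else np.asarray(depth))


@pytest.fixture(scope="session")
def two_cluster_dataset():
    """Two well-separated clusters of sites: clean structure for clustering tests."""
    cfg = synthgen.SimulationConfig(
        n_sites=6, n_per_site=20, n_clusters=2, n_neutral_loci=500,
        n_adaptive_loci=0, fst_between_clusters=0.15, fst_within_cluster=0.005,
        missing_rate=0.0, seed=11,
    )
    return synthgen.simulate_seascape(cfg)


@pytest.fixture(scope="session")
def adaptive_dataset():
    """Planted environmental clines at strong effect, for GEA power tests."""
    cfg = synthgen.SimulationConfig(
        n_sites=13, n_per_site=20, n_clusters=1, n_neutral_loci=800,
        n_adaptive_loci=20, fst_between_clusters=0.003, fst_within_cluster=0.003,
        adaptive_effect=2.0, env_n_vars=4, missing_rate=0.0, seed=5,
    )
    return synthgen.simulate_seascape(cfg)
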
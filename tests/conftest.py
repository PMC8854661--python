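import numpy as np
import pandas as pd
import pytest

from popscan.core import GenotypeMatrix
from popscan.simulate import InversionSpec, SimConfig, SweepSpec, simulate_dataset


def make_matrix(genotypes, populations, chrom="chr1", positions=None, missense=None):
    """Hand-rolled GenotypeMatrix from a (variants x samples) list/array."""
    g = np.asarray(genotypes, dtype=np.int8)
    n_var, n_samp = g.shape
    if positions is None:
        positions = np.arange(1, n_var + 1) * 10
    pops = list(populations)
    samples = [f"s{i}" for i in range(n_samp)]
    variants = pd.DataFrame(
        {
            "chrom": [chrom] * n_var,
            "pos": positions,
            "ref": ["A"] * n_var,
            "alt": ["T"] * n_var,
            "missense": missense if missense is not None else [False] * n_var,
        }
    )
    return GenotypeMatrix(
        samples=samples, populations=np.array(pops, dtype=object),
        variants=variants, genotypes=g,
    )


@pytest.fixture(scope="session")
def two_pop_sim():
    """Two equally drifted populations, independent sites: F_ST oracle checks."""
    cfg = SimConfig(
        chromosomes={"chr1": 2_000_000},
        populations={"A": 50, "B": 50},
        drift={"A": 0.15, "B": 0.15},
        snp_density=0.01,
        seed=101,
    )
    gm, truth = simulate_dataset(cfg)
    return cfg, gm, truth


@pytest.fixture(scope="session")
def inversion_sim():
    """Planted 2-Mb inversion (q=0.3), one null chromosome, 60 samples."""
    cfg = SimConfig(
        chromosomes={"chr1": 6_000_000, "chr2": 6_000_000},
        populations={"A": 20, "B": 20, "C": 20},
        drift={"A": 0.15, "B": 0.15, "C": 0.15},
        snp_density=0.0008,
        inversions=[InversionSpec("chr1", 2_000_000, 4_000_000, 0.3, marker_error=0.01)],
        seed=3,
    )
    gm, truth = simulate_dataset(cfg)
    return cfg, gm, truth


# planted-sweep geometry: each 140-kb sweep spans 10 full 50/10-kb windows,
# about two thirds of the per-chromosome top-5% budget (15 of 296 windows),
# so recovery is not confounded by quantile-budget saturation
SWEEP_CHROMS = {"chr1": 3_000_000, "chr2": 3_000_000}
SWEEP_SPECS = [
    SweepSpec("N", "chr1", 800_000, 940_000, 0.9),
    SweepSpec("N", "chr2", 2_200_000, 2_340_000, 0.9),
]


def sweep_config(seed, planted=True):
    return SimConfig(
        chromosomes=dict(SWEEP_CHROMS),
        populations={"N": 15, "R1": 15, "R2": 15},
        drift={"N": 0.15, "R1": 0.15, "R2": 0.15},
        snp_density=0.002,
        sweeps=list(SWEEP_SPECS) if planted else [],
        seed=seed,
    )


@pytest.fixture(scope="session")
def sweep_sim():
    cfg = sweep_config(11, planted=True)
    gm, truth = simulate_dataset(cfg)
    return cfg, gm, truth
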
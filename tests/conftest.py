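import numpy as np
import pandas as pd
import pytest

from vegwas.genotype_qc import GenotypeSet


def make_genotypes(dosages, chrom=None, bp=None, populations=None):
    """GenotypeSet from a raw matrix with auto-generated map/samples."""
    dosages = np.asarray(dosages, dtype=float)
    n, m = dosages.shape
    chrom = ["1"] * m if chrom is None else [str(c) for c in chrom]
    bp = [(j + 1) * 1000 for j in range(m)] if bp is None else list(bp)
    populations = ["base"] * n if populations is None else list(populations)
    return GenotypeSet(
        dosages=dosages,
        snp_map=pd.DataFrame(
            {"snp_id": [f"s{j}" for j in range(m)], "chrom": chrom, "bp": bp}
        ),
        samples=pd.DataFrame(
            {"doe_id": [f"d{i}" for i in range(n)], "population": populations}
        ),
    )


@pytest.fixture
def toy_genotypes():
    rng = np.random.default_rng(42)
    return make_genotypes(rng.integers(0, 3, size=(20, 12)).astype(float))


@pytest.fixture
def litter_table():
    rng = np.random.default_rng(7)
    rows = []
    for d in range(40):
        for p in range(1, int(rng.integers(2, 6)) + 1):
            rows.append(
                {
                    "doe_id": f"doe{d}",
                    "parity": p,
                    "tnb": int(rng.integers(2, 14)),
                    "yearseason": f"ys{rng.integers(3)}",
                    "paritylact": f"pl{rng.integers(3)}",
                    "population": "base",
                }
            )
    return pd.DataFrame(rows)


@pytest.fixture(scope="session")
def vqtl_dataset():
    """One mid-size simulated dataset with a strong planted vQTL, shared by
    the slower association tests."""
    from vegwas.genotype_qc import impute_missing
    from vegwas.phenotype import build_phenotypes
    from vegwas.simulate import CausalVariant, SimConfig, simulate_genotypes, simulate_litters

    cfg = SimConfig(
        n_base=100,
        n_high=100,
        n_low=100,
        n_chrom=2,
        snps_per_chrom=100,
        parity_range=(8, 12),
        causal_vqtl=[CausalVariant("1", 5_000_000, float(np.log(2.2)), 0.5)],
        seed=3,
    )
    gs, truth = simulate_genotypes(cfg)
    pheno = build_phenotypes(simulate_litters(cfg, gs, truth))
    return impute_missing(gs, 1), pheno, truth, cfg
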
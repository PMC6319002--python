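import numpy as np
import pytest

import eqtlcross as eq


@pytest.fixture(scope="session")
def small_panel():
    """One F2 panel (n=300, 3 chromosomes x 100 markers) with GRM machinery."""
    cfg = eq.SimConfig(seed=11, n_f2=300, n_chrom=3, markers_per_chrom=100,
                       n_genes=30)
    geno_raw, counts, phen, truth = eq.simulate_dataset(cfg)
    geno = eq.filter_markers(geno_raw.M.astype(int), geno_raw.map)
    Z = eq.standardize_genotypes(geno.M, geno.p)
    runner = eq.GBLUPRunner(eq.compute_grm(Z))
    runner.set_markers(Z)
    return {"cfg": cfg, "geno_raw": geno_raw, "geno": geno, "Z": Z,
            "runner": runner, "counts": counts, "phen": phen, "truth": truth}


@pytest.fixture(scope="session")
def toy_counts():
    """Small deterministic count matrix with annotation."""
    import pandas as pd
    rng = np.random.default_rng(5)
    counts = rng.poisson(100, size=(40, 6)).astype(np.int64)
    genes = pd.DataFrame({
        "gene": [f"g{i}" for i in range(40)],
        "chrom": ["chr1"] * 40,
        "start": np.arange(1, 41) * 1000,
        "end": np.arange(1, 41) * 1000 + 500,
    })
    return eq.CountMatrix(counts=counts, genes=genes,
                          samples=[f"s{i}" for i in range(6)])
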
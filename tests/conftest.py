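import numpy as np
import pandas as pd
import pytest

from feednet import SimConfig, simulate_genotypes, simulate_traits


@pytest.fixture(scope="session")
def small_genotypes():
    return simulate_genotypes(300, 400, (0.1, 0.5), ld_block_size=4, seed=42,
                              n_chromosomes=5)


@pytest.fixture(scope="session")
def small_population(small_genotypes):
    cfg = SimConfig(
        n_individuals=300,
        n_variants=400,
        n_causal=30,
        n_chromosomes=5,
        seed=42,
    )
    traits, tbv, causal_ids, effects = simulate_traits(small_genotypes, cfg)
    return {
        "genotypes": small_genotypes,
        "traits": traits,
        "tbv": tbv,
        "causal_ids": causal_ids,
        "effects": effects,
        "config": cfg,
    }


@pytest.fixture()
def toy_gwas_results():
    """Six variants x three traits with hand-set p/z.

    Variants v1, v2 pass the key threshold; trait B duplicates the key
    z-scores on those rows (r = 1); trait C is orthogonal (r = 0);
    v5 hits the threshold for B only.
    """
    meta = pd.DataFrame(
        {
            "variant_id": [f"v{i}" for i in range(1, 7)],
            "chrom": "1",
            "pos": np.arange(100, 700, 100),
        }
    )

    def table(z, p):
        df = meta.copy()
        df["z"] = z
        df["p"] = p
        return df

    key = table([3.5, -3.4, 0.1, 0.2, 0.5, -0.1],
                [0.0004, 0.0006, 0.9, 0.8, 0.6, 0.9])
    b = table([3.5, -3.4, 0.3, 0.1, 3.6, 0.0],
              [0.5, 0.5, 0.7, 0.9, 0.0003, 0.99])
    c = table([1.0, 1.0, -0.5, 0.2, 0.1, 0.3],
              [0.3, 0.3, 0.6, 0.8, 0.9, 0.7])
    return {"KEY": key, "B": b, "C": c}
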
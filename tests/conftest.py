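import numpy as np
import pandas as pd
import pytest

from slafbsa.config import SimulationConfig
from slafbsa.simulate import simulate_population


@pytest.fixture(scope="session")
def standard_population():
    """The reference synthetic population: h2=0.29, 2000 progeny."""
    cfg = SimulationConfig(
        n_sires=50,
        dams_per_sire=5,
        progeny_per_dam=8,
        n_loci=20,
        n_causal=2,
        causal_effect_sizes=[0.2, 0.1],
        causal_modes=["additive", "additive"],
        seed=42,
    )
    return simulate_population(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)


def null_depth_table(rng, n_loci=100, depth=50, freqs=None):
    """Biallelic depth table with equal true frequencies in both bulks."""
    if freqs is None:
        freqs = rng.uniform(0.2, 0.8, n_loci)
    df = pd.DataFrame(
        {
            "locus_id": [f"L{i:04d}" for i in range(n_loci)],
            "chrom": "C1",
            "pos": np.arange(1, n_loci + 1),
            "ref": "A",
            "alt": "G",
        }
    )
    for tag in ("H", "L"):
        alt = rng.binomial(depth, freqs)
        df[f"A_{tag}"] = depth - alt
        df[f"C_{tag}"] = 0
        df[f"G_{tag}"] = alt
        df[f"T_{tag}"] = 0
    df["Q"] = 30.0
    return df
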
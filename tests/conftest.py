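import numpy as np
import pandas as pd
import pytest

from epitax import synthdata
from epitax.synthdata import SimConfig, ViewSpec


def small_config(seed=0, n_samples=45, effect=2.0, missing=0.0, n_features=150, k=3):
    """Compact cohort for unit tests: same structure, smaller everything."""
    return SimConfig(
        n_samples=n_samples, k_true=k,
        views=tuple(ViewSpec(v.name, n_features=n_features, effect_size=effect,
                             missing_fraction=missing)
                    for v in synthdata.DEFAULT_VIEWS[:3]),
        seed=seed)


@pytest.fixture(scope="session")
def small_cohort():
    return synthdata.simulate_cohort(small_config())


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def jittered_peak_sets(rng, n_samples=5, n_sites=20, chrom_len=1_000_000):
    """Per-sample peaks jittered around shared sites (site-centered, realistic)."""
    sites = rng.integers(5_000, chrom_len - 5_000, n_sites)
    out = {}
    for s in range(n_samples):
        present = rng.random(n_sites) < 0.7
        centers = sites[present] + rng.integers(-200, 200, present.sum())
        half = rng.integers(100, 400, present.sum())
        out[f"s{s}"] = pd.DataFrame({
            "chrom": "chr1",
            "start": np.maximum(centers - half, 0),
            "end": centers + half,
        })
    return out
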
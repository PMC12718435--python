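import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import diatomcal as dc

settings.register_profile(
    "suite", derandomize=True, max_examples=25, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def benchmark():
    """Default synthetic benchmark: 35 sites, 55 benthic + 19 planktonic taxa."""
    return dc.make_benchmark(dc.SimConfig(seed=1))


def preprocess(bench):
    """Benthic subset -> proportions -> rare filter (renormalised) -> Hellinger."""
    ds = bench.dataset
    rel = dc.relative_abundance(ds.counts.subset_habit("benthic"))
    rel, _ = dc.rare_taxon_filter(rel, renormalize=True)
    hel = dc.hellinger(rel)
    x = ds.env.values["temperature"].to_numpy(dtype=float)
    return rel, hel, x


@pytest.fixture(scope="session")
def bench_matrices(benchmark):
    return preprocess(benchmark)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def random_community(rng, n=12, m=8, gradient=None):
    """Random gradient community as (proportions AbundanceMatrix, x)."""
    x = gradient if gradient is not None else rng.normal(size=n)
    opt = rng.normal(np.mean(x), np.std(x) + 0.5, m)
    mu = np.exp(-((x[:, None] - opt[None, :]) ** 2) / 2.0) + 0.01
    p = mu / mu.sum(axis=1, keepdims=True)
    df = pd.DataFrame(p, index=[f"s{i}" for i in range(n)], columns=[f"t{j}" for j in range(m)])
    return dc.AbundanceMatrix(df, "none"), np.asarray(x, dtype=float)
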
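"""Shared fixtures: miniature simulation configs, random tiny haplotype
matrices, and the (expensive, session-scoped) scaled-down IM benchmark."""

from __future__ import annotations

import numpy as np
import pytest

from demoml.demography import SampleDesign, default_priors, sample_parameters
from demoml.simulate import LocusData, build_reference_table, fixture_config, simulate_dataset
from demoml.sumstats import StatConfig, build_schema


@pytest.fixture(scope="session")
def fixture_setup():
    model, priors, design = fixture_config()
    return model, priors, design


@pytest.fixture(scope="session")
def fixture_loci(fixture_setup):
    model, priors, design = fixture_setup
    draws, _ = sample_parameters(priors, 1, seed=11)
    return simulate_dataset(draws[0], design, seed=11)


def random_tiny_locus(rng, n_per_pop=None, max_sites=8, length=10_000.0) -> LocusData:
    """A random tiny two-population haplotype matrix with valid invariants."""
    n_per_pop = n_per_pop or int(rng.integers(2, 4))
    n = 2 * n_per_pop
    s = int(rng.integers(1, max_sites + 1))
    while True:
        hap = rng.integers(0, 2, size=(n, s)).astype(np.int8)
        counts = hap.sum(axis=0)
        keep = (counts > 0) & (counts < n)
        if keep.any():
            hap = hap[:, keep]
            break
    k = hap.shape[1]
    positions = np.sort(rng.choice(np.arange(1, int(length)), size=k, replace=False)).astype(float)
    return LocusData(
        haplotypes=hap,
        positions=positions,
        pop_labels=np.repeat([0, 1], n_per_pop),
        locus_length=length,
    )


# ---------------------------------------------------------------------------
# scaled-down IM benchmark (shared by the parameter-recovery, clipping and
# interpretability acceptance checks so the simulation cost is paid once)
# ---------------------------------------------------------------------------

BENCH_DESIGN = SampleDesign(
    n_diploid_per_pop=4, n_loci=5, locus_length=500_000,
    recombination_rate=1.0e-8, mutation_rate=1.25e-8,
)
BENCH_SPLIT = (1000, 250, 250)
BENCH_SEED = 2024


@pytest.fixture(scope="session")
def im_benchmark_table():
    """1500 IM simulations (1000 train / 250 validation / 250 test) of
    5 x 500 kb loci with 4 diploids per population."""
    priors = default_priors("IM")
    return build_reference_table(
        "IM", priors, BENCH_DESIGN, sum(BENCH_SPLIT), BENCH_SPLIT, BENCH_SEED,
    )


@pytest.fixture(scope="session")
def im_benchmark_models(im_benchmark_table):
    """One regressor per method per parameter, trained on the benchmark."""
    from demoml.inference import RegressorConfig, fit_standardizer, train_regressor

    table = im_benchmark_table
    priors = default_priors("IM")
    X_train, P_train = table.subset("train")
    X_val, P_val = table.subset("validation")
    std = fit_standardizer(X_train)
    models = {}
    for method in ("RF", "XGB", "MLP"):
        for k, param in enumerate(table.param_names):
            cfg = RegressorConfig(method=method, seed=5)
            models[(param, method)] = train_regressor(
                cfg, X_train, P_train[:, k], X_val, P_val[:, k],
                target=param, prior=priors[param],
                feature_names=table.feature_names, standardizer=std,
            )
    return models
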
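import numpy as np
import pandas as pd
import pytest

from meth3d import synthgen


@pytest.fixture(scope="session")
def suite():
    """The default planted study, shared read-only across tests."""
    return synthgen.design_cohort(seed=0)


@pytest.fixture(scope="session")
def annotation():
    cfg = synthgen.SimulationConfig(seed=3, n_cpgs=2000)
    cpg_ann, gene_ann, fragments = synthgen.simulate_annotation(cfg)
    return cfg, cpg_ann, gene_ann, fragments


def make_null_cohort(seed: int, n_cpgs: int = 2000, **overrides):
    """A cohort with no planted effects and a single batch."""
    cfg = synthgen.SimulationConfig(seed=seed, n_cpgs=n_cpgs, n_batches=1,
                                    **overrides)
    cpg_ann, gene_ann, fragments = synthgen.simulate_annotation(cfg)
    beta, samples, truth = synthgen.simulate_methylation(cfg, cpg_ann)
    return cfg, cpg_ann, beta, samples


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_intervals(rng, n, chroms=("chr1", "chr2"), span=100_000,
                     max_len=500):
    starts = rng.integers(0, span, n)
    lengths = rng.integers(1, max_len, n)
    return pd.DataFrame({
        "chrom": rng.choice(chroms, n),
        "start": starts,
        "end": starts + lengths,
    })
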
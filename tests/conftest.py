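import warnings

import numpy as np
import pandas as pd
import pytest

from rmcseq.de import DesignSpec
from rmcseq.io import CountMatrix, SampleTable
from rmcseq.preprocess import normalize
from rmcseq.simulate import SimulationConfig, simulate_counts

warnings.filterwarnings("ignore", category=UserWarning)


def make_null_config(seed: int, n_genes: int = 2000, n: int = 20) -> SimulationConfig:
    """Null study: no DE, no age drift, one batch, identical age distributions."""
    return SimulationConfig(n_genes=n_genes, n_cases=n, n_controls=n,
                            pi_de=0.0, pi_age=0.0, n_batches=1, seed=seed,
                            case_age_mean=60.0, control_age_mean=60.0)


def expressed_subset(study) -> tuple[CountMatrix, DesignSpec]:
    """Drop all-zero and low-count genes (the classifier's gates) and build
    the two-group design."""
    counts = study.counts
    nm = normalize(counts, "size_factor")
    keep = (counts.counts.sum(axis=1) > 0) & (nm.values.mean(axis=1) >= 10.0)
    sub = counts.subset_genes([g for g, k in zip(counts.gene_ids, keep) if k])
    design = DesignSpec.from_samples(study.samples, counts.sample_ids,
                                     seed=study.config.seed)
    return sub, design


@pytest.fixture(scope="session")
def null_study():
    return simulate_counts(make_null_config(seed=101))


@pytest.fixture(scope="session")
def planted_study():
    """10% DE genes with |log2FC| in [1, 2] on a 20 vs 20 design."""
    cfg = SimulationConfig(n_genes=2000, n_cases=20, n_controls=20,
                           pi_de=0.1, lfc_min=1.0, lfc_max=2.0, pi_age=0.0,
                           seed=202, case_age_mean=60.0, control_age_mean=60.0)
    return simulate_counts(cfg)


@pytest.fixture()
def toy_counts():
    rng = np.random.default_rng(0)
    mat = rng.poisson(50, size=(5, 6))
    return CountMatrix([f"g{i}" for i in range(5)],
                       [f"s{i}" for i in range(6)], mat)


@pytest.fixture()
def aged_samples():
    """146 cases ~ N(58, 11) and 207 controls ~ N(70, 10): the study's
    age-mismatch scenario."""
    rng = np.random.default_rng(7)
    ids = [f"case{i:03d}" for i in range(146)] + [f"ctrl{i:03d}" for i in range(207)]
    return SampleTable(pd.DataFrame({
        "sample_id": ids,
        "condition": ["case"] * 146 + ["control"] * 207,
        "age": np.r_[rng.normal(58, 11, 146), rng.normal(70, 10, 207)],
    }))
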
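import numpy as np
import pytest

from leukorisk import simulate
from leukorisk.datamodel import ExpressionMatrix, SampleMetadata


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_matrix(values, dataset_id="D", cell_type="monocyte", probe_ids=None, sample_ids=None):
    values = np.asarray(values, dtype=float)
    probe_ids = probe_ids or [f"p{i}" for i in range(values.shape[0])]
    sample_ids = sample_ids or [f"s{j}" for j in range(values.shape[1])]
    return ExpressionMatrix(dataset_id, cell_type, tuple(probe_ids), tuple(sample_ids), values)


def make_metadata(n_high, n_low, prefix="s", start=0):
    """n_high heterozygous FH samples followed by n_low controls."""
    records = []
    for i in range(n_high + n_low):
        sid = f"{prefix}{start + i}"
        if i < n_high:
            records.append(SampleMetadata(sid, "high", "heterozygous_FH"))
        else:
            records.append(SampleMetadata(sid, "low", "control"))
    return records


@pytest.fixture(scope="session")
def fh_pair_cohort():
    """One FH1 (monocyte) + FH2 (T cell, same subjects) cohort at defaults."""
    cfg = simulate.CohortConfig(designs=simulate.DEFAULT_DESIGNS[:2], seed=11)
    return simulate.generate_cohort(cfg)


@pytest.fixture(scope="session")
def full_cohort():
    """All four dataset shapes at the default configuration."""
    return simulate.generate_cohort(simulate.CohortConfig(seed=7))
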
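import numpy as np
import pandas as pd
import pytest

from guildlink import AbundanceTable, CohortConfig, SampleMetadata, ValueKind, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """One modest synthetic cohort shared across read-only tests."""
    cfg = CohortConfig(seed=11, n_metabolites=80, n_modules=6,
                       module_size_range=(5, 10), n_species=60, n_cags=6,
                       cag_size_range=(4, 8), n_kos=100, n_qc=3)
    return generate_cohort(cfg)


@pytest.fixture
def tiny_table():
    df = pd.DataFrame(
        [[1.0, 2.0, 3.0, 4.0],
         [4.0, 3.0, 2.0, 1.0],
         [1.0, 1.0, 2.0, 2.0]],
        index=["f1", "f2", "f3"],
        columns=["s1", "s2", "s3", "s4"],
    )
    return AbundanceTable(df, ValueKind.intensity)


@pytest.fixture
def two_group_meta():
    df = pd.DataFrame(
        {"group": ["case", "case", "control", "control"],
         "bin_flag": [1.0, 0.0, 1.0, 0.0],
         "cov_age": [50.0, 60.0, 55.0, 65.0]},
        index=pd.Index(["s1", "s2", "s3", "s4"], name="sample_id"),
    )
    return SampleMetadata(df, binary_indices=["bin_flag"],
                          continuous_indices=["cov_age"])


def biological_metabolome(cohort):
    """Metabolome restricted to biological (non-QC) samples."""
    bio = [s for s in cohort.metabolome.sample_ids
           if s not in set(cohort.qc_sample_ids)]
    return cohort.metabolome.subset_samples(bio)
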
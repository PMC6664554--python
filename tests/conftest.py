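import numpy as np
import pytest

from plasmasig import CohortConfig, generate_cohort, study_like_config
from plasmasig.synthetic import EffectSpec


@pytest.fixture(scope="session")
def study_cohort():
    """A full-size study-like synthetic cohort (343 × 92), shared read-only."""
    return generate_cohort(study_like_config(seed=11))


@pytest.fixture(scope="session")
def small_cohort():
    """A small two-group cohort with three strongly shifted proteins."""
    cfg = CohortConfig(
        group_sizes={"LAC": 40, "benign": 24},
        n_proteins=12,
        effects=(
            EffectSpec("CXCL17", "LAC", 2.0),
            EffectSpec("CEACAM5", "LAC", 2.0),
            EffectSpec("VEGFR2", "LAC", -2.0),
        ),
        seed=5,
    )
    return generate_cohort(cfg)


@pytest.fixture()
def cohort_on_disk(tmp_path, small_cohort):
    """The small cohort written out as TSV files."""
    from plasmasig import write_cohort

    matrix, metadata, panel, _ = small_cohort
    write_cohort(matrix, metadata, panel, tmp_path)
    return tmp_path


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)
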
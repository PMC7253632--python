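import pytest

from nirsmap.features import ChannelLayout
from nirsmap.pipeline import RunConfig, preprocess_stage
from nirsmap.simulate import CohortSpec, NoiseSpec, generate_cohort

FS = 8.138


@pytest.fixture(scope="session")
def layout():
    return ChannelLayout.default_48()


@pytest.fixture(scope="session")
def small_cohort():
    """2 impaired + 1 control, one task, low noise: fast but full-shape."""
    spec = CohortSpec(n_impaired=2, n_control=1, tasks=("n_back",),
                      noise=NoiseSpec.low(), seed=11)
    return generate_cohort(spec)


@pytest.fixture(scope="session")
def small_epochs(small_cohort):
    cfg = RunConfig(cohort=small_cohort.spec)
    return preprocess_stage(cfg, small_cohort)


@pytest.fixture(scope="session")
def strong_cohort():
    """Strong group effect (ratio 0.3), low noise, desk scale (4 + 3)."""
    spec = CohortSpec(n_impaired=4, n_control=3, tasks=("n_back",),
                      amplitude_ratio_impaired=0.3, noise=NoiseSpec.low(), seed=5)
    return generate_cohort(spec)


@pytest.fixture(scope="session")
def strong_epochs(strong_cohort):
    cfg = RunConfig(cohort=strong_cohort.spec)
    return preprocess_stage(cfg, strong_cohort)
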
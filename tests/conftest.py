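import numpy as np
import pytest

from oartx import FixtureConfig, generate_course
from oartx.fixture_mobius import write_directory


@pytest.fixture(scope="session")
def small_cohort():
    """3 patients x 5 fractions with revisions possible; known ground truth."""
    cfg = FixtureConfig(n_patients=3, fractions_per_patient=5, revision_probability=0.3, seed=11)
    return generate_course(cfg)


@pytest.fixture(scope="session")
def minimal_course():
    """1 patient, 1 fraction, no revisions: the smallest complete course."""
    cfg = FixtureConfig(n_patients=1, fractions_per_patient=1, revision_probability=0.0, seed=1)
    return generate_course(cfg)


@pytest.fixture()
def fixture_dir(tmp_path, small_cohort):
    docs, truth = small_cohort
    return write_directory(docs, truth, tmp_path / "src")


def random_truncated_curve(rng: np.random.Generator):
    """A random plausible truncated cumulative-DVH point list (dose, vol%)."""
    n = int(rng.integers(2, 40))
    doses = np.sort(rng.uniform(0.5, 70.0, size=n))
    doses = np.unique(np.round(doses, 3))
    vols = np.sort(rng.uniform(0.01, 99.99, size=doses.size))[::-1]
    return np.column_stack([doses, vols])
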
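import sys
from pathlib import Path

import pytest
from hypothesis import settings

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

settings.register_profile("ci", derandomize=True, deadline=None)
settings.load_profile("ci")

from ordvert.data_io import export_cohort, read_manifest
from ordvert.synthetic_data import SyntheticConfig, generate_cohort


def random_prob_vector(rng, n):
    """Dirichlet-ish random point on the probability simplex."""
    x = rng.exponential(size=n)
    return x / x.sum()


@pytest.fixture(scope="session")
def small_cohort():
    """Tiny cohort for structural tests: 6 patients, 3 levels, 16x16."""
    cfg = SyntheticConfig(
        n_patients=6, n_levels=3, slices_per_level_range=(2, 3),
        image_size=(16, 16), seed=7,
    )
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def exported_dataset(small_cohort, tmp_path_factory):
    root = tmp_path_factory.mktemp("cohort")
    manifest = export_cohort(small_cohort, root)
    return read_manifest(root / "manifest.csv")
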
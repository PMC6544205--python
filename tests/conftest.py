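import matplotlib

matplotlib.use("Agg")

import pytest

from ukbkit import build_dataset
from ukbkit.fixtures import default_fileset_spec, generate_fileset


@pytest.fixture(scope="session")
def fileset(tmp_path_factory):
    """A generated demo fileset: (directory, spec, paths, ground truth)."""
    d = tmp_path_factory.mktemp("fileset")
    spec = default_fileset_spec(100, seed=11)
    paths, truth = generate_fileset(spec, d)
    return d, spec, paths, truth


@pytest.fixture(scope="session")
def dataset(fileset):
    """The assembled dataset for the session fileset."""
    d, spec, _, _ = fileset
    return build_dataset(spec.stem, d)
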
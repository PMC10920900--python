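import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from splicefate.fixtures import FixtureSpec, generate_cohort, generate_toy_gene


@pytest.fixture(scope="session")
def spec():
    return FixtureSpec(seed=11, n_genes=4, n_patients=10, mutations_per_patient=4)


@pytest.fixture(scope="session")
def toys(spec):
    return [generate_toy_gene(spec, i) for i in range(spec.n_genes)]


@pytest.fixture(scope="session")
def cohort(spec, toys):
    variants, truth = generate_cohort(spec, toys)
    return variants, truth


@pytest.fixture(scope="session")
def conservation(toys):
    return {
        t.gene.gene_id: {
            tid: df["rate"].to_numpy(dtype=float)
            for tid, df in t.conservation.items()
        }
        for t in toys
    }


@pytest.fixture(scope="session")
def fixture_dir(spec, tmp_path_factory):
    from splicefate.fixtures import write_fixtures

    out = tmp_path_factory.mktemp("fixtures")
    paths = write_fixtures(spec, str(out))
    return paths
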
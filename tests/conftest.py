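import numpy as np
import pytest

from morphosca.atlas import RegionAtlas, load_atlas
from morphosca.data import ConfoundTable, MorphometryTable


@pytest.fixture(scope="session")
def default_atlas():
    return load_atlas()


@pytest.fixture
def tiny_atlas():
    """Five-region cortical atlas for small hand-checkable cases."""
    names = tuple(f"r{i}" for i in range(5))
    return RegionAtlas(names, ("midline",) * 5, ("cortical",) * 5)


def make_table(values, group="HC", measure="CT", prefix="s"):
    values = np.asarray(values, dtype=float)
    ids = tuple(f"{prefix}{i:02d}" for i in range(values.shape[0]))
    return MorphometryTable(group, measure, values, ids)


def make_confounds(n, rng=None, prefix="s"):
    rng = rng or np.random.default_rng(0)
    ids = tuple(f"{prefix}{i:02d}" for i in range(n))
    return ConfoundTable(
        ids,
        age=rng.uniform(50, 85, n),
        gender=(np.arange(n) % 2).astype(float),  # always both levels present
        total_gm_volume=rng.normal(6e5, 5e4, n),
    )


@pytest.fixture
def table_factory():
    return make_table


@pytest.fixture
def confound_factory():
    return make_confounds
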
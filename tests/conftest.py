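import pytest

import ickkit as ik


@pytest.fixture(scope="session")
def catalog():
    return ik.load_default_catalog()


@pytest.fixture(scope="session")
def schema():
    return ik.load_default_schema()


@pytest.fixture(scope="session")
def small_dataset():
    """Three evolved ICK families plus five decoys, fixed seed."""
    return ik.generate_dataset(
        ik.GeneratorConfig(seed=2023, n_families=3, n_decoys=5)
    )


def dataset_hits(ds):
    """Homology hits as the screen module expects them."""
    return [
        ik.HomologyHit(sid, "knottin_ref", ev) for sid, ev in ds.hits_evalue.items()
    ]
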
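import pytest

from chromarch.synthetic_data import (SyntheticWorldConfig, generate_world,
                                      write_world)


@pytest.fixture(scope="session")
def small_config():
    return SyntheticWorldConfig(seed=7, n_chroms=2, chrom_length=115_000,
                                n_genes=100)


@pytest.fixture(scope="session")
def small_world(small_config):
    return generate_world(small_config)


@pytest.fixture(scope="session")
def world_dir(tmp_path_factory, small_world):
    d = tmp_path_factory.mktemp("world")
    write_world(small_world, d)
    return d
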
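import dataclasses

import pytest

from sharkcpue.config import default_config
from sharkcpue.synthetic import simulate_program


@pytest.fixture(scope="session")
def small_config():
    """Two regions x two beaches over twenty years: quick but structured."""
    cfg = default_config(seed=11)
    regions = []
    for region in cfg.regions[:2]:
        beaches = tuple(
            dataclasses.replace(b, installed=min(b.installed, 1978))
            for b in region.beaches[:2]
        )
        regions.append(dataclasses.replace(region, beaches=beaches))
    cfg = dataclasses.replace(cfg, years=(1962, 1981),
                              regions=tuple(regions))
    cfg.validate()
    return cfg


@pytest.fixture(scope="session")
def small_program(small_config):
    catch, effort = simulate_program(small_config)
    return catch, effort
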
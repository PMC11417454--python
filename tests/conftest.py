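import logging

import pytest
from hypothesis import settings

from antioxdb import build_database, default_registry
from antioxdb import simulate

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")

# recipe missing-ingredient warnings are expected on sparse synthetic builds
logging.getLogger("antioxdb.construction").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def registry():
    return default_registry()


@pytest.fixture(scope="session")
def tiny_world(registry):
    """Small end-to-end fixture: sources, built table + ledger, VCEAC, design."""
    config = simulate.canned_config("tiny", seed=20240)
    sources = simulate.gen_sources(config, registry)
    table, ledger = build_database(
        sources.foods,
        sources.sources,
        recipes=sources.recipes,
        mw_table=sources.mw_table,
        registry=registry,
    )
    vceac = simulate.gen_vceac(registry, seed=20240)
    design = simulate.gen_design(config, sources.foods)
    return {
        "config": config,
        "sources": sources,
        "table": table,
        "ledger": ledger,
        "vceac": vceac,
        "design": design,
    }
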
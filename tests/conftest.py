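import warnings

import pytest

from rbpath.simulate import (
    SyntheticConfig,
    generate_clinical_expression,
    generate_isogenic_experiment,
    generate_pancancer,
)

# generator warnings (dropped decoys etc.) are expected in recovery fixtures
warnings.filterwarnings("ignore", category=UserWarning)


@pytest.fixture(scope="session")
def default_config():
    return SyntheticConfig(seed=11)


@pytest.fixture(scope="session")
def pancancer(default_config):
    """Default synthetic pan-cancer bundles plus planted truth (shared)."""
    return generate_pancancer(default_config)


@pytest.fixture(scope="session")
def isogenic(default_config):
    return generate_isogenic_experiment(default_config)


@pytest.fixture(scope="session")
def clinical_expr(default_config):
    return generate_clinical_expression(default_config)


@pytest.fixture(scope="session")
def derived_signature(default_config, isogenic, clinical_expr):
    """Full derivation chain: CPM -> repression -> RB dependency -> prune."""
    from rbpath import signature as sg

    counts, itruth = isogenic
    cpm = sg.cpm_normalize(counts)
    cols = itruth["columns"]
    parental = sg.repressed_genes(cpm, cols["parental_drug"], cols["parental_vehicle"])
    ko_de = sg.differential_expression(cpm, cols["rb1_null_drug"], cols["rb1_null_vehicle"])
    seed_genes = sg.rb_dependency_filter(parental.index, ko_de)
    return sg.correlation_prune(seed_genes, clinical_expr)
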
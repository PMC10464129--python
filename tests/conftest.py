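import warnings

import pytest

from depscreen.synthetic import SyntheticConfig, generate_bundle


@pytest.fixture(scope="session")
def small_config() -> SyntheticConfig:
    return SyntheticConfig(
        n_cell_lines=120,
        n_genes=200,
        mechanism_counts={
            "genetic_driver": 4,
            "expression_addiction": 4,
            "paralog": 4,
            "cyclops": 4,
        },
        n_modules=2,
        module_size=5,
        n_drugs=12,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_bundle(small_config):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return generate_bundle(small_config)
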
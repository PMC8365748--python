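import pytest

from prisafe import (
    DoseContext,
    FixtureSpec,
    generate_example_inventory,
)


@pytest.fixture(scope="session")
def example_dataset():
    """Worked-example dataset: 105-PRI inventory, toxicity map, LOD
    measurements for the flagged impurities, and dose context."""
    return generate_example_inventory(FixtureSpec(seed=0))


@pytest.fixture()
def ctx():
    """Plain dose context: 500 mg dose at 50 mg/ml, 50 kg adult, default
    modifying factors (F2 = 10, others 1)."""
    return DoseContext(product_dose=500.0, product_protein_concentration=50.0)
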
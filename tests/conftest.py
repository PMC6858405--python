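import dendropy
import pytest

from bacrate import simulate


@pytest.fixture(scope="session")
def reference_data():
    """Engineered synthetic benchmark dataset (seeded, deterministic)."""
    return simulate.reference_dataset(seed=1)


@pytest.fixture()
def two_tip_tree():
    return dendropy.Tree.get(data="(A:1.0,B:1.0);", schema="newick")


@pytest.fixture()
def balanced_four_tip_tree():
    return dendropy.Tree.get(
        data="((A:1.0,B:1.0):1.0,(C:1.0,D:1.0):1.0);", schema="newick"
    )


@pytest.fixture(scope="session")
def yule_tree_100():
    return simulate.simulate_tree(100, birth_rate=1.0, seed=42)
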
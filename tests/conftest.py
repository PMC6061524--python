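import pytest

from phylomoves import toolbox
from phylomoves.netcore import RootedNetwork


@pytest.fixture(scope="session")
def named():
    return toolbox.fixtures()


@pytest.fixture(scope="session")
def tier_2_1():
    return toolbox.enumerate_tier(2, 1)


@pytest.fixture(scope="session")
def tier_3_1():
    return toolbox.enumerate_tier(3, 1)


@pytest.fixture(scope="session")
def tier_2_2():
    return toolbox.enumerate_tier(2, 2)


@pytest.fixture(scope="session")
def tier_1_2():
    return toolbox.enumerate_tier(1, 2)


@pytest.fixture()
def cherry_xy():
    """((x,y)); — cherry with the conventional outdegree-1 root."""
    return RootedNetwork(
        [("rho", "a"), ("a", "x"), ("a", "y")], {"x": "x", "y": "y"}
    )


@pytest.fixture()
def tree_xy_z():
    """((x,y),z) as a rooted binary tree."""
    return RootedNetwork(
        [("rho", "b"), ("b", "a"), ("b", "z"), ("a", "x"), ("a", "y")],
        {"x": "x", "y": "y", "z": "z"},
    )


@pytest.fixture()
def tree_xz_y():
    return RootedNetwork(
        [("rho", "b"), ("b", "a"), ("b", "y"), ("a", "x"), ("a", "z")],
        {"x": "x", "y": "y", "z": "z"},
    )


@pytest.fixture()
def double_diamond():
    """Tier (2,2) network whose leaves have two incomparable LCAs."""
    return RootedNetwork(
        [
            ("rho", "s"),
            ("s", "b"),
            ("s", "c"),
            ("b", "r1"),
            ("b", "r2"),
            ("c", "r1"),
            ("c", "r2"),
            ("r1", "x"),
            ("r2", "y"),
        ],
        {"x": "x", "y": "y"},
    )
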
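import numpy as np
import pytest

from phylomorph import mk, simulate
from phylomorph.tree import read_newick


@pytest.fixture
def three_tip_tree():
    return read_newick("((A:1,B:1):1,C:2):0;")


@pytest.fixture
def balanced_tree():
    return read_newick("((A:1,B:1):1,(C:0.5,D:0.5):1.5):0;")


@pytest.fixture
def q3():
    return mk.QMatrix(
        ("x", "y", "z"),
        np.array([[0, 0.3, 0.2], [0.1, 0, 0.4], [0.25, 0.15, 0]]),
    )


@pytest.fixture
def foot_template():
    return simulate.foot_template()
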
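import numpy as np
import pandas as pd
import pytest

import phylostruct as ps


@pytest.fixture(scope="session")
def worked_tree():
    """The 3-tip worked example: ((A:1,B:1):1,C:2);"""
    return ps.parse_newick("((A:1,B:1):1,C:2);")


@pytest.fixture(scope="session")
def worked_dist(worked_tree):
    return ps.patristic_matrix(worked_tree)


@pytest.fixture(scope="session")
def pool20():
    """A 20-tip dated Yule pool shared across oracle tests."""
    return ps.simulate_yule_tree(20, seed=11)


@pytest.fixture(scope="session")
def pool20_dist(pool20):
    return ps.patristic_matrix(pool20)


@pytest.fixture(scope="session")
def caatinga():
    """Published 13-site summary (coordinates, substrate, NRI/NTI)."""
    return ps.caatinga_site_table()
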
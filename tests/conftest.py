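import numpy as np
import pytest

import airwaykit as ak


@pytest.fixture(scope="session")
def small_tree():
    return ak.make_bifurcating_tree(ak.TreeSpec(generations=3, seed=1))


@pytest.fixture(scope="session")
def stenosed_tree():
    tree = ak.make_bifurcating_tree(ak.TreeSpec(generations=3, seed=1))
    skel, ann = ak.insert_stenosis(tree, tree.root.id, center_mm=30.0,
                                   length_mm=20.0, severity=0.5)
    return skel, ann


@pytest.fixture(scope="session")
def training_fit():
    return ak.fit_ols(ak.TRAINING_RECORDS)


@pytest.fixture
def straight_branch():
    pts = [ak.SkeletonPoint(np.array([0.0, 0.0, z]), 2.0)
           for z in np.linspace(0.0, 20.0, 11)]
    return ak.Branch("b0", None, pts)


def straight_tube_skeleton(radius: float, length: float, n: int = 11) -> ak.Skeleton:
    pts = [ak.SkeletonPoint(np.array([0.0, 0.0, z]), radius)
           for z in np.linspace(0.0, length, n)]
    return ak.Skeleton([ak.Branch("tube", None, pts)])
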
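import numpy as np
import pytest

import phylotraits as pt


@pytest.fixture
def cherry3():
    """((A:1,B:1):1,C:2); — the canonical 5-node worked tree."""
    return pt.read_newick("((A:1,B:1):1,C:2);")


@pytest.fixture
def star3():
    return pt.read_newick("(A:1,B:1,C:1);")


@pytest.fixture
def balanced4():
    return pt.read_newick("((A:1,B:1):1,(C:1,D:1):1);")


@pytest.fixture
def five_tip():
    return pt.read_newick("(((A:0.3,B:0.3):0.4,C:0.7):0.3,(D:0.5,E:0.5):0.5);")


@pytest.fixture(scope="session")
def yule50():
    return pt.yule_tree(50, seed=42)


def random_tree_and_painting(rng, max_tips=8):
    """Random small Yule tree with a random era painting (0-2 shifts)."""
    n = int(rng.integers(4, max_tips + 1))
    tree = pt.yule_tree(n, seed=int(rng.integers(2 ** 31)))
    n_shift = int(rng.integers(0, 3))
    edges = rng.choice(np.arange(1, tree.n_nodes),
                       size=min(n_shift, tree.n_nodes - 1), replace=False)
    painting = pt.shift_branches_to_era_map(tree, edges.tolist())
    return tree, painting


def random_spec(rng, family, labels):
    """Random-but-sane parameters for a family over given regime labels."""
    def draw(lo, hi, per_regime):
        if per_regime:
            return {l: float(rng.uniform(lo, hi)) for l in labels}
        return float(rng.uniform(lo, hi))

    if family == "BM1":
        return pt.ModelSpec("BM1", draw(0.2, 3.0, False),
                            x0=float(rng.normal()))
    if family == "BMS":
        return pt.ModelSpec("BMS", draw(0.2, 3.0, True),
                            x0=float(rng.normal()))
    if family == "ACDC":
        return pt.ModelSpec("ACDC", draw(0.2, 3.0, False),
                            r=float(rng.uniform(-3, 3)),
                            x0=float(rng.normal()))
    per = {"OU1": (False, False), "OUM": (False, False),
           "OUMV": (True, False), "OUMA": (False, True),
           "OUMVA": (True, True)}[family]
    theta = {l: float(rng.normal(0, 2)) for l in labels} \
        if family != "OU1" else float(rng.normal(0, 2))
    return pt.ModelSpec(family, draw(0.2, 3.0, per[0]),
                        alpha=draw(0.2, 5.0, per[1]), theta=theta)
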
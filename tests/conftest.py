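import numpy as np
import pytest

from fbdsky.tree import FBDNode, FBDTree, FossilInfo


@pytest.fixture
def rng():
    return np.random.default_rng(20250901)


def two_tip_tree(x1, labels=("A", "B")):
    a = FBDNode(0.0, labels[0])
    b = FBDNode(0.0, labels[1])
    return FBDTree(FBDNode(x1, children=[a, b]))


def tree_with_fossil_tip(x1, bif_age, fossil_age, fossil_bounds=None):
    """((A, F:tip) at bif_age, B) rooted at x1."""
    lower, upper = fossil_bounds or (None, None)
    a = FBDNode(0.0, "A")
    b = FBDNode(0.0, "B")
    f = FBDNode(fossil_age, "F",
                fossil=FossilInfo("psi", age_lower=lower, age_upper=upper))
    return FBDTree(FBDNode(x1, children=[FBDNode(bif_age, children=[a, f]), b]))


def tree_with_sampled_ancestor(x1, fossil_age, fossil_bounds=None):
    """F as a sampled ancestor on A's lineage; B the other crown child."""
    lower, upper = fossil_bounds or (None, None)
    a = FBDNode(0.0, "A")
    b = FBDNode(0.0, "B")
    f = FBDNode(fossil_age, "F",
                fossil=FossilInfo("psi", age_lower=lower, age_upper=upper))
    att = FBDNode(fossil_age, children=[a, f])
    return FBDTree(FBDNode(x1, children=[att, b]))


def four_tip_mixed_tree():
    """Four samples: two extant, one fossil tip, one sampled ancestor.

    Topology (ages in parentheses):
        root(9)
        ├── n1(6)
        │   ├── att(4)  <- sampled ancestor F2 at age 4 on C's lineage
        │   │   ├── C(0)
        │   │   └── F2(4, zero-length)
        │   └── F1(2.5) fossil tip hanging from n1 via bif at 6? no:
        └── D(0)
    Concretely: root(9){ n1(6){ att(4){C, F2}, F1(2.5) }, D(0) }.
    """
    c = FBDNode(0.0, "C")
    d = FBDNode(0.0, "D")
    f1 = FBDNode(2.5, "F1", fossil=FossilInfo("psi"))
    f2 = FBDNode(4.0, "F2", fossil=FossilInfo("psi"))
    att = FBDNode(4.0, children=[c, f2])
    n1 = FBDNode(6.0, children=[att, f1])
    return FBDTree(FBDNode(9.0, children=[n1, d]))


# ---------------------------------------------------------------------------
# Independent closed-form birth-death oracles (complete sampling, no fossils)
# ---------------------------------------------------------------------------

def classic_p0(t, lam, mu, rho=1.0):
    """Probability that a lineage at age t leaves no sampled extant tip."""
    net = lam - mu
    denom = rho * lam + (lam * (1 - rho) - mu) * np.exp(-net * t)
    return 1.0 - rho * net / denom


def classic_p1(t, lam, mu):
    """Density factor for a lineage with exactly one sampled-through path
    (complete sampling)."""
    net = lam - mu
    e = np.exp(-net * t)
    return net ** 2 * e / (lam - mu * e) ** 2


def classic_crown_log_density(branching_ages, x1, lam, mu):
    """Oriented crown-conditioned birth-death density, complete sampling."""
    terms = sum(np.log(lam) + np.log(classic_p1(x, lam, mu))
                for x in branching_ages)
    return (terms + 2 * np.log(classic_p1(x1, lam, mu))
            - 2 * np.log(1 - classic_p0(x1, lam, mu)))
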
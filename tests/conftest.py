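import numpy as np
import pytest

import stratcong as sc


@pytest.fixture
def ages4() -> sc.FOTable:
    """Four-taxon FO table: span 6, Gmin=6, Gmax=11."""
    return sc.FOTable.from_ages({"A": 10, "B": 4, "C": 6, "D": 9})


@pytest.fixture
def t_bad() -> sc.Cladogram:
    """Worst-fit topology for ages4: the oldest taxon is nested deepest (MIG=11)."""
    return sc.parse_newick("(((A,B),C),D);")


@pytest.fixture
def t_good() -> sc.Cladogram:
    """Best-fit ladder for ages4: FO order matches branching order (MIG=6)."""
    return sc.parse_newick("(A,(D,(C,B)));")


@pytest.fixture
def t_mid() -> sc.Cladogram:
    """Intermediate-fit balanced topology for ages4 (MIG=7)."""
    return sc.parse_newick("((A,D),(C,B));")


def random_binary_tree(rng: np.random.Generator, labels: list[str]) -> sc.Cladogram:
    """Random binary topology by successive random joins of subtrees."""
    from stratcong.trees import Node

    pool = [Node(x) for x in labels]
    while len(pool) > 1:
        i, j = rng.choice(len(pool), size=2, replace=False)
        a, b = pool[i], pool[j]
        parent = Node()
        parent.add_child(a)
        parent.add_child(b)
        pool = [n for k, n in enumerate(pool) if k not in (i, j)] + [parent]
    return sc.Cladogram(pool[0])


def random_fo_table(rng: np.random.Generator, labels: list[str],
                    max_age: int = 20) -> sc.FOTable:
    ages = rng.integers(0, max_age + 1, size=len(labels)).astype(float)
    return sc.FOTable.from_ages(dict(zip(labels, ages)))
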
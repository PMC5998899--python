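import numpy as np
import pytest

import misscoal as mc


@pytest.fixture
def quartet_rooted():
    t = mc.parse_newick("((a:1,b:1):1,(c:1,d:1):1);")
    t.is_rooted = True
    return t


@pytest.fixture
def quartet_unrooted():
    return mc.parse_newick("(a,b,(c,d));")


@pytest.fixture
def six_taxon_tall():
    """Low-ILS 6-taxon species tree: gene trees match it almost surely
    (per-branch discordance probability (2/3) e^-3 ~ 0.03)."""
    return mc.caterpillar_species_tree(6, internal=3.0)


def random_unrooted_tree(n, seed, lengths=None):
    """Random binary unrooted topology on n labeled leaves."""
    rng = np.random.default_rng(seed)
    labels = [f"x{i}" for i in range(n)]
    from misscoal._combinatorics import tree_from_nested

    nested = labels[1]
    pool = labels[2:]
    rng.shuffle(pool)
    for leaf in pool:
        # insert at a uniformly chosen position by rebuilding
        positions = []

        def count(node):
            positions.append(node)
            if isinstance(node, tuple):
                count(node[0])
                count(node[1])

        count(nested)
        target = positions[rng.integers(len(positions))]

        def insert(node):
            if node is target:
                return (node, leaf)
            if isinstance(node, tuple):
                return (insert(node[0]), insert(node[1]))
            return node

        nested = insert(nested)
    return tree_from_nested(labels[0], nested, lengths=lengths)
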
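import numpy as np
import pytest

import phyloldg as pl


@pytest.fixture(scope="session")
def default_dataset():
    """One synthetic dataset under the default PNC construction."""
    return pl.simulate_dataset(pl.SimConfig(seed=7))


@pytest.fixture(scope="session")
def default_summary(default_dataset):
    return pl.reserve_summaries(default_dataset)


def random_tuple_tree(rng: np.random.Generator, n_tips: int):
    """Random rooted tree as nested tuples of string labels (polytomies allowed)."""
    nodes = [f"T{i}" for i in range(n_tips)]
    while len(nodes) > 1:
        k = int(rng.integers(2, min(4, len(nodes)) + 1))
        idx = rng.choice(len(nodes), size=k, replace=False)
        children = tuple(nodes[i] for i in sorted(idx, reverse=True))
        for i in sorted(idx, reverse=True):
            del nodes[i]
        nodes.append(children)
    return nodes[0]


def tuple_tree_to_newick(node) -> str:
    def render(nd):
        if isinstance(nd, str):
            return nd
        return "(" + ",".join(render(c) for c in nd) + ")"
    return render(node) + ";"


def tuple_tree_depths(node, depth=0, out=None):
    """Independent oracle: root-inclusive internal-node count per tip.

    A tip at nesting depth d sits below d internal nodes (the root is the
    outermost tuple), so RD = d.
    """
    if out is None:
        out = {}
    if isinstance(node, str):
        out[node] = depth
        return out
    for child in node:
        tuple_tree_depths(child, depth + 1, out)
    return out
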
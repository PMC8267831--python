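import numpy as np
import pytest

from taxoresolve.synthetic import SimulationConfig, generate_dataset
from taxoresolve.tree import LabeledTree, TreeNode


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(n_tips=20, n_genes=8, gene_length_codons=120,
                            seed=101)


@pytest.fixture(scope="session")
def small_dataset(small_config):
    """Records, truth tree, truth table, traits, ledger (clean data)."""
    return generate_dataset(small_config)


def random_binary_tree(rng: np.random.Generator, names,
                       min_len=0.05, max_len=0.5) -> LabeledTree:
    """A random rooted binary tree with uniform branch lengths."""
    nodes = [TreeNode(name=n, length=float(rng.uniform(min_len, max_len)))
             for n in names]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        parent = TreeNode(length=float(rng.uniform(min_len, max_len)),
                          children=[a, b])
        nodes.append(parent)
    nodes[0].length = None
    return LabeledTree(nodes[0])


def enumerate_rooted_trees(names):
    """All rooted binary topologies over the given tip names."""
    names = list(names)
    if len(names) == 1:
        yield TreeNode(name=names[0])
        return
    first, rest = names[0], names[1:]
    for sub in enumerate_rooted_trees(rest):
        for target in _iter_edges(sub):
            yield _attach_copy(sub, target, first)


def _iter_edges(root):
    yield root
    stack = list(root.children)
    while stack:
        node = stack.pop()
        yield node
        stack.extend(node.children)


def _attach_copy(root, target, new_name):
    mapping = {}

    def clone(node):
        new = TreeNode(node.name, node.length, node.support,
                       [clone(c) for c in node.children])
        mapping[id(node)] = new
        return new

    new_root = clone(root)
    tgt = mapping[id(target)]
    moved = TreeNode(tgt.name, 1.0, None, tgt.children)
    tgt.name = None
    tgt.children = [moved, TreeNode(name=new_name, length=1.0)]
    if new_root is tgt:
        pass
    return new_root
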
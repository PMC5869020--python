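import numpy as np
import pytest

from arborkit import ArborSkeleton, SkeletonNode


def make_skeleton(rows, **kwargs):
    """Build a skeleton from (id, x, y, z, parent[, label]) tuples."""
    nodes = []
    for row in rows:
        nid, x, y, z, parent = row[:5]
        label = row[5] if len(row) > 5 else "unspecified"
        nodes.append(SkeletonNode(id=nid, position=np.array([x, y, z], float),
                                  parent_id=parent, structure_label=label))
    return ArborSkeleton(nodes, **kwargs)


def random_tree(n_nodes, seed, scale=10.0):
    """Random rooted tree: each node's parent is a uniformly chosen
    predecessor; positions uniform in a cube of the given scale."""
    rng = np.random.default_rng(seed)
    nodes = [SkeletonNode(id=1, position=rng.uniform(0, scale, 3))]
    for i in range(2, n_nodes + 1):
        parent = int(rng.integers(1, i))
        nodes.append(SkeletonNode(id=i, position=rng.uniform(0, scale, 3),
                                  parent_id=parent))
    return ArborSkeleton(nodes)


@pytest.fixture
def y_skeleton():
    """Root -> stem (10 µm) -> fork -> two arms of sqrt(200) µm each."""
    return make_skeleton([
        (1, 0, 0, 0, -1),
        (2, 10, 0, 0, 1),
        (3, 20, 10, 0, 2),
        (4, 20, -10, 0, 2),
    ])


@pytest.fixture
def path_skeleton():
    return make_skeleton([(1, 0, 0, 0, -1), (2, 3, 0, 0, 1), (3, 6, 0, 0, 2)])
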
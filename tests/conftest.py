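import json

import numpy as np
import pytest

import flexatlas as fa
from flexatlas.synth import ToyAtlasSpec, make_toy_atlas


def plain_tree(node):
    """Helper: build plain-dialect ontology JSON from a nested tuple
    (id, acronym, [children])."""
    nid, acr, children = node
    return {
        "id": nid,
        "name": f"name of {acr}",
        "acronym": acr,
        "children": [plain_tree(c) for c in children],
    }


@pytest.fixture
def tiny_tree_json():
    """root(1) -> A(2) -> {a1(3), a2(4)}, B(5)."""
    tree = (1, "root", [(2, "A", [(3, "a1", []), (4, "a2", [])]), (5, "B", [])])
    return json.dumps(plain_tree(tree))


@pytest.fixture
def branch_tree():
    """root with grey/{A,B}, fiber tracts/{f1}, VS/{v1} branches."""
    tree = (
        1,
        "root",
        [
            (2, "grey", [(3, "A", []), (4, "B", [])]),
            (5, "fiber tracts", [(6, "f1", [])]),
            (7, "VS", [(8, "v1", [])]),
        ],
    )
    return fa.load_ontology(json.dumps(plain_tree(tree)))


@pytest.fixture
def toy_atlas():
    """Deterministic toy atlas with 2 destructive leaves + 1 destructive inner."""
    return make_toy_atlas(ToyAtlasSpec(seed=42))


@pytest.fixture
def toy_base(toy_atlas):
    onto, vol, truth = toy_atlas
    return fa.build_faa_base(onto, vol)


def enlarge_leaf(faa, label, n_extra, seed=0):
    """Give a leaf more voxels (into background) so histograms have samples."""
    rng = np.random.default_rng(seed)
    data = faa.volume.data.copy()
    free = np.argwhere(data == 0)
    assert len(free) >= n_extra
    pick = free[rng.choice(len(free), size=n_extra, replace=False)]
    data[tuple(pick.T)] = label
    faa.volume = faa.volume.with_data(data)
    from flexatlas.base import append_sizes

    append_sizes(faa.ontology, fa.label_sizes(faa.volume))
    fa.validate_faa(faa)
    return faa
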
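"""Combining subtrees and producing double-sided atlases.

Combining collapses an inner node's entire subtree into a single leaf:
all voxels of its descendant leaves are relabeled to the node's own id.
The all-or-none rule (either the whole subtree or nothing) is what keeps
the anatomical hierarchy intact — partial sibling merges are not
expressible.

Double-siding assigns distinct ids to homotopic left/right structures:
the single-sided tree is renumbered 1..N in depth-first pre-order, the
right-hemisphere copy gets ``id + N``, and a new root (id 2N+1) holds the
``root_L``/``root_R`` twins.  Voxels take the left or right id according
to hemisphere masks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .base import FAA, append_sizes, validate_faa
from .errors import CombineSpecError
from .ontology import AnnotationOntology, OntologyNode
from .volume import hemisphere_masks, label_sizes

__all__ = [
    "CombineSpec",
    "SideMap",
    "parse_combine_spec",
    "combine_nodes",
    "make_double_sided",
]


@dataclass
class CombineSpec:
    """Inner nodes (by acronym or id) whose subtrees collapse into leaves."""

    targets: list[int | str]


def parse_combine_spec(text: str) -> CombineSpec:
    """Parse a combine-spec file: one acronym or id per line, ``#`` comments."""
    targets: list[int | str] = []
    for raw in text.splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        targets.append(int(line) if line.lstrip("-").isdigit() else line)
    return CombineSpec(targets)


def combine_nodes(faa: FAA, spec: CombineSpec, strict: bool = True) -> FAA:
    """Collapse each target's subtree into a leaf carrying all its voxels.

    Nested targets are redundant (the outermost one already collapses the
    inner one); they are dropped with a warning.  A leaf target is a spec
    error when ``strict`` (the default); with ``strict=False`` it is
    skipped with a warning, which makes the operation idempotent.
    """
    onto = faa.ontology.copy()
    ids: list[int] = []
    for ref in spec.targets:
        nid = onto.resolve(ref)
        if onto.nodes[nid].is_leaf:
            if strict:
                raise CombineSpecError(f"combine target {ref!r} (id {nid}) is a leaf")
            warnings.warn(f"combine target {ref!r} (id {nid}) is already a leaf; skipped")
            continue
        ids.append(nid)
    # outermost wins: drop any target that is a descendant of another
    keep: list[int] = []
    for nid in ids:
        anc = set(onto.ancestors(nid))
        if anc & set(ids):
            warnings.warn(f"combine target {nid} nested inside another target; outermost wins")
        else:
            keep.append(nid)

    mapping: dict[int, int] = {}
    removed_total = 0
    for nid in keep:
        desc = onto.descendants(nid)
        for d in desc:
            if onto.nodes[d].is_leaf:
                mapping[d] = nid
            del onto.nodes[d]
        onto.nodes[nid].children_ids = []
        removed_total += len(desc)
    onto.validate()

    uniq, inverse = np.unique(faa.volume.data, return_inverse=True)
    lut = np.array([mapping.get(int(u), int(u)) for u in uniq], dtype=np.int64)
    vol = faa.volume.with_data(lut[inverse].reshape(faa.volume.data.shape))
    append_sizes(onto, label_sizes(vol))
    out = FAA(onto, vol, list(faa.provenance))
    out.log(f"combined {len(keep)} targets {sorted(keep)}, removed {removed_total} descendant nodes")
    validate_faa(out)
    return out


@dataclass
class SideMap:
    """Renumbering record for a double-sided atlas.

    Left ids are 1..N in depth-first pre-order of the single-sided tree;
    right id = left id + ``offset`` with ``offset = N`` (the per-hemisphere
    node count); the new root has id 2N+1.
    """

    n_per_side: int
    offset: int
    mapping: dict[int, tuple[int, int]]

    def to_frame(self, onto: AnnotationOntology | None = None):
        import pandas as pd

        rows = []
        for old in sorted(self.mapping, key=lambda o: self.mapping[o][0]):
            left, right = self.mapping[old]
            acr = onto.nodes[old].acronym if (onto is not None and old in onto.nodes) else ""
            rows.append({"old_id": old, "acronym": acr, "left_id": left, "right_id": right})
        return pd.DataFrame(rows, columns=["old_id", "acronym", "left_id", "right_id"])


def make_double_sided(faa: FAA) -> tuple[FAA, SideMap]:
    """Split every structure into distinct left/right nodes.

    The ontology gains a new root with ``root_L``/``root_R`` children,
    each a full copy of the old tree with acronyms suffixed ``_L``/``_R``.
    Voxels left of the midline (per the volume's ``lr_axis`` declaration)
    take left ids, the rest right ids.  A structure lying wholly in one
    hemisphere keeps an empty (size-0) twin on the other side so the two
    half-trees stay isomorphic; empty twins are flagged in provenance.
    """
    old = faa.ontology
    order = old.preorder()
    n = len(order)
    left_id = {nid: k + 1 for k, nid in enumerate(order)}
    offset = n
    mapping = {nid: (left_id[nid], left_id[nid] + offset) for nid in order}
    new_root_id = 2 * n + 1

    nodes: dict[int, OntologyNode] = {}
    old_root = old.nodes[old.root_id]
    nodes[new_root_id] = OntologyNode(
        id=new_root_id, name=old_root.name, acronym=old_root.acronym,
        parent_id=None,
        children_ids=[mapping[old.root_id][0], mapping[old.root_id][1]],
        color_hex=old_root.color_hex,
    )
    for side, suffix in ((0, "_L"), (1, "_R")):
        for nid in order:
            src = old.nodes[nid]
            parent = (
                new_root_id if nid == old.root_id else mapping[src.parent_id][side]
            )
            nodes[mapping[nid][side]] = OntologyNode(
                id=mapping[nid][side],
                name=src.name + (", left" if side == 0 else ", right"),
                acronym=src.acronym + suffix,
                parent_id=parent,
                children_ids=[mapping[c][side] for c in src.children_ids],
                color_hex=src.color_hex,
            )
    onto = AnnotationOntology(nodes, new_root_id)

    left_mask, _ = hemisphere_masks(faa.volume)
    data = faa.volume.data
    uniq, inverse = np.unique(data, return_inverse=True)
    lut_l = np.array([mapping.get(int(u), (0, 0))[0] for u in uniq], dtype=np.int64)
    lut_r = np.array([mapping.get(int(u), (0, 0))[1] for u in uniq], dtype=np.int64)
    coded = np.where(left_mask, lut_l[inverse].reshape(data.shape), lut_r[inverse].reshape(data.shape))
    vol = faa.volume.with_data(coded)

    sizes = label_sizes(vol)
    append_sizes(onto, sizes)
    out = FAA(onto, vol, list(faa.provenance))
    empty_twins = sorted(
        onto.nodes[i].acronym
        for i in onto.leaf_ids()
        if (onto.nodes[i].size_nl or 0) == 0
    )
    out.log(f"double-sided: {n} nodes/hemisphere, right offset {offset}, new root id {new_root_id}")
    if empty_twins:
        out.log(f"empty homotopic twins kept with size 0: {empty_twins}")
    validate_faa(out)
    return out, SideMap(n_per_side=n, offset=offset, mapping=mapping)
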